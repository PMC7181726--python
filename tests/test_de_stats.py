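"""Moderated differential-abundance statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibroprot.de_stats import (
    DERecord,
    assess_significance,
    estimate_prior_sd,
    moderate_sd,
    moderated_t_test,
    multigroup_union,
    protein_group_stats,
    records_to_frame,
    run_two_group_test,
)
from fibroprot.ingest import SampleDesign
from fibroprot.synthetic_data import LfqSimParams, generate_lfq

from conftest import make_matrix


def _design(groups):
    rows = []
    for g, n in groups:
        for i in range(n):
            rows.append((f"{g}{i}", f"{g}{i}", g, 1))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "biounit_id", "group", "tech_rep"]
    ))


class TestProteinGroupStats:
    def test_clean_two_group_case(self):
        m = make_matrix([[10.0, 10.0, 10.0, 8.0, 8.0, 8.0]],
                        sample_ids=["a0", "a1", "a2", "b0", "b1", "b2"])
        d = _design([("a", 3), ("b", 3)])
        (r,) = protein_group_stats(m, d, ("a", "b"))
        assert r.log2fc == pytest.approx(2.0)
        assert r.sd == pytest.approx(0.0)
        assert r.fraction_missing == 0.0
        assert (r.n_valid_a, r.n_valid_b) == (3, 3)

    def test_all_missing_group_untestable(self):
        m = make_matrix([[10.0, 11.0, np.nan, np.nan]],
                        sample_ids=["a0", "a1", "b0", "b1"])
        d = _design([("a", 2), ("b", 2)])
        (r,) = protein_group_stats(m, d, ("a", "b"))
        assert r.untestable
        assert math.isnan(r.mean_b)

    def test_unknown_group_errors(self):
        m = make_matrix([[1.0, 2.0]], sample_ids=["a0", "b0"])
        d = _design([("a", 1), ("b", 1)])
        with pytest.raises(KeyError, match="nope"):
            protein_group_stats(m, d, ("a", "nope"))

    def test_matches_brute_force(self, rng):
        vals = rng.normal(25, 2, size=(30, 8))
        vals[rng.random(vals.shape) < 0.25] = np.nan
        sids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        m = make_matrix(vals, sample_ids=sids)
        d = _design([("a", 4), ("b", 4)])
        recs = protein_group_stats(m, d, ("a", "b"))
        for i, r in enumerate(recs):
            va = vals[i, :4][np.isfinite(vals[i, :4])]
            vb = vals[i, 4:][np.isfinite(vals[i, 4:])]
            if len(va) and len(vb):
                assert r.mean_a == pytest.approx(va.mean(), abs=1e-12)
                assert r.mean_b == pytest.approx(vb.mean(), abs=1e-12)
                assert r.log2fc == pytest.approx(va.mean() - vb.mean(),
                                                 abs=1e-12)
                df = len(va) + len(vb) - 2
                if df >= 1:
                    pooled = math.sqrt(
                        (((va - va.mean()) ** 2).sum()
                         + ((vb - vb.mean()) ** 2).sum()) / df)
                    assert r.sd == pytest.approx(pooled, abs=1e-12)
            assert r.fraction_missing == pytest.approx(
                np.isnan(vals[i]).mean(), abs=1e-12)


def _records_from_arrays(inten, sd):
    return [
        DERecord(f"P{i}", "a", "b", mean_a=float(x), mean_b=float(x),
                 sd=float(s))
        for i, (x, s) in enumerate(zip(inten, sd))
    ]


class TestPriorSd:
    def test_constant_sd_recovered(self, rng):
        inten = rng.uniform(20, 30, 400)
        recs = _records_from_arrays(inten, np.full(400, 0.3))
        prior = estimate_prior_sd(recs, 1000)
        assert all(abs(v - 0.3) < 0.01 for v in prior.values())

    def test_linear_trend_recovered(self, rng):
        inten = rng.uniform(5, 20, 2000)
        true = 0.5 - 0.02 * inten
        obs = true * np.sqrt(rng.chisquare(10, 2000) / 10)
        recs = _records_from_arrays(inten, obs)
        prior = estimate_prior_sd(recs, 1000)
        fitted = np.array([prior[f"P{i}"] for i in range(2000)])
        lo, hi = np.argmin(inten), np.argmax(inten)
        assert fitted[lo] == pytest.approx(0.5 - 0.02 * inten[lo], rel=0.10)
        assert fitted[hi] == pytest.approx(0.5 - 0.02 * inten[hi], rel=0.10)
        # slope sign: decreasing in intensity
        order = np.argsort(inten)
        assert fitted[order][:100].mean() > fitted[order][-100:].mean()

    def test_span_clipped_to_dataset(self, rng):
        inten = rng.uniform(20, 30, 50)
        sd = rng.uniform(0.2, 0.4, 50)
        recs = _records_from_arrays(inten, sd)
        clipped = estimate_prior_sd(recs, 1000)
        exact = estimate_prior_sd(recs, 50)
        for k in clipped:
            assert clipped[k] == pytest.approx(exact[k], abs=1e-12)

    def test_too_few_records_errors(self):
        recs = _records_from_arrays([25.0] * 5, [0.3] * 5)
        with pytest.raises(ValueError, match=">= 10"):
            estimate_prior_sd(recs, 1000)

    def test_prior_floored_at_zero(self, rng):
        inten = np.linspace(10, 30, 200)
        sd = np.clip(0.05 - 0.002 * inten, 0, None) + rng.normal(0, 0.001, 200)
        recs = _records_from_arrays(inten, np.abs(sd))
        prior = estimate_prior_sd(recs, 50)
        assert all(v >= 0 for v in prior.values())


class TestModeration:
    @pytest.mark.parametrize("sd,prior,expected", [
        (0.2, 0.4, 0.3),
        (0.0, 0.4, 0.2),
        (None, 0.4, 0.4),
    ])
    def test_moderate_sd_rule(self, sd, prior, expected):
        assert moderate_sd(sd, prior) == pytest.approx(expected)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            moderate_sd(-0.1, 0.2)
        with pytest.raises(ValueError):
            moderate_sd(0.1, -0.2)

    def test_zero_fold_change_gives_p_one(self):
        r = DERecord("P", "a", "b", mean_a=10.0, mean_b=10.0,
                     n_valid_a=3, n_valid_b=3, log2fc=0.0,
                     sd=0.3, sd_prior=0.3, sd_mod=0.3)
        moderated_t_test(r)
        assert r.t_stat == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_equals_classic_pooled_t_when_prior_matches_sd(self, rng):
        # with sd_prior = sd the moderated statistic must reduce exactly to
        # the textbook pooled two-sample t on the same cells
        for _ in range(500):
            na, nb = rng.integers(2, 7, size=2)
            a = rng.normal(25, 0.5, na)
            b = rng.normal(25 + rng.normal(0, 1), 0.5, nb)
            df = na + nb - 2
            pooled = math.sqrt((((a - a.mean()) ** 2).sum()
                                + ((b - b.mean()) ** 2).sum()) / df)
            if pooled == 0:
                continue
            r = DERecord("P", "a", "b", mean_a=a.mean(), mean_b=b.mean(),
                         n_valid_a=int(na), n_valid_b=int(nb),
                         log2fc=a.mean() - b.mean(),
                         sd=pooled, sd_prior=pooled,
                         sd_mod=moderate_sd(pooled, pooled))
            moderated_t_test(r)
            t_ref = stats.ttest_ind(a, b, equal_var=True).statistic
            assert abs(r.t_stat - t_ref) < 1e-9

    def test_untestable_when_df_below_one(self):
        r = DERecord("P", "a", "b", mean_a=10.0, mean_b=9.0,
                     n_valid_a=1, n_valid_b=1, log2fc=1.0,
                     sd=None, sd_prior=0.3, sd_mod=0.3)
        moderated_t_test(r)
        assert r.untestable

    def test_moderation_stabilizes_t_variance(self, rng):
        # null proteins: Var(t) with moderated SD <= Var(t) with raw SD
        n = 1000
        t_raw, t_mod = [], []
        prior = 0.3 * math.sqrt(2 / 10) * math.gamma(5.5) / math.gamma(5.0)
        for _ in range(n):
            a, b = rng.normal(0, 0.3, 6), rng.normal(0, 0.3, 6)
            df = 10
            pooled = math.sqrt((((a - a.mean()) ** 2).sum()
                                + ((b - b.mean()) ** 2).sum()) / df)
            se_raw = pooled * math.sqrt(1 / 3)
            se_mod = 0.5 * (pooled + prior) * math.sqrt(1 / 3)
            delta = a.mean() - b.mean()
            t_raw.append(delta / se_raw)
            t_mod.append(delta / se_mod)
        assert np.var(t_mod) <= np.var(t_raw)


class TestSignificance:
    @pytest.mark.parametrize("p,miss,expected", [
        (0.005, 0.40, True),
        (0.005, 0.60, False),
        (0.02, 0.00, False),
    ])
    def test_threshold_and_missingness_gate(self, p, miss, expected):
        r = DERecord("P", "a", "b", p_value=p, fraction_missing=miss)
        assess_significance([r])
        assert r.significant is expected

    def test_untestable_never_significant(self):
        r = DERecord("P", "a", "b", p_value=0.001, fraction_missing=0.0,
                     untestable=True)
        assess_significance([r])
        assert not r.significant


class TestPowerAndUnion:
    def test_power_monotone_in_effect_size(self):
        powers = []
        for k, fc in enumerate([0.5, 1.0, 2.0]):
            p = LfqSimParams(
                n_proteins=600, de_fraction=0.15, de_log2fc_values=(fc,),
                noise_b=0.0, noise_a=0.3, sample_shift_sd=0.0,
                mnar_midpoint=-100.0, mcar_rate=0.0, seed=77,
                n_contaminants=0, n_reverse=0, n_only_site=0,
            )
            sim = generate_lfq(p)
            recs = run_two_group_test(sim.matrix, sim.design,
                                      ("case", "control"))
            true_de = sim.truth.de_proteins("case")
            sig = {r.protein_id for r in recs if r.significant}
            powers.append(len(sig & true_de) / len(true_de))
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > 0.95

    def test_fold_change_recovery(self):
        p = LfqSimParams(
            n_proteins=1000, de_fraction=0.1, noise_b=0.0, noise_a=0.3,
            sample_shift_sd=0.0, mnar_midpoint=-100.0, mcar_rate=0.0,
            seed=5, n_contaminants=0, n_reverse=0, n_only_site=0,
        )
        sim = generate_lfq(p)
        recs = run_two_group_test(sim.matrix, sim.design, ("case", "control"))
        truth = sim.truth.effects["case"]
        est = {r.protein_id: r.log2fc for r in recs if not r.untestable}
        de = sim.truth.de_proteins("case")
        aligned = [np.sign(truth[p_]) * (est[p_] - truth[p_])
                   for p_ in de if p_ in est]
        assert abs(np.mean(aligned)) < 0.1

    def test_union_matches_per_contrast_oracle(self):
        p = LfqSimParams(
            n_proteins=500,
            groups=(("ctl", 4), ("ko", 4), ("ko_drug", 4), ("ctl_drug", 4)),
            seed=13, n_contaminants=0, n_reverse=0, n_only_site=0,
        )
        sim = generate_lfq(p)
        contrasts = [("ko", "ctl"), ("ko_drug", "ko"), ("ctl_drug", "ctl")]
        union = multigroup_union(sim.matrix, sim.design, contrasts)
        brute = set()
        for c in contrasts:
            recs = run_two_group_test(sim.matrix, sim.design, c)
            brute |= {r.protein_id for r in recs if r.significant}
        assert union == brute
        assert len(union) > 0

    def test_single_contrast_union_equals_that_contrast(self):
        p = LfqSimParams(n_proteins=300, seed=21,
                         n_contaminants=0, n_reverse=0, n_only_site=0)
        sim = generate_lfq(p)
        union = multigroup_union(sim.matrix, sim.design, [("case", "control")])
        recs = run_two_group_test(sim.matrix, sim.design, ("case", "control"))
        assert union == {r.protein_id for r in recs if r.significant}

    def test_empty_contrast_list_errors(self):
        p = LfqSimParams(n_proteins=50, seed=1)
        sim = generate_lfq(p)
        with pytest.raises(ValueError, match="empty"):
            multigroup_union(sim.matrix, sim.design, [])


def test_records_frame_has_fdr_column_and_rows():
    p = LfqSimParams(n_proteins=200, seed=3,
                     n_contaminants=0, n_reverse=0, n_only_site=0)
    sim = generate_lfq(p)
    recs = run_two_group_test(sim.matrix, sim.design, ("case", "control"))
    df = records_to_frame(recs)
    assert len(df) == 200
    tested = df[~df["untestable"]]
    assert (tested["fdr_bh"] >= tested["p_value"] - 1e-12).all()
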