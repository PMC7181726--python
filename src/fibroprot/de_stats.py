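"""Moderated differential-abundance testing for LFQ intensities.

Per-protein noise is estimated as an equally weighted average of the
protein-specific pooled residual standard deviation SD and an
intensity-dependent prior SD_prior obtained by LOWESS smoothing of SD
against mean log2 intensity across all proteins. The moderated t statistic

    t = log2fc / (sd_mod * sqrt(1/nA + 1/nB)),   sd_mod = (SD + SD_prior)/2

is referred to a t distribution with nA + nB - 2 degrees of freedom. A
protein is called significantly changed when its two-sided P value falls
below ``alpha_sig`` and fewer than ``max_missing_fraction`` of its cells in
the compared samples are missing. No multiple-testing correction gates the
call (a Benjamini-Hochberg column is reported for reference only).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .ingest import LfqMatrix, SampleDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestConfig:
    """Significance-calling parameters.

    alpha_sig
        Raw two-sided P-value threshold (default 0.01).
    max_missing_fraction
        Proteins with at least this fraction of missing cells among the
        compared samples are never called significant (default 0.5).
    lowess_span_points
        Nearest-neighbour window of the LOWESS prior, clipped to the number
        of proteins with a defined SD (default 1000).
    df_scale
        Multiplier on the residual degrees of freedom nA + nB - 2 used when
        referring t to its null distribution. Averaging the protein SD with
        an (approximately known) prior halves the standard deviation of the
        variance estimate, so by the delta method (Var(s) ~ sigma^2 / 2d)
        the moderated SD behaves like an SD estimate with ~4x the residual
        degrees of freedom; the default of 4 keeps the test calibrated. Set
        to 1 for the classic residual-df reference.
    """

    alpha_sig: float = 0.01
    max_missing_fraction: float = 0.5
    lowess_span_points: int = 1000
    df_scale: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_sig < 1.0:
            raise ValueError("alpha_sig must be in (0, 1)")
        if not 0.0 < self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in (0, 1]")
        if self.lowess_span_points < 10:
            raise ValueError("lowess_span_points must be >= 10")
        if self.df_scale <= 0:
            raise ValueError("df_scale must be > 0")


@dataclass
class DERecord:
    """Differential-abundance result for one protein and one contrast."""

    protein_id: str
    group_a: str
    group_b: str
    mean_a: float = math.nan
    mean_b: float = math.nan
    n_valid_a: int = 0
    n_valid_b: int = 0
    fraction_missing: float = math.nan
    log2fc: float = math.nan
    sd: float | None = None  # None when residual df < 1
    sd_prior: float = math.nan
    sd_mod: float = math.nan
    t_stat: float = math.nan
    p_value: float = math.nan
    significant: bool = False
    untestable: bool = False

    @property
    def mean_intensity(self) -> float:
        """Mean of the two group means; the LOWESS prior's abscissa."""
        return 0.5 * (self.mean_a + self.mean_b)


def protein_group_stats(
    m: LfqMatrix, d: SampleDesign, groups: tuple[str, str]
) -> list[DERecord]:
    """Group means, valid counts, missingness, log2fc and pooled SD per protein.

    ``log2fc`` is mean(group A) - mean(group B); the pooled residual SD uses
    both groups' residuals and is undefined when the total residual degrees
    of freedom nA + nB - 2 fall below 1.
    """
    ga, gb = groups
    cols_a = [m.sample_ids.index(s) for s in d.samples_in_group(ga)
              if s in m.sample_ids]
    cols_b = [m.sample_ids.index(s) for s in d.samples_in_group(gb)
              if s in m.sample_ids]
    if not cols_a or not cols_b:
        raise ValueError(f"groups {groups} have no samples in the matrix")

    va, vb = m.values[:, cols_a], m.values[:, cols_b]
    fa, fb = np.isfinite(va), np.isfinite(vb)
    na, nb = fa.sum(axis=1), fb.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_a = np.where(na > 0, np.nansum(va, axis=1) / np.maximum(na, 1), np.nan)
        mean_b = np.where(nb > 0, np.nansum(vb, axis=1) / np.maximum(nb, 1), np.nan)
        ss_a = np.nansum((va - mean_a[:, None]) ** 2 * fa, axis=1)
        ss_b = np.nansum((vb - mean_b[:, None]) ** 2 * fb, axis=1)
    df = na + nb - 2
    n_cells = len(cols_a) + len(cols_b)
    frac_missing = 1.0 - (na + nb) / n_cells

    records = []
    for i, pid in enumerate(m.protein_ids):
        sd: float | None = None
        if na[i] >= 1 and nb[i] >= 1 and df[i] >= 1:
            sd = float(np.sqrt((ss_a[i] + ss_b[i]) / df[i]))
        untestable = na[i] < 1 or nb[i] < 1
        records.append(DERecord(
            protein_id=pid,
            group_a=ga,
            group_b=gb,
            mean_a=float(mean_a[i]) if na[i] > 0 else math.nan,
            mean_b=float(mean_b[i]) if nb[i] > 0 else math.nan,
            n_valid_a=int(na[i]),
            n_valid_b=int(nb[i]),
            fraction_missing=float(frac_missing[i]),
            log2fc=float(mean_a[i] - mean_b[i])
            if na[i] > 0 and nb[i] > 0 else math.nan,
            sd=sd,
            untestable=bool(untestable),
        ))
    return records


def estimate_prior_sd(
    records: list[DERecord], span_points: int = 1000
) -> dict[str, float]:
    """LOWESS fit of pooled SD against mean log2 intensity.

    The smoother uses the ``min(span_points, n)`` nearest neighbours by
    intensity with tricube weights and a locally linear fit (no robustness
    iterations); predictions are floored at 0. Returns SD_prior per protein
    id, including proteins whose own SD is undefined (evaluated at their mean
    intensity when defined).
    """
    fit_recs = [r for r in records
                if r.sd is not None and math.isfinite(r.mean_intensity)]
    if len(fit_recs) < 10:
        raise ValueError(
            f"only {len(fit_recs)} proteins with defined SD; need >= 10"
        )
    x = np.array([r.mean_intensity for r in fit_recs])
    y = np.array([r.sd for r in fit_recs])
    window = min(span_points, len(x))
    frac = window / len(x)

    eval_recs = [r for r in records if math.isfinite(r.mean_intensity)]
    xeval = np.array([r.mean_intensity for r in eval_recs])
    # fit on SD-defined proteins, evaluate at every protein's intensity
    fitted = sm_lowess(y, x, frac=frac, it=0, xvals=np.sort(xeval))
    order = np.argsort(xeval, kind="stable")
    prior = np.empty_like(xeval)
    prior[order] = np.maximum(fitted, 0.0)
    return {r.protein_id: float(p) for r, p in zip(eval_recs, prior)}


def moderate_sd(sd: float | None, sd_prior: float) -> float:
    """Equally weighted average of protein SD and prior SD.

    Falls back to the prior alone when the protein SD is undefined (zero
    residual degrees of freedom).
    """
    if sd_prior < 0 or (sd is not None and sd < 0):
        raise ValueError("standard deviations must be non-negative")
    if sd is None:
        return sd_prior
    return 0.5 * (sd + sd_prior)


def moderated_t_test(r: DERecord, df_scale: float = 4.0) -> DERecord:
    """Complete a record with the moderated t statistic and two-sided P.

    The statistic uses residual degrees of freedom nA + nB - 2; its null
    reference is a t distribution with ``df_scale`` times that (see
    :class:`TestConfig.df_scale`). Records with residual df < 1 or a zero
    moderated SD are flagged untestable.
    """
    if r.untestable or not (math.isfinite(r.mean_a) and math.isfinite(r.mean_b)):
        r.untestable = True
        return r
    df = r.n_valid_a + r.n_valid_b - 2
    if df < 1 or not (r.sd_mod > 0):
        r.untestable = True
        return r
    se = r.sd_mod * math.sqrt(1.0 / r.n_valid_a + 1.0 / r.n_valid_b)
    r.t_stat = r.log2fc / se
    r.p_value = float(2.0 * sps.t.sf(abs(r.t_stat), df_scale * df))
    return r


def assess_significance(
    records: list[DERecord], cfg: TestConfig | None = None
) -> list[DERecord]:
    """Flag proteins with P below alpha and missingness below the gate."""
    cfg = cfg or TestConfig()
    for r in records:
        r.significant = (
            not r.untestable
            and math.isfinite(r.p_value)
            and r.p_value < cfg.alpha_sig
            and r.fraction_missing < cfg.max_missing_fraction
        )
    return records


def run_two_group_test(
    m: LfqMatrix,
    d: SampleDesign,
    groups: tuple[str, str],
    cfg: TestConfig | None = None,
) -> list[DERecord]:
    """Full moderated test for one contrast: stats, prior, moderation, calls."""
    cfg = cfg or TestConfig()
    records = protein_group_stats(m, d, groups)
    prior = estimate_prior_sd(records, cfg.lowess_span_points)
    for r in records:
        if r.protein_id in prior:
            r.sd_prior = prior[r.protein_id]
            r.sd_mod = moderate_sd(r.sd, r.sd_prior)
            if r.sd is None:
                logger.debug(
                    "protein %s: SD undefined, using prior alone", r.protein_id
                )
        moderated_t_test(r, df_scale=cfg.df_scale)
    return assess_significance(records, cfg)


def multigroup_union(
    m: LfqMatrix,
    d: SampleDesign,
    contrasts: list[tuple[str, str]],
    cfg: TestConfig | None = None,
) -> set[str]:
    """Proteins significant in at least one of the pairwise contrasts."""
    if not contrasts:
        raise ValueError("contrast list is empty")
    out: set[str] = set()
    for pair in contrasts:
        recs = run_two_group_test(m, d, tuple(pair), cfg)
        out |= {r.protein_id for r in recs if r.significant}
    return out


def records_to_frame(records: list[DERecord]) -> pd.DataFrame:
    """Tabular view of DE records (one row per protein) with a BH-FDR column."""
    df = pd.DataFrame([{
        "protein_id": r.protein_id,
        "group_a": r.group_a,
        "group_b": r.group_b,
        "mean_a": r.mean_a,
        "mean_b": r.mean_b,
        "n_valid_a": r.n_valid_a,
        "n_valid_b": r.n_valid_b,
        "fraction_missing": r.fraction_missing,
        "log2fc": r.log2fc,
        "sd": math.nan if r.sd is None else r.sd,
        "sd_prior": r.sd_prior,
        "sd_mod": r.sd_mod,
        "t_stat": r.t_stat,
        "p_value": r.p_value,
        "significant": r.significant,
        "untestable": r.untestable,
    } for r in records])
    tested = df["p_value"].notna() & ~df["untestable"]
    fdr = np.full(len(df), np.nan)
    if tested.any():
        from statsmodels.stats.multitest import multipletests
        fdr[tested.to_numpy()] = multipletests(
            df.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    df["fdr_bh"] = fdr
    return df
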