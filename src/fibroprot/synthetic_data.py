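"""Synthetic LFQ and PRM data with known ground truth.

The LFQ generator emulates the statistical structure the analysis pipeline
assumes: heavy-tailed base log2-intensity distributions (lognormal mixture
or t location-scale), per-sample systematic shifts, an intensity-dependent
noise level ``a + b*exp(-c*intensity)`` that decreases with abundance,
missing-not-at-random dropout that is logistic in the realized log2
intensity (low-abundance cells drop out most), a uniform missing-completely-
at-random component, technical replicates, multi-group designs, and a known
subset of truly changed proteins with stated log2 fold changes. Output is
written in the proteinGroups dialect (raw-scale intensities, zeros for
missing cells, a few planted contaminant/decoy rows) so the generator
exercises the ingest layer as well.

The PRM generator produces a transition report with two quantified peptides
plus the excluded standard peptide, six fragments each; light areas are the
heavy areas times the group ratio times lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import (
    LfqMatrix,
    PrmTable,
    ProteinMeta,
    SampleDesign,
    write_design,
    write_prm_table,
    write_protein_groups,
)
from .prm_quant import DEFAULT_EXCLUDED

_MATRISOME_SEED_SYMBOLS = (
    "COL14A1", "TNC", "SERPINH1", "COL4A1", "COL4A2", "COL4A3",
    "FN1", "POSTN", "SPARC", "DCN", "BGN", "LUM", "MMP2", "TIMP1",
)


@dataclass(frozen=True)
class LfqSimParams:
    """Ground-truth parameters of the synthetic LFQ experiment."""

    n_proteins: int = 2000
    groups: tuple[tuple[str, int], ...] = (("control", 6), ("case", 6))
    tech_reps: int = 1
    base_intensity_dist: str = "lognormal-mixture"  # or "t-location-scale"
    mixture_weights: tuple[float, float] = (0.85, 0.15)
    mixture_means: tuple[float, float] = (27.0, 24.0)
    mixture_sds: tuple[float, float] = (1.8, 1.2)
    t_df: float = 4.0
    t_loc: float = 26.5
    t_scale: float = 1.8
    sample_shift_sd: float = 0.3
    noise_a: float = 0.2
    noise_b: float = 6.0
    noise_c: float = 0.18
    tech_noise_sd: float = 0.1
    de_fraction: float = 0.1
    de_log2fc_values: tuple[float, ...] = (-1.0, 1.0)
    mnar_midpoint: float = 23.5
    mnar_slope: float = 1.2
    mcar_rate: float = 0.02
    n_contaminants: int = 4
    n_reverse: int = 3
    n_only_site: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ValueError("each group needs >= 1 biological unit")
        if self.tech_reps < 1:
            raise ValueError("tech_reps must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.mcar_rate <= 1.0:
            raise ValueError("mcar_rate must be in [0, 1]")
        if self.base_intensity_dist not in (
            "lognormal-mixture", "t-location-scale"
        ):
            raise ValueError(f"unknown base distribution {self.base_intensity_dist}")

    def noise_sd_at(self, intensity: np.ndarray) -> np.ndarray:
        """Monotone-decreasing noise SD as a function of log2 intensity."""
        return self.noise_a + self.noise_b * np.exp(-self.noise_c * intensity)


@dataclass
class SynthTruth:
    """Everything needed to recover the planted signal."""

    base_intensity: np.ndarray  # per protein
    effects: pd.DataFrame  # protein x group true log2fc vs reference group
    sample_shift: pd.Series  # per sample
    true_values: pd.DataFrame  # protein x sample pre-dropout log2 intensity
    dropout_cause: pd.DataFrame  # protein x sample in {observed, mnar, mcar}
    params: LfqSimParams

    def de_proteins(self, group: str) -> set[str]:
        eff = self.effects[group]
        return set(eff.index[eff != 0.0])

    def expected_missing_rate(self) -> float:
        """Analytic expectation of the overall missingness fraction."""
        p = self.params
        x = self.true_values.to_numpy()
        p_mnar = 1.0 / (1.0 + np.exp(p.mnar_slope * (x - p.mnar_midpoint)))
        return float(np.mean(p_mnar + (1.0 - p_mnar) * p.mcar_rate))


@dataclass
class SynthLfq:
    matrix: LfqMatrix
    design: SampleDesign
    truth: SynthTruth
    protein_groups_path: Path | None = None
    design_path: Path | None = None


def _sample_base_intensity(p: LfqSimParams, rng: np.random.Generator) -> np.ndarray:
    if p.base_intensity_dist == "lognormal-mixture":
        comp = rng.choice(2, size=p.n_proteins, p=np.asarray(p.mixture_weights) /
                          sum(p.mixture_weights))
        mu = np.asarray(p.mixture_means)[comp]
        sd = np.asarray(p.mixture_sds)[comp]
        return rng.normal(mu, sd)
    return p.t_loc + p.t_scale * rng.standard_t(p.t_df, size=p.n_proteins)


def generate_lfq(
    params: LfqSimParams | None = None, out_dir: str | Path | None = None
) -> SynthLfq:
    """Simulate an LFQ experiment; optionally write proteinGroups + design.

    The observed raw intensity of a quantified cell is
    ``2**(base + group_effect + biological_noise + sample_shift + tech_noise)``;
    cells drop out with logistic-in-intensity MNAR probability plus a uniform
    MCAR rate and are written as 0.
    """
    p = params or LfqSimParams()
    rng = np.random.default_rng(p.seed)

    # design: biounits per group, tech_reps samples per biounit
    rows = []
    for g, n_bio in p.groups:
        for b in range(1, n_bio + 1):
            bid = f"{g}_{b:02d}"
            for r in range(1, p.tech_reps + 1):
                sid = bid if p.tech_reps == 1 else f"{bid}_r{r}"
                rows.append((sid, bid, g, r))
    design = SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "biounit_id", "group", "tech_rep"]
    ))
    sample_ids = design.sample_ids
    biounits = list(dict.fromkeys(design.table["biounit_id"]))

    protein_ids = [f"P{i:05d}" for i in range(1, p.n_proteins + 1)]
    genes = []
    for i in range(p.n_proteins):
        if i < len(_MATRISOME_SEED_SYMBOLS):
            genes.append((_MATRISOME_SEED_SYMBOLS[i],))
        else:
            genes.append((f"GENE{i + 1}",))

    base = _sample_base_intensity(p, rng)
    noise_sd = p.noise_sd_at(base)

    ref_group = p.groups[0][0]
    effects = pd.DataFrame(
        0.0, index=protein_ids, columns=[g for g, _ in p.groups]
    )
    n_de = int(round(p.de_fraction * p.n_proteins))
    for g, _ in p.groups[1:]:
        idx = rng.choice(p.n_proteins, size=n_de, replace=False)
        effects.iloc[idx, effects.columns.get_loc(g)] = rng.choice(
            p.de_log2fc_values, size=n_de
        )

    shift = pd.Series(
        rng.normal(0.0, p.sample_shift_sd, size=len(sample_ids)),
        index=sample_ids,
    )
    group_of = dict(zip(design.table["sample_id"], design.table["group"]))
    biounit_of = dict(zip(design.table["sample_id"], design.table["biounit_id"]))

    bio_noise = {
        b: rng.normal(0.0, noise_sd) for b in biounits
    }  # per-protein vector per biounit
    x = np.empty((p.n_proteins, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        tech = (rng.normal(0.0, p.tech_noise_sd, size=p.n_proteins)
                if p.tech_reps > 1 else 0.0)
        x[:, j] = (base + effects[group_of[s]].to_numpy()
                   + bio_noise[biounit_of[s]] + shift[s] + tech)

    p_mnar = 1.0 / (1.0 + np.exp(p.mnar_slope * (x - p.mnar_midpoint)))
    u_mnar = rng.random(x.shape)
    u_mcar = rng.random(x.shape)
    mnar = u_mnar < p_mnar
    mcar = ~mnar & (u_mcar < p.mcar_rate)
    missing = mnar | mcar
    cause = np.where(mnar, "mnar", np.where(mcar, "mcar", "observed"))

    values = np.where(missing, np.nan, x)
    meta = [ProteinMeta(pid, g) for pid, g in zip(protein_ids, genes)]
    matrix = LfqMatrix(values, missing, protein_ids, sample_ids, meta)

    # planted flagged rows exercise the pre-filter
    extra_vals, extra_meta, extra_ids = [], [], []
    flag_specs = (
        [("CON__Q{:04d}".format(i), dict(is_contaminant=True))
         for i in range(p.n_contaminants)]
        + [("REV__Q{:04d}".format(i), dict(is_reverse=True))
           for i in range(p.n_reverse)]
        + [("SITE__Q{:04d}".format(i), dict(only_by_site=True))
           for i in range(p.n_only_site)]
    )
    for pid, flags in flag_specs:
        extra_ids.append(pid)
        extra_meta.append(ProteinMeta(pid, (pid.split("__")[0],), **flags))
        extra_vals.append(rng.normal(24.0, 1.0, size=len(sample_ids)))
    if extra_ids:
        full_values = np.vstack([values] + [np.asarray(extra_vals)])
        full_missing = np.vstack(
            [missing, np.zeros((len(extra_ids), len(sample_ids)), dtype=bool)]
        )
        full = LfqMatrix(full_values, full_missing,
                         protein_ids + extra_ids, sample_ids, meta + extra_meta)
    else:
        full = matrix

    truth = SynthTruth(
        base_intensity=base,
        effects=effects,
        sample_shift=shift,
        true_values=pd.DataFrame(x, index=protein_ids, columns=sample_ids),
        dropout_cause=pd.DataFrame(cause, index=protein_ids, columns=sample_ids),
        params=p,
    )
    out = SynthLfq(matrix=full, design=design, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.protein_groups_path = out_dir / "proteinGroups.tsv"
        out.design_path = out_dir / "design.tsv"
        write_protein_groups(full, out.protein_groups_path)
        write_design(design, out.design_path)
        effects.to_csv(out_dir / "truth_effects.tsv", sep="\t",
                       index_label="protein_id")
        shift.rename("shift").to_csv(out_dir / "truth_sample_shift.tsv", sep="\t",
                                     index_label="sample_id")
        truth.dropout_cause.to_csv(out_dir / "truth_dropout.tsv", sep="\t",
                                   index_label="protein_id")
    return out


QUANT_PEPTIDES = ("SYNTHPEPTIDEAK", "SYNTHPEPTIDEBK")
PRM_FRAGMENTS = ("y3", "y4", "y5", "y6", "y7", "y8")
_FRAGMENT_PROPS = np.array([0.05, 0.10, 0.20, 0.30, 0.20, 0.15])


@dataclass
class SynthPrm:
    table: PrmTable
    control_samples: set[str]
    case_samples: set[str]
    true_case_ratio: float
    true_sample_ratio: dict[str, float]


def generate_prm(
    n_control: int = 11,
    n_case: int = 11,
    true_case_ratio: float = 0.4,
    noise_cv: float = 0.1,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> SynthPrm:
    """Simulate a PRM transition report for a control/case cohort.

    Two quantified peptides plus the excluded standard peptide, six fragments
    each; heavy areas fluctuate around a common scale and
    ``light = heavy * group_ratio * lognormal(cv)``.
    """
    if n_control < 1 or n_case < 1:
        raise ValueError("need >= 1 sample per group")
    if true_case_ratio <= 0:
        raise ValueError("true_case_ratio must be > 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    samples = ([(f"control_{i:02d}", "control", 1.0)
                for i in range(1, n_control + 1)]
               + [(f"case_{i:02d}", "case", true_case_ratio)
                  for i in range(1, n_case + 1)])
    peptides = QUANT_PEPTIDES + DEFAULT_EXCLUDED
    rows = []
    true_sample_ratio = {}
    for sid, _, group_ratio in samples:
        true_sample_ratio[sid] = group_ratio
        for pep in peptides:
            heavy_total = 1e6 * rng.lognormal(0.0, 0.2)
            if pep in DEFAULT_EXCLUDED:
                # unreliable standard: erratic heavy signal
                heavy_total *= rng.lognormal(0.0, 1.5) * 1e-2
            ratio = group_ratio * (rng.lognormal(0.0, sigma) if sigma else 1.0)
            heavy_frags = heavy_total * _FRAGMENT_PROPS
            light_frags = heavy_frags * ratio
            for frag, ha, la in zip(PRM_FRAGMENTS, heavy_frags, light_frags):
                rows.append((sid, pep, "heavy", frag, ha))
                rows.append((sid, pep, "light", frag, la))
    table = PrmTable(pd.DataFrame(
        rows, columns=["sample_id", "peptide", "label", "fragment", "area"]
    ))
    out = SynthPrm(
        table=table,
        control_samples={s for s, g, _ in samples if g == "control"},
        case_samples={s for s, g, _ in samples if g == "case"},
        true_case_ratio=true_case_ratio,
        true_sample_ratio=true_sample_ratio,
    )
    if out_path is not None:
        write_prm_table(table, out_path)
    return out
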