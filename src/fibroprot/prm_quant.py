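"""Targeted protein quantification from PRM transition areas.

Each targeted peptide is monitored as light (endogenous) and heavy
(isotope-labelled standard spiked at a fixed amount) with several fragment
ions. The cumulative peak area over a peptide's fragments gives one number
per (sample, peptide, label); the light/heavy ratio is then proportional to
the endogenous amount. Ratios of the quantified peptides are averaged per
sample and expressed relative to the mean of the control group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import fmean

import pandas as pd

from .ingest import PrmTable

logger = logging.getLogger(__name__)

# standard peptide excluded due to unreliable heavy quantification
DEFAULT_EXCLUDED = ("SLSSPTVTLSAPLEGAK",)


@dataclass(frozen=True)
class PrmConfig:
    excluded_peptides: tuple[str, ...] = DEFAULT_EXCLUDED
    expected_peptides_per_sample: int = 2
    geometric_mean: bool = False  # arithmetic mean of peptide ratios by default

    def __post_init__(self) -> None:
        if self.expected_peptides_per_sample < 1:
            raise ValueError("expected_peptides_per_sample must be >= 1")


@dataclass
class PrmResult:
    sample_id: str
    peptide_ratios: dict[str, float]
    mean_ratio: float
    relative_level: float = math.nan


def sum_fragment_areas(
    t: PrmTable, sample: str, peptide: str, label: str
) -> float | None:
    """Cumulative peak area over a peptide's fragment transitions."""
    tab = t.table
    sel = (
        (tab["sample_id"] == sample)
        & (tab["peptide"] == peptide)
        & (tab["label"] == label)
    )
    if not sel.any():
        return None
    return float(tab.loc[sel, "area"].sum())


def peptide_ratio(t: PrmTable, sample: str, peptide: str) -> float | None:
    """Light/heavy cumulative-area ratio (endogenous over spiked standard)."""
    light = sum_fragment_areas(t, sample, peptide, "light")
    heavy = sum_fragment_areas(t, sample, peptide, "heavy")
    if light is None or heavy is None or heavy <= 0:
        logger.warning(
            "undefined ratio for sample=%s peptide=%s (light=%s heavy=%s)",
            sample, peptide, light, heavy,
        )
        return None
    return light / heavy


def sample_level_quant(
    t: PrmTable, cfg: PrmConfig | None = None
) -> list[PrmResult]:
    """Per-sample mean of defined, non-excluded peptide ratios."""
    cfg = cfg or PrmConfig()
    excluded = set(cfg.excluded_peptides)
    results = []
    for sample in t.sample_ids:
        ratios: dict[str, float] = {}
        for pep in t.peptides:
            if pep in excluded:
                continue
            r = peptide_ratio(t, sample, pep)
            if r is not None:
                ratios[pep] = r
        if not ratios:
            logger.error("sample %s: no defined peptide ratios; dropped", sample)
            continue
        if len(ratios) != cfg.expected_peptides_per_sample:
            logger.warning(
                "sample %s: %d peptide ratios (expected %d)",
                sample, len(ratios), cfg.expected_peptides_per_sample,
            )
        if cfg.geometric_mean:
            mean = math.exp(fmean(math.log(v) for v in ratios.values()))
        else:
            mean = fmean(ratios.values())
        results.append(PrmResult(sample, ratios, mean))
    return results


def relative_to_control(
    results: list[PrmResult], control_samples: set[str]
) -> list[PrmResult]:
    """Scale each sample's mean ratio by the control-group average."""
    if not control_samples:
        raise ValueError("control sample set is empty")
    controls = [r for r in results if r.sample_id in control_samples]
    missing = control_samples - {r.sample_id for r in controls}
    if missing:
        raise ValueError(f"control samples without defined levels: {sorted(missing)}")
    ctrl_mean = fmean(r.mean_ratio for r in controls)
    for r in results:
        r.relative_level = r.mean_ratio / ctrl_mean
    return results


def quantify(
    t: PrmTable, control_samples: set[str], cfg: PrmConfig | None = None
) -> list[PrmResult]:
    """Full PRM pipeline: ratios -> per-sample mean -> control-relative level."""
    return relative_to_control(sample_level_quant(t, cfg), control_samples)


def results_to_frame(results: list[PrmResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "mean_ratio": r.mean_ratio,
               "relative_level": r.relative_level}
        for pep, v in sorted(r.peptide_ratios.items()):
            row[f"ratio[{pep}]"] = v
        rows.append(row)
    return pd.DataFrame(rows)
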