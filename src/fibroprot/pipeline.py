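"""End-to-end orchestration: ingest -> normalize -> average -> test -> report.

The stages run in the canonical order for an LFQ differential-abundance
study: pre-filter flagged protein groups, require a minimum number of valid
values, normalize samples, average technical replicates, estimate the
intensity-dependent noise prior, run the moderated test per contrast, call
significance, then annotate/overlap/cluster/project. Outputs are plain TSV
and JSON with a deterministic sort and a checksummed run manifest so two
runs from the same inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation_overlap import (
    annotate_matrisome,
    canonical_symbol,
    overlap_significant,
    pca_scores,
    pearson_hclust_order,
)
from .de_stats import TestConfig, records_to_frame, run_two_group_test
from .ingest import (
    LfqMatrix,
    SampleDesign,
    apply_min_valid_filter,
    filter_flagged,
    packaged_matrisome,
    read_design,
    read_matrisome,
    read_protein_groups,
)
from .normalization import (
    NormalizationConfig,
    average_technical_replicates,
    ordinary_quantile_normalize,
    robust_quantile_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    protein_groups: str
    design: str
    contrasts: list[tuple[str, str]]
    out_dir: str
    matrisome: str | None = None  # packaged mini table when omitted
    second_species_significant: str | None = None  # symbol list, one per line
    intensity_prefix: str = "LFQ intensity "
    min_valid: int = 6
    normalization_method: str = "robust"  # robust | ordinary | none
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    test: TestConfig = field(default_factory=TestConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        norm_raw = raw.pop("normalization", {}) or {}
        method = norm_raw.pop("method", "robust")
        test_raw = raw.pop("test", {}) or {}
        return cls(
            protein_groups=raw["protein_groups"],
            design=raw["design"],
            contrasts=[tuple(c) for c in raw["contrasts"]],
            out_dir=raw["out_dir"],
            matrisome=raw.get("matrisome"),
            second_species_significant=raw.get("second_species_significant"),
            intensity_prefix=raw.get("intensity_prefix", "LFQ intensity "),
            min_valid=int(raw.get("min_valid", 6)),
            normalization_method=method,
            normalization=NormalizationConfig(**norm_raw),
            test=TestConfig(**test_raw),
            seed=int(raw.get("seed", 0)),
        )

    def digest(self) -> str:
        payload = {
            "protein_groups": self.protein_groups,
            "design": self.design,
            "contrasts": [list(c) for c in self.contrasts],
            "matrisome": self.matrisome,
            "second_species_significant": self.second_species_significant,
            "intensity_prefix": self.intensity_prefix,
            "min_valid": self.min_valid,
            "normalization_method": self.normalization_method,
            "normalization": [self.normalization.central_span_alpha,
                              self.normalization.grid_size],
            "test": [self.test.alpha_sig, self.test.max_missing_fraction,
                     self.test.lowess_span_points],
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _significant_symbols(df: pd.DataFrame, m: LfqMatrix) -> set[str]:
    genes_of = {mt.protein_id: mt.gene_symbols for mt in m.meta}
    out: set[str] = set()
    for pid in df.loc[df["significant"], "protein_id"]:
        for g in genes_of.get(pid, ()):
            out.add(canonical_symbol(g))
    return out


def write_de_table(df: pd.DataFrame, path: Path) -> None:
    """Deterministic DE table: sorted by P ascending, ties by protein id."""
    out = df.sort_values(
        ["p_value", "protein_id"], kind="stable", na_position="last"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; write artifacts; return the run summary."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    artifacts: list[Path] = []

    def _stage(name: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # surface the failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    m = _stage("ingest", read_protein_groups, cfg.protein_groups,
               cfg.intensity_prefix)
    stage_counts["loaded"] = m.n_proteins
    d = _stage("design", read_design, cfg.design)

    m = _stage("filter_flagged", filter_flagged, m)
    stage_counts["after_flag_filter"] = m.n_proteins
    m = _stage("min_valid", apply_min_valid_filter, m, cfg.min_valid)
    stage_counts["after_min_valid"] = m.n_proteins

    if cfg.normalization_method == "robust":
        m = _stage("normalize", robust_quantile_normalize, m, cfg.normalization)
    elif cfg.normalization_method == "ordinary":
        m = _stage("normalize", ordinary_quantile_normalize, m)
    elif cfg.normalization_method != "none":
        raise ValueError(f"unknown normalization method {cfg.normalization_method}")

    m, d = _stage("average_replicates", average_technical_replicates, m, d)
    stage_counts["biounits"] = m.n_samples

    mm = (read_matrisome(cfg.matrisome) if cfg.matrisome
          else packaged_matrisome())

    union_significant: set[str] = set()
    all_symbols: set[str] = set()
    for ga, gb in cfg.contrasts:
        recs = _stage(f"test[{ga}-vs-{gb}]", run_two_group_test,
                      m, d, (ga, gb), cfg.test)
        df = records_to_frame(recs)
        name = f"de_{ga}_vs_{gb}"
        write_de_table(df, out_dir / f"{name}.tsv")
        artifacts.append(out_dir / f"{name}.tsv")
        sig_ids = sorted(df.loc[df["significant"], "protein_id"])
        (out_dir / f"{name}.significant.txt").write_text(
            "".join(f"{p}\n" for p in sig_ids)
        )
        artifacts.append(out_dir / f"{name}.significant.txt")
        stage_counts[f"significant[{ga}-vs-{gb}]"] = len(sig_ids)
        union_significant |= set(sig_ids)
        all_symbols |= _significant_symbols(df, m)
    stage_counts["significant_union"] = len(union_significant)

    # matrisome annotation of the union's gene symbols
    ann = annotate_matrisome(all_symbols, mm)
    ann_rows = [
        {"symbol": s,
         "division": v[0] if v else "",
         "category": v[1] if v else ""}
        for s, v in sorted(ann.items())
    ]
    pd.DataFrame(ann_rows, columns=["symbol", "division", "category"]).to_csv(
        out_dir / "matrisome_annotation.tsv", sep="\t", index=False
    )
    artifacts.append(out_dir / "matrisome_annotation.tsv")
    stage_counts["matrisome_annotated"] = sum(
        1 for v in ann.values() if v is not None
    )

    # cross-species overlap when a second significant list is supplied
    if cfg.second_species_significant:
        other = {
            canonical_symbol(line)
            for line in Path(cfg.second_species_significant).read_text().split()
            if line.strip()
        }
        ov = overlap_significant(all_symbols, other)
        (out_dir / "overlap.json").write_text(
            json.dumps(ov.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        artifacts.append(out_dir / "overlap.json")
        stage_counts["overlap_common"] = ov.n_common

    # heatmap matrix + clustering order and PCA over the significant union
    sig_index = [i for i, pid in enumerate(m.protein_ids)
                 if pid in union_significant]
    if len(sig_index) >= 2:
        sub = m.take_rows(np.array(sig_index))
        frame = sub.to_frame()
        frame.to_csv(out_dir / "heatmap_matrix.tsv", sep="\t",
                     index_label="protein_id", float_format="%.10g")
        artifacts.append(out_dir / "heatmap_matrix.tsv")
        try:
            order = pearson_hclust_order(sub.values)
            ordered = [sub.protein_ids[i] for i in order]
            (out_dir / "heatmap_row_order.txt").write_text(
                "".join(f"{p}\n" for p in ordered)
            )
            artifacts.append(out_dir / "heatmap_row_order.txt")
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)
        try:
            scores, evr = pca_scores(sub.values)
            pca_df = pd.DataFrame(
                {"sample_id": sub.sample_ids,
                 "pc1": scores[:, 0], "pc2": scores[:, 1]}
            )
            pca_df.to_csv(out_dir / "pca_scores.tsv", sep="\t", index=False,
                          float_format="%.10g")
            (out_dir / "pca_explained.json").write_text(
                json.dumps({"pc1": float(evr[0]), "pc2": float(evr[1])},
                           sort_keys=True) + "\n"
            )
            artifacts.extend([out_dir / "pca_scores.tsv",
                              out_dir / "pca_explained.json"])
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)

    manifest = {
        "package_version": __version__,
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "stage_counts": stage_counts,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return {"stage_counts": stage_counts, "manifest": manifest,
            "out_dir": str(out_dir)}
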