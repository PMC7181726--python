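"""Parsing and pre-filtering of proteomics input tables.

Reads MaxQuant-dialect ``proteinGroups`` tables into an :class:`LfqMatrix`
(log2 LFQ intensities with an explicit missing mask), sample design tables,
matrisome annotation tables, and long-format PRM transition reports.

Pre-filtering follows the standard Perseus workflow: drop decoy ("Reverse"),
potential contaminant and "only identified by site" entries, then require a
minimum number of valid (quantified) values per protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# canonical MaxQuant proteinGroups column names
COL_MAJORITY_IDS = "Majority protein IDs"
COL_GENE_NAMES = "Gene names"
COL_REVERSE = "Reverse"
COL_CONTAMINANT = "Potential contaminant"
COL_ONLY_BY_SITE = "Only identified by site"
DEFAULT_INTENSITY_PREFIX = "LFQ intensity "

PRM_LABELS = frozenset({"light", "heavy"})


class FormatError(ValueError):
    """Raised when an input table does not conform to the expected dialect."""


@dataclass(frozen=True)
class ProteinMeta:
    """Identity and filter flags for one protein group."""

    protein_id: str
    gene_symbols: tuple[str, ...]
    is_reverse: bool = False
    is_contaminant: bool = False
    only_by_site: bool = False

    @property
    def flagged(self) -> bool:
        return self.is_reverse or self.is_contaminant or self.only_by_site


@dataclass
class LfqMatrix:
    """Protein x sample matrix of log2 LFQ intensities.

    ``values`` holds NaN at missing cells; ``missing`` is the matching boolean
    mask (a cell is either finite or flagged missing, never both).
    """

    values: np.ndarray
    missing: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    meta: list[ProteinMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n_prot, n_samp = self.values.shape
        if self.missing.shape != self.values.shape:
            raise ValueError("values and missing mask shapes differ")
        if len(self.protein_ids) != n_prot or len(self.meta) != n_prot:
            raise ValueError("protein id / meta length does not match matrix")
        if len(self.sample_ids) != n_samp:
            raise ValueError("sample id length does not match matrix")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample ids")
        if len(set(self.protein_ids)) != n_prot:
            raise ValueError("duplicate protein ids")
        finite = np.isfinite(self.values)
        if np.any(finite & self.missing) or np.any(~finite & ~self.missing):
            raise ValueError("missing mask inconsistent with non-finite cells")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def valid_counts(self) -> np.ndarray:
        """Number of non-missing cells per protein."""
        return (~self.missing).sum(axis=1)

    def take_rows(self, index: np.ndarray) -> "LfqMatrix":
        index = np.asarray(index)
        return LfqMatrix(
            values=self.values[index],
            missing=self.missing[index],
            protein_ids=[self.protein_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            meta=[self.meta[i] for i in index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )


@dataclass
class SampleDesign:
    """Per-sample metadata: biological unit, group label, technical replicate."""

    table: pd.DataFrame  # columns: sample_id, biounit_id, group, tech_rep

    def __post_init__(self) -> None:
        required = ["sample_id", "biounit_id", "group", "tech_rep"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise FormatError(f"design table lacks columns: {missing_cols}")
        t = self.table[required].copy()
        t["tech_rep"] = t["tech_rep"].astype(int)
        if (t["tech_rep"] < 1).any():
            raise ValueError("tech_rep must be >= 1")
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise ValueError(f"duplicate sample_id in design: {dups}")
        pair_dup = t.duplicated(subset=["biounit_id", "tech_rep"])
        if pair_dup.any():
            bad = t.loc[pair_dup, ["biounit_id", "tech_rep"]].values.tolist()
            raise ValueError(f"duplicate (biounit_id, tech_rep) pairs: {bad}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def samples_in_group(self, group: str) -> list[str]:
        if group not in set(self.table["group"]):
            raise KeyError(f"unknown group label: {group!r}")
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleDesign(keep.reset_index(drop=True))


@dataclass
class PrmTable:
    """Long-format PRM transition areas: one row per fragment ion."""

    table: pd.DataFrame  # columns: sample_id, peptide, label, fragment, area

    def __post_init__(self) -> None:
        required = ["sample_id", "peptide", "label", "fragment", "area"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise FormatError(f"PRM table lacks columns: {missing_cols}")
        t = self.table[required].copy()
        t["area"] = t["area"].astype(float)
        bad_label = ~t["label"].isin(PRM_LABELS)
        if bad_label.any():
            rows = t.index[bad_label].tolist()
            raise ValueError(
                f"unknown isotope label(s) {sorted(set(t.loc[bad_label, 'label']))} "
                f"in rows {rows}; expected one of {sorted(PRM_LABELS)}"
            )
        if (t["area"] < 0).any():
            rows = t.index[t["area"] < 0].tolist()
            raise ValueError(f"negative transition areas in rows {rows}")
        frag_counts = t.groupby(["sample_id", "peptide", "label"]).size()
        if (frag_counts > 10).any():
            bad = frag_counts[frag_counts > 10].index.tolist()
            raise ValueError(f"more than 10 fragment rows for keys {bad}")
        self.table = t.reset_index(drop=True)

    @property
    def peptides(self) -> list[str]:
        return sorted(self.table["peptide"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["sample_id"]))


def _flag_column(df: pd.DataFrame, name: str) -> np.ndarray:
    """Any non-empty cell means flagged; an absent column means all false."""
    if name not in df.columns:
        return np.zeros(len(df), dtype=bool)
    col = df[name]
    return np.array(
        [bool(str(v).strip()) and str(v).strip().lower() != "nan" for v in col]
    )


def read_protein_groups(
    path: str | Path,
    intensity_prefix: str = DEFAULT_INTENSITY_PREFIX,
    log_base2: bool = True,
) -> LfqMatrix:
    """Read a MaxQuant-dialect proteinGroups table into an :class:`LfqMatrix`.

    Intensity columns are ``<intensity_prefix><sample_id>``. Zero or empty
    intensities denote non-quantified cells and become missing. Raw
    intensities are log2-transformed unless ``log_base2`` is off.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    raw_int = [c for c in header if c.startswith(intensity_prefix)]
    if len(set(raw_int)) != len(raw_int):
        dups = sorted({c for c in raw_int if raw_int.count(c) > 1})
        raise FormatError(f"duplicate intensity sample columns in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    int_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not int_cols:
        raise FormatError(
            f"no intensity columns with prefix {intensity_prefix!r} in {path}"
        )
    sample_ids = [c[len(intensity_prefix):] for c in int_cols]
    if COL_MAJORITY_IDS not in df.columns:
        raise FormatError(f"missing column {COL_MAJORITY_IDS!r} in {path}")

    raw = np.empty((len(df), len(int_cols)), dtype=float)
    for j, c in enumerate(int_cols):
        col = df[c].astype(str).str.strip().replace("", "0")
        raw[:, j] = col.astype(float)
    missing = raw <= 0
    values = np.where(missing, np.nan, raw)
    if log_base2:
        values = np.where(missing, np.nan, np.log2(np.where(missing, 1.0, raw)))

    is_rev = _flag_column(df, COL_REVERSE)
    is_con = _flag_column(df, COL_CONTAMINANT)
    by_site = _flag_column(df, COL_ONLY_BY_SITE)
    gene_col = (
        df[COL_GENE_NAMES] if COL_GENE_NAMES in df.columns else [""] * len(df)
    )

    protein_ids, meta = [], []
    for i in range(len(df)):
        majority = str(df[COL_MAJORITY_IDS].iloc[i]).strip()
        pid = majority.split(";")[0].strip()
        if not pid:
            raise FormatError(f"empty protein id in row {i} of {path}")
        genes = tuple(
            g.strip() for g in str(gene_col[i] if isinstance(gene_col, list)
                                   else gene_col.iloc[i]).split(";") if g.strip()
        )
        protein_ids.append(pid)
        meta.append(
            ProteinMeta(
                protein_id=pid,
                gene_symbols=genes,
                is_reverse=bool(is_rev[i]),
                is_contaminant=bool(is_con[i]),
                only_by_site=bool(by_site[i]),
            )
        )
    if len(set(protein_ids)) != len(protein_ids):
        seen, dups = set(), []
        for p in protein_ids:
            if p in seen:
                dups.append(p)
            seen.add(p)
        raise FormatError(f"duplicate protein ids in {path}: {sorted(set(dups))}")
    return LfqMatrix(values, missing, protein_ids, sample_ids, meta)


def write_protein_groups(
    m: LfqMatrix,
    path: str | Path,
    intensity_prefix: str = DEFAULT_INTENSITY_PREFIX,
    log_base2: bool = True,
) -> None:
    """Write an :class:`LfqMatrix` back to the proteinGroups dialect.

    The inverse of :func:`read_protein_groups`: log2 values are written as raw
    intensities (2**x) and missing cells as 0.
    """
    out = {}
    out[COL_MAJORITY_IDS] = [mt.protein_id for mt in m.meta]
    out[COL_GENE_NAMES] = [";".join(mt.gene_symbols) for mt in m.meta]
    out[COL_REVERSE] = ["+" if mt.is_reverse else "" for mt in m.meta]
    out[COL_CONTAMINANT] = ["+" if mt.is_contaminant else "" for mt in m.meta]
    out[COL_ONLY_BY_SITE] = ["+" if mt.only_by_site else "" for mt in m.meta]
    vals = np.power(2.0, m.values) if log_base2 else m.values
    for j, s in enumerate(m.sample_ids):
        col = np.where(m.missing[:, j], 0.0, vals[:, j])
        out[intensity_prefix + s] = [format(v, ".12g") for v in col]
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def filter_flagged(m: LfqMatrix) -> LfqMatrix:
    """Drop decoy, potential-contaminant and only-identified-by-site rows."""
    keep = np.array([not mt.flagged for mt in m.meta])
    return m.take_rows(np.flatnonzero(keep))


def apply_min_valid_filter(m: LfqMatrix, min_valid: int = 6) -> LfqMatrix:
    """Keep proteins with at least ``min_valid`` quantified cells overall."""
    if min_valid < 0:
        raise ValueError("min_valid must be >= 0")
    if min_valid > m.n_samples:
        logger.warning(
            "min_valid=%d exceeds sample count %d; result may be empty",
            min_valid, m.n_samples,
        )
    keep = m.valid_counts() >= min_valid
    return m.take_rows(np.flatnonzero(keep))


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    known = {"sample_id", "biounit_id", "group", "tech_rep"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.info("ignoring unknown design columns: %s", extra)
    if "tech_rep" not in df.columns:
        df["tech_rep"] = 1
    return SampleDesign(df)


def write_design(d: SampleDesign, path: str | Path) -> None:
    d.table.to_csv(path, sep="\t", index=False)


class MatrisomeMap(dict):
    """Uppercase gene symbol -> (division, category) lookup."""

    def divisions(self) -> set[str]:
        return {div for div, _ in self.values()}


def read_matrisome(path: str | Path) -> MatrisomeMap:
    """Read a matrisome annotation table (gene_symbol, division, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_symbol", "division", "category"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise FormatError(f"matrisome table lacks columns: {missing_cols}")
    if len(df) == 0:
        raise FormatError(f"empty matrisome table: {path}")
    mm = MatrisomeMap()
    for _, row in df.iterrows():
        sym = str(row["gene_symbol"]).strip().upper()
        if not sym:
            continue
        if sym in mm:
            logger.warning("duplicate matrisome symbol %s; keeping first", sym)
            continue
        mm[sym] = (str(row["division"]).strip(), str(row["category"]).strip())
    return mm


def packaged_matrisome() -> MatrisomeMap:
    """The small matrisome annotation table shipped with the package."""
    with resources.as_file(
        resources.files("fibroprot.data").joinpath("matrisome_mini.tsv")
    ) as p:
        return read_matrisome(p)


def read_prm_table(path: str | Path) -> PrmTable:
    """Read a Skyline-style long-format transition report (TSV or CSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "area" in df.columns:
        df["area"] = df["area"].astype(float)
    return PrmTable(df)


def write_prm_table(t: PrmTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = t.table.copy()
    out["area"] = [format(v, ".12g") for v in out["area"]]
    out.to_csv(path, sep=sep, index=False)
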