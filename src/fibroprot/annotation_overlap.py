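"""Cross-species overlap, matrisome annotation, clustering and PCA plumbing.

Mouse and human significant-protein sets are matched on upper-cased gene
symbols (protein groups with multiple gene names contribute every symbol).
Heatmap row ordering uses agglomerative clustering with the Pearson
correlation distance d = 1 - r on pairwise-complete cells; PCA projects
samples onto the first two components of the row-standardized matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .ingest import MatrisomeMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    n_set_a: int
    n_set_b: int
    n_common: int
    common_symbols: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_set_a": self.n_set_a,
            "n_set_b": self.n_set_b,
            "n_common": self.n_common,
            "common_symbols": list(self.common_symbols),
        }


def canonical_symbol(s: str) -> str:
    """Trimmed, upper-cased gene symbol (split multi-symbol strings upstream)."""
    out = s.strip().upper()
    if not out:
        raise ValueError("empty gene symbol")
    return out


def overlap_significant(a: Iterable[str], b: Iterable[str]) -> OverlapResult:
    """Exact intersection of two canonicalized symbol sets (Venn counts)."""
    sa, sb = set(a), set(b)
    common = sorted(sa & sb)
    return OverlapResult(len(sa), len(sb), len(common), tuple(common))


def annotate_matrisome(
    symbols: Iterable[str], mm: MatrisomeMap
) -> dict[str, tuple[str, str] | None]:
    """Look up matrisome division/category per symbol; None when unannotated."""
    out = {s: mm.get(s) for s in symbols}
    n_hit = sum(v is not None for v in out.values())
    logger.info("matrisome annotation: %d/%d symbols annotated", n_hit, len(out))
    return out


def pairwise_complete_pearson(values: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation over cells finite in both rows."""
    n = values.shape[0]
    r = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(values[i]) & np.isfinite(values[j])
            if both.sum() < 3:
                raise ValueError(
                    f"rows {i} and {j} share fewer than 3 finite cells"
                )
            xi, xj = values[i, both], values[j, both]
            sxi, sxj = xi.std(), xj.std()
            if sxi == 0 or sxj == 0:
                raise ValueError(f"constant row encountered ({i} or {j})")
            r[i, j] = r[j, i] = np.corrcoef(xi, xj)[0, 1]
    return r


def pearson_hclust(values: np.ndarray, method: str = "average") -> np.ndarray:
    """Linkage matrix for rows under d = 1 - Pearson r."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    counts = np.isfinite(values).sum(axis=1)
    if (counts < 3).any():
        bad = np.flatnonzero(counts < 3).tolist()
        raise ValueError(f"rows with < 3 finite values: {bad}")
    with np.errstate(invalid="ignore"):
        stds = np.nanstd(values, axis=1)
    if (stds == 0).any():
        bad = np.flatnonzero(stds == 0).tolist()
        raise ValueError(f"constant rows cannot be clustered: {bad}")
    dist = 1.0 - pairwise_complete_pearson(values)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return linkage(squareform(dist, checks=False), method=method)


def pearson_hclust_order(
    values: np.ndarray, method: str = "average"
) -> np.ndarray:
    """Leaf order for heatmap display from Pearson-distance clustering."""
    return np.asarray(leaves_list(pearson_hclust(values, method=method)))


def pca_scores(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores on the first two PCs of the standardized protein matrix.

    ``values`` is protein x sample; proteins with any missing cell are
    dropped (logged). Each retained protein is centred and scaled to unit
    variance across samples before the samples are projected.

    Returns (scores: sample x 2, explained_variance_fraction: length-2).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 3:
        raise ValueError("PCA requires >= 3 samples")
    complete = np.isfinite(values).all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("PCA: dropping %d proteins with missing cells", n_drop)
    x = values[complete]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 complete proteins retained for PCA")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    x = (x[keep] - mu[keep]) / sd[keep]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 variable proteins retained for PCA")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(x.T)  # samples as observations
    return scores, pca.explained_variance_ratio_
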