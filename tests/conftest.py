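import numpy as np
import pytest

from fibroprot.ingest import LfqMatrix, ProteinMeta


def make_matrix(values, sample_ids=None, missing=None, flags=None, genes=None):
    """Build an LfqMatrix from a 2-D array; NaN cells become missing."""
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(s)]
    if missing is None:
        missing = ~np.isfinite(values)
    flags = flags or {}
    meta = []
    for i in range(n):
        f = flags.get(i, {})
        meta.append(ProteinMeta(
            protein_id=f"P{i + 1:04d}",
            gene_symbols=(genes[i],) if genes else (f"GENE{i + 1}",),
            **f,
        ))
    return LfqMatrix(values, missing, [m.protein_id for m in meta],
                     list(sample_ids), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
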