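import numpy as np
import pytest

from screqtl import (
    AlleleCountRecord, AlleleCountTable, ExpressionMatrix, SnvLocus,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_allele_table(rng, n_loci=10, n_cells=5, max_count=30) -> AlleleCountTable:
    """A random long-format allele-count table with unique (locus, cell) keys."""
    records = []
    for i in range(n_loci):
        locus = SnvLocus("chr1", 100 + i * 10, "A", "G")
        for j in range(n_cells):
            if rng.random() < 0.7:
                records.append(AlleleCountRecord(
                    locus, f"CELL{j:03d}",
                    int(rng.integers(0, max_count)),
                    int(rng.integers(0, max_count)),
                ))
    return AlleleCountTable.from_records(records)


@pytest.fixture
def small_table(rng):
    return random_allele_table(rng, n_loci=8, n_cells=6)


@pytest.fixture
def small_expression(rng):
    genes = [f"G{i}" for i in range(20)]
    barcodes = [f"C{j}" for j in range(12)]
    counts = rng.integers(0, 50, size=(20, 12))
    return ExpressionMatrix(genes, barcodes, counts)
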