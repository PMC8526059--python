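import numpy as np
import pandas as pd
import pytest

from sweepset.haplotypes import HaplotypeMatrix


def make_hap(rows: list[str], spacing_cm: float = 0.02) -> HaplotypeMatrix:
    """Build a HaplotypeMatrix from strings like '0101'."""
    alleles = np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
    n = alleles.shape[1]
    return HaplotypeMatrix(
        alleles=alleles,
        positions_bp=np.arange(n) * 1000 + 1000,
        positions_cM=np.arange(n) * spacing_cm,
    )


@pytest.fixture
def toy_genes() -> pd.DataFrame:
    """Six genes on two chromosomes with simple round coordinates."""
    rows = [
        ("gA", "chr1", 90_000, 110_000, True, 6),
        ("gB", "chr1", 390_000, 410_000, False, 0),
        ("gC", "chr1", 990_000, 1_010_000, False, 0),
        ("gD", "chr2", 90_000, 110_000, True, 2),
        ("gE", "chr2", 490_000, 510_000, False, 0),
        ("gF", "chr2", 2_090_000, 2_110_000, False, 0),
    ]
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "span_start", "span_end", "is_focal", "n_disease_variants"],
    )
    df["center"] = (df["span_start"] + df["span_end"]) / 2.0
    return df[
        ["gene_id", "chrom", "span_start", "span_end", "center", "is_focal", "n_disease_variants"]
    ]
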