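import numpy as np
import pandas as pd
import pytest

from apchits.cna import AmpliconCountMatrix
from apchits.gene_model import default_apc_model


@pytest.fixture(scope="session")
def apc_model():
    return default_apc_model()


@pytest.fixture()
def tiny_matrix():
    """Two pools x three samples with hand-enterable counts."""
    amplicons = pd.DataFrame({
        "amplicon_id": ["a1", "a2", "a3", "a4"],
        "gene": ["APC", "APC", "KRAS", "KRAS"],
        "pool_id": ["pool1", "pool1", "pool2", "pool2"],
        "chrom": ["chr5", "chr5", "chr12", "chr12"],
        "start": [100, 300, 100, 300],
        "end": [250, 450, 250, 450],
    })
    counts = pd.DataFrame(
        {"N1": [100, 200, 50, 150], "N2": [110, 190, 60, 140], "T1": [50, 100, 55, 145]},
        index=amplicons["amplicon_id"],
    )
    return AmpliconCountMatrix(
        amplicons=amplicons, counts=counts,
        sample_roles={"N1": "normal_reference", "N2": "normal_reference", "T1": "tumor"},
    )


def make_ratio_matrix(log2_ratios, rng_label="sim"):
    """One-gene matrix whose tumor/normal scaled ratio equals 2**log2_ratios.

    Used to drive the CNA caller with exactly controlled per-amplicon ratios:
    the normal has uniform within-pool fractions and the tumor's fractions
    are scaled by the requested ratios (then renormalized by the caller's
    own pool normalization being bypassed — scaled values are passed direct).
    """
    log2_ratios = np.asarray(log2_ratios, dtype=float)
    n = len(log2_ratios)
    amplicons = pd.DataFrame({
        "amplicon_id": [f"amp{i}" for i in range(n)],
        "gene": ["APC"] * n,
        "pool_id": ["pool1"] * n,
        "chrom": ["chr5"] * n,
        "start": np.arange(n) * 1000,
        "end": np.arange(n) * 1000 + 150,
    })
    ref = np.full(n, 1.0 / n)
    tum = ref * 2.0 ** log2_ratios
    scaled = pd.DataFrame({"N1": ref, "T1": tum}, index=amplicons["amplicon_id"])
    counts = pd.DataFrame(
        (scaled * 10000).round().astype(int), index=amplicons["amplicon_id"]
    )
    matrix = AmpliconCountMatrix(
        amplicons=amplicons, counts=counts,
        sample_roles={"N1": "normal_reference", "T1": "tumor"},
    )
    return matrix, scaled
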