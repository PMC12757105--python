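"""Gene-level copy-number calling from amplicon read counts and VAF-based
allelic-imbalance / postzygotic-mosaicism inference.

Multiplex amplicon panels sequence each gene with a handful of PCR amplicons
distributed over one or more primer pools.  Copy-number change shifts the
relative representation of a gene's amplicons within their pools, so counts
are first converted to within-pool fractions per sample, then expressed as
log2 ratios against the mean of the normal-reference samples, and a gene's
ratios are tested against zero with a one-sample t-test.

Allelic imbalance at a heterozygous germline variant is read directly off
its VAF: a binomial test against the heterozygous expectation of 0.5 flags
increased/decreased VAF in tumors and, in blood or normal tissue, a VAF well
below 0.5 signals a postzygotic (mosaic) origin of the variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .variants import VariantCall

__all__ = [
    "AmpliconCountMatrix",
    "CNACall",
    "AllelicState",
    "normalize_by_pool",
    "gene_cna_call",
    "vaf_allelic_state",
]

SAMPLE_ROLES = ("tumor", "normal_reference")
CNA_CALLS = ("loss", "neutral", "gain", "no_call")
ALLELIC_STATES = ("balanced", "increased", "decreased", "postzygotic_mosaic", "indeterminate")


@dataclass
class AmpliconCountMatrix:
    """Raw amplicon x sample read counts plus the panel annotation.

    ``amplicons`` columns: amplicon_id, gene, pool_id, chrom, start, end
    (genomic interval 0-based half-open, BED convention).  ``counts`` is
    indexed by amplicon_id with one column per sample.
    """

    amplicons: pd.DataFrame
    counts: pd.DataFrame
    sample_roles: Dict[str, str]

    def __post_init__(self):
        required = {"amplicon_id", "gene", "pool_id"}
        missing = required - set(self.amplicons.columns)
        if missing:
            raise ValueError(f"amplicon annotation missing columns: {sorted(missing)}")
        if list(self.counts.index) != list(self.amplicons["amplicon_id"]):
            self.counts = self.counts.loc[self.amplicons["amplicon_id"]]
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        for s, role in self.sample_roles.items():
            if role not in SAMPLE_ROLES:
                raise ValueError(f"unknown sample role {role!r} for {s}")

    @property
    def normal_ids(self) -> List[str]:
        return [s for s, r in self.sample_roles.items() if r == "normal_reference"]

    def gene_amplicons(self, gene: str) -> pd.DataFrame:
        sub = self.amplicons[self.amplicons["gene"] == gene]
        if "start" in sub.columns:
            sub = sub.sort_values(["start"], kind="stable")
        return sub


@dataclass
class CNACall:
    gene: str
    sample_id: str
    n_amplicons: int
    mean_log2_ratio: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    call: str
    reason: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if self.call not in CNA_CALLS:
            raise ValueError(f"unknown CNA call {self.call!r}")


@dataclass
class AllelicState:
    variant_key: Tuple[str, str]
    sample_id: str
    vaf: float
    depth: int
    state: str
    p_value: float

    def __post_init__(self):
        if self.state not in ALLELIC_STATES:
            raise ValueError(f"unknown allelic state {self.state!r}")


# ---------------------------------------------------------------------------
# normalization

def normalize_by_pool(
    matrix: AmpliconCountMatrix, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Scale counts to within-pool fractions per sample.

    entry(a, s) = (count(a, s) + pc) / sum over amplicons in pool(a) of
    (count(., s) + pc); within each (pool, sample) the entries sum to 1.
    An all-zero pool in a sample degrades to the uniform fraction (the
    pseudocount dominates) and triggers a warning.
    """
    counts = matrix.counts.astype(float)
    pools = matrix.amplicons.set_index("amplicon_id")["pool_id"]
    shifted = counts + pseudocount
    out = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for pool_id, idx in pools.groupby(pools).groups.items():
        block = shifted.loc[idx]
        totals = block.sum(axis=0)
        zero_raw = counts.loc[idx].sum(axis=0) == 0
        if zero_raw.any():
            bad = list(counts.columns[zero_raw])
            warnings.warn(
                f"pool {pool_id!r} has zero total reads in samples {bad}; "
                "fractions fall back to uniform",
                stacklevel=2,
            )
        if (totals == 0).any():
            raise ValueError(
                f"pool {pool_id!r} has zero total with pseudocount disabled"
            )
        out.loc[idx] = block / totals
    return out


# ---------------------------------------------------------------------------
# gene-level CNA calling

def _one_sample_t(values: np.ndarray) -> Tuple[float, int, float]:
    """Two-sided one-sample t-test of ``values`` against mean 0.

    Returns (t, df, p); degenerate variance yields (0, df, 1) by convention.
    """
    n = len(values)
    df = n - 1
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return 0.0, df, 1.0
    t = values.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(min(p, 1.0))


def gene_cna_call(
    scaled: pd.DataFrame,
    matrix: AmpliconCountMatrix,
    gene: str,
    sample_id: str,
    normal_ids: Optional[Sequence[str]] = None,
    window: Optional[int] = None,
    alpha: float = 0.05,
    loss_log2: float = -0.32,
    gain_log2: float = 0.26,
    min_amplicons: int = 4,
) -> CNACall:
    """Call loss/neutral/gain for one gene in one sample.

    Per amplicon, log2 ratio = log2(scaled(a, sample) / mean over normals of
    scaled(a, .)).  With ``window=None`` all of the gene's amplicons form one
    group; otherwise each sliding window of ``window`` genomically ordered
    amplicons is tested and the most significant window is reported.  A call
    requires both significance (p < alpha) and an effect-size guard on the
    mean log2 ratio (<= ``loss_log2`` for loss, >= ``gain_log2`` for gain).
    """
    if normal_ids is None:
        normal_ids = matrix.normal_ids
    if not normal_ids:
        raise ValueError("at least one normal_reference sample is required")
    amp = matrix.gene_amplicons(gene)
    ids = list(amp["amplicon_id"])
    if len(ids) < min_amplicons:
        return CNACall(gene, sample_id, len(ids), float("nan"), float("nan"),
                       max(len(ids) - 1, 0), 1.0, "no_call",
                       reason=f"fewer than {min_amplicons} amplicons")
    ref = scaled.loc[ids, list(normal_ids)].mean(axis=1)
    ratios = np.log2(scaled.loc[ids, sample_id].to_numpy() / ref.to_numpy())

    if window is None or window >= len(ratios):
        groups = [ratios]
    else:
        if window < 2:
            raise ValueError("window must be >= 2")
        groups = [ratios[i:i + window] for i in range(len(ratios) - window + 1)]

    best = None  # (p, t, df, mean, n, degenerate)
    for g in groups:
        g = np.asarray(g)
        t, df, p = _one_sample_t(g)
        cand = (p, t, df, float(g.mean()), len(g), g.std(ddof=1) == 0)
        if best is None or cand[0] < best[0]:
            best = cand
    p, t, df, mean, n, degenerate = best

    if degenerate:
        return CNACall(gene, sample_id, n, mean, 0.0, df, 1.0, "no_call",
                       reason="degenerate variance")
    call = "neutral"
    if p < alpha and mean <= loss_log2:
        call = "loss"
    elif p < alpha and mean >= gain_log2:
        call = "gain"
    return CNACall(gene, sample_id, n, mean, t, df, p, call)


# ---------------------------------------------------------------------------
# allelic state from VAF

def vaf_allelic_state(
    variant: VariantCall,
    sample_role: str = "tumor",
    alpha: float = 0.05,
    mosaic_vaf_max: float = 0.4,
) -> AllelicState:
    """Classify a germline variant's VAF against the heterozygous 0.5.

    Exact two-sided binomial test of round(vaf * depth) successes out of
    depth against p = 0.5.  In tumor tissue a significant deviation is
    ``increased`` (VAF > 0.5, e.g. loss of the wild-type allele) or
    ``decreased`` (VAF < 0.5, e.g. loss of the mutant allele or low purity).
    In blood/normal tissue a significant VAF below ``mosaic_vaf_max`` flags a
    postzygotic (mosaic) variant.
    """
    if variant.depth <= 0:
        return AllelicState(variant.key, variant.sample_id, variant.vaf, variant.depth,
                            "indeterminate", 1.0)
    k = int(round(variant.vaf * variant.depth))
    p = float(stats.binomtest(k, variant.depth, 0.5).pvalue)
    state = "balanced"
    if sample_role in {"normal", "normal_reference", "blood"}:
        if p < alpha and variant.vaf < mosaic_vaf_max:
            state = "postzygotic_mosaic"
    else:
        if p < alpha:
            state = "increased" if variant.vaf > 0.5 else "decreased"
    return AllelicState(variant.key, variant.sample_id, variant.vaf, variant.depth,
                        state, p)
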