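"""Contingency-table summaries and the cohort tests: Pearson chi-square
(uncorrected), Fisher's exact test and Mood's median test.

No continuity correction is applied anywhere: the uncorrected Pearson
statistic is what reproduces the cohort comparisons this package targets.
Reported tables round p-values to three decimals; full precision is kept on
the result objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .variants import HitProfile, PatientRecord

__all__ = [
    "ContingencyTable",
    "TestResult",
    "build_contingency",
    "pearson_chi2",
    "fisher_exact",
    "mood_median_test",
    "genotype_cross_tab",
    "GERMLINE_CATEGORIES",
]

METHODS = ("pearson_chi2", "fisher_exact", "mood_median")


@dataclass
class ContingencyTable:
    row_labels: List[str]
    col_labels: List[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class TestResult:
    method: str
    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if (self.df is not None) != (self.method == "pearson_chi2"):
            raise ValueError("df present iff method is pearson_chi2")

    @property
    def p_rounded(self) -> float:
        return round(self.p_value, 3)


def build_contingency(
    records: Sequence[Mapping],
    row_factor: str,
    col_factor: str,
    row_order: Optional[Sequence[str]] = None,
    col_order: Optional[Sequence[str]] = None,
    exclude: Optional[Mapping[str, Sequence[str]]] = None,
) -> ContingencyTable:
    """Cross-tabulate two categorical fields of a record sequence.

    ``exclude`` maps factor name -> levels dropped before tabulation (e.g.
    location "unknown" is listed outside the tested cells).  Levels appear in
    the declared vocabulary order when given, else in order of appearance.
    """
    exclude = exclude or {}
    rows, cols = [], []
    for rec in records:
        r, c = str(rec[row_factor]), str(rec[col_factor])
        if r in exclude.get(row_factor, ()) or c in exclude.get(col_factor, ()):
            continue
        rows.append(r)
        cols.append(c)
    if not rows:
        raise ValueError("contingency table empty after exclusions")
    row_order = list(row_order) if row_order else list(dict.fromkeys(rows))
    col_order = list(col_order) if col_order else list(dict.fromkeys(cols))
    counts = np.zeros((len(row_order), len(col_order)), dtype=int)
    for r, c in zip(rows, cols):
        if r in row_order and c in col_order:
            counts[row_order.index(r), col_order.index(c)] += 1
    if len(row_order) == 1 or len(col_order) == 1:
        warnings.warn(
            "single-level factor: table is 1 x k (goodness-of-fit only)",
            stacklevel=2,
        )
    return ContingencyTable(row_order, col_order, counts)


def _drop_zero_margins(counts: np.ndarray) -> np.ndarray:
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns before chi-square",
                      stacklevel=3)
    return counts[keep_r][:, keep_c]


def pearson_chi2(table: ContingencyTable | Sequence[Sequence[int]]) -> TestResult:
    """Uncorrected Pearson chi-square test of independence on an r x c table."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = _drop_zero_margins(np.asarray(counts, dtype=float))
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2 x 2 table after dropping "
                         "zero margins")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult("pearson_chi2", float(p), float(stat), int(df))


def fisher_exact(table: ContingencyTable | Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2 x 2 table.

    p is the sum of hypergeometric probabilities, over tables with the same
    margins, of all tables no more probable than the observed one.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact supports 2 x 2 only; use pearson_chi2 for r x c")
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return TestResult("fisher_exact", float(min(p, 1.0)))


def mood_median_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Mood's median test on two or more groups of a continuous variable.

    Observations are classified above vs at-or-below the pooled grand median
    and the resulting 2 x k table is tested — by Fisher's exact test when it
    is 2 x 2 with any expected count below 5, else by Pearson chi-square.
    All-identical data yields p = 1 with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    nonempty = [g for g in groups if g.size]
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(nonempty)
    if pooled.size < 2:
        raise ValueError("pooled sample size must be >= 2")
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical; median test is degenerate",
                      stacklevel=2)
        return TestResult("mood_median", 1.0)
    med = float(np.median(pooled))
    above = np.array([(g > med).sum() for g in nonempty])
    below = np.array([(g <= med).sum() for g in nonempty])
    counts = np.vstack([above, below])
    if (counts.sum(axis=0) == 0).any():
        counts = counts[:, counts.sum(axis=0) > 0]
    if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
        warnings.warn("median split degenerate; p = 1", stacklevel=2)
        return TestResult("mood_median", 1.0)
    if counts.shape[1] == 2:
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
        if (expected < 5).any():
            inner = fisher_exact(counts)
            return TestResult("mood_median", inner.p_value)
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult("mood_median", float(p))


# ---------------------------------------------------------------------------
# germline x somatic 20AAR cross-tabulation

#: Default germline categories: retained-20AAR count -> row label.
GERMLINE_CATEGORIES: Dict[object, str] = {0: "5'-0", 5: "3'-5", "deletion": "whole_APC_deletion"}
SOMATIC_20AAR_BINS = ("0", "1", "2", "3")


@dataclass
class CrossTabResult:
    table: ContingencyTable
    n_excluded: int


def genotype_cross_tab(
    patients: Mapping[str, PatientRecord],
    profiles_by_polyp: Mapping[str, Tuple[str, HitProfile]] | Sequence[Tuple[str, HitProfile]],
    categories: Optional[Mapping[object, str]] = None,
) -> CrossTabResult:
    """Cross-tabulate germline category x somatic retained-20AAR count.

    One tally per somatic APC mutation (a polyp with two somatic hits
    contributes two).  Rows come from the patient's germline retained-20AAR
    category (default: 0 retained = 5' variant, 5 retained = 3' variant, or
    whole-gene deletion); somatic retained counts are binned 0/1/2/3+.
    Mutations of patients with an unclassifiable germline are excluded and
    counted.
    """
    categories = dict(categories or GERMLINE_CATEGORIES)
    pairs = (
        profiles_by_polyp.values()
        if isinstance(profiles_by_polyp, Mapping)
        else profiles_by_polyp
    )
    row_labels = list(dict.fromkeys(categories.values()))
    counts = np.zeros((len(row_labels), len(SOMATIC_20AAR_BINS)), dtype=int)
    excluded = 0
    for patient_id, profile in pairs:
        patient = patients[patient_id]
        if not patient.has_germline_hit:
            excluded += profile.somatic_hits
            continue
        if patient.germline_status == "whole_gene_deletion":
            key: object = "deletion"
        else:
            key = profile.retained_20aars_germline
        label = categories.get(key)
        if label is None:
            excluded += profile.somatic_hits
            continue
        for retained in profile.retained_20aars_somatic:
            col = min(int(retained), 3)
            counts[row_labels.index(label), col] += 1
    return CrossTabResult(
        ContingencyTable(row_labels, list(SOMATIC_20AAR_BINS), counts), excluded
    )
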