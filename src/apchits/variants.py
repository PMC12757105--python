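"""Per-polyp variant filtering, germline/somatic partitioning and APC hit counting.

A polyp's APC genotype is decomposed into hits: the inherited (germline)
hit — a pathogenic small variant or a whole-gene deletion — plus somatic
small-variant hits and somatic copy-number-loss hits detected in the lesion.
Two hits inactivate both alleles; a third alteration on top of a germline
hit defines the three-hit genotype.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .gene_model import (
    GeneModel,
    VariantEffect,
    in_mcr,
    parse_variant_effect,
    retained_20aars,
    retained_20aars_for_effect,
)

__all__ = [
    "VariantCall",
    "PatientRecord",
    "PolypRecord",
    "HitProfile",
    "filter_by_vaf",
    "partition_germline_somatic",
    "count_apc_hits",
    "mcr_rate",
    "mutation_class_tally",
    "MutationTally",
    "screen_mutyh_germline",
]

ORIGINS = ("germline", "somatic", "unknown")
COHORTS = ("FAP", "sporadic")
GERMLINE_STATUSES = ("pathogenic_variant", "whole_gene_deletion", "none_detected")
PHENOTYPES = ("AFAP", "sparse", "profuse", "not_applicable")
HISTOLOGIES = ("low_grade", "high_grade", "carcinoma")
LOCATIONS = ("proximal", "distal", "rectum", "unknown")


@dataclass
class VariantCall:
    """One called small variant in one sample."""

    sample_id: str
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    vaf: float = 0.0
    depth: int = 0
    origin: str = "unknown"
    patient_id: str = ""
    effect: Optional[VariantEffect] = None
    pathogenic: bool = True

    def __post_init__(self):
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def key(self) -> Tuple[str, str]:
        """Identity of the variant irrespective of sample: (gene, hgvs_c)."""
        return (self.gene, self.hgvs_c)

    def with_effect(self) -> "VariantCall":
        """Return a copy with ``effect`` parsed from the HGVS notations."""
        if self.effect is not None:
            return self
        return replace(self, effect=parse_variant_effect(self.hgvs_p, self.hgvs_c))


@dataclass
class PatientRecord:
    patient_id: str
    cohort: str
    pedigree_id: str = ""
    sex: str = ""
    germline_status: str = "none_detected"
    germline_variant: Optional[VariantCall] = None
    phenotype: str = "not_applicable"
    mosaic: bool = False
    age: Optional[float] = None

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.germline_status not in GERMLINE_STATUSES:
            raise ValueError(f"unknown germline status {self.germline_status!r}")
        if (self.germline_variant is not None) != (
            self.germline_status == "pathogenic_variant"
        ):
            raise ValueError(
                "germline_variant must be present iff status is pathogenic_variant"
            )
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if (self.phenotype == "not_applicable") != (self.cohort == "sporadic"):
            raise ValueError("phenotype not_applicable iff cohort is sporadic")

    @property
    def has_germline_hit(self) -> bool:
        return self.germline_status in {"pathogenic_variant", "whole_gene_deletion"}


@dataclass
class PolypRecord:
    polyp_id: str
    patient_id: str
    histology: str = "low_grade"
    location: str = "unknown"
    age_at_resection: float = 0.0
    variants: List[VariantCall] = field(default_factory=list)
    cna_calls: list = field(default_factory=list)

    def __post_init__(self):
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.age_at_resection < 0:
            raise ValueError("age_at_resection must be >= 0")


@dataclass
class HitProfile:
    """Per-polyp APC hit decomposition."""

    polyp_id: str
    germline_hit: int
    somatic_hits: int
    cna_hit: int
    somatic_in_mcr: List[bool] = field(default_factory=list)
    retained_20aars_germline: Optional[int] = None
    retained_20aars_somatic: List[int] = field(default_factory=list)

    def __post_init__(self):
        if min(self.germline_hit, self.somatic_hits, self.cna_hit) < 0:
            raise ValueError("hit counts must be >= 0")

    @property
    def total_hits(self) -> int:
        return self.germline_hit + self.somatic_hits + self.cna_hit

    @property
    def hit_bin(self) -> str:
        """Total hits binned 0/1/2/3+ for report tables."""
        return str(self.total_hits) if self.total_hits < 3 else "3"


# ---------------------------------------------------------------------------
# filtering and partitioning

def filter_by_vaf(calls: Sequence[VariantCall], vaf_min: float = 0.05) -> List[VariantCall]:
    """Keep calls with ``vaf >= vaf_min`` (inclusive cutoff), order preserved."""
    if not (0.0 <= vaf_min <= 1.0):
        raise ValueError("vaf_min must lie in [0, 1]")
    return [c for c in calls if c.vaf >= vaf_min]


def partition_germline_somatic(
    tumor_calls: Sequence[VariantCall],
    normal_calls: Optional[Sequence[VariantCall]],
    normal_vaf_min: float = 0.25,
) -> Tuple[List[VariantCall], List[VariantCall]]:
    """Split tumor calls into germline vs somatic using the matched normal.

    A tumor call whose (gene, hgvs_c) is present in the reference sample at
    VAF >= ``normal_vaf_min`` is germline; everything else is somatic.  With
    no reference sample at all the calls are returned in the germline slot
    with origin ``unknown`` and a warning — never silently as somatic.
    """
    if normal_calls is None:
        warnings.warn(
            "no matched normal sample: origins left as 'unknown'", stacklevel=2
        )
        unknown = [replace(c, origin="unknown") for c in tumor_calls]
        return unknown, []
    germ_keys = {c.key for c in normal_calls if c.vaf >= normal_vaf_min}
    germline = [replace(c, origin="germline") for c in tumor_calls if c.key in germ_keys]
    somatic = [replace(c, origin="somatic") for c in tumor_calls if c.key not in germ_keys]
    return germline, somatic


# ---------------------------------------------------------------------------
# hit counting

def count_apc_hits(
    polyp: PolypRecord,
    patient: PatientRecord,
    model: GeneModel,
    include_nontruncating: bool = True,
) -> HitProfile:
    """Compute the APC hit profile of one polyp.

    germline hit: 1 when the patient carries a pathogenic variant or a
    whole-gene deletion.  Somatic hits: distinct (by hgvs_c) somatic calls in
    the modeled gene; with ``include_nontruncating=False`` only truncating
    alleles count.  CNA hit: a somatic loss call for the gene in this polyp,
    beyond any germline whole-gene deletion (which is already the germline
    hit).  MCR membership and retained-20AAR counts are annotated per somatic
    mutation.
    """
    gene = model.gene_name
    somatic: Dict[str, VariantCall] = {}
    for call in polyp.variants:
        if call.origin != "somatic" or call.gene != gene:
            continue
        if call.hgvs_c not in somatic:
            somatic[call.hgvs_c] = call.with_effect()
    if not include_nontruncating:
        somatic = {
            k: c for k, c in somatic.items() if c.effect is not None and c.effect.is_truncating
        }

    in_mcr_flags = [in_mcr(c.effect.codon, model) for c in somatic.values()]
    retained_som = [retained_20aars_for_effect(c.effect, model) for c in somatic.values()]

    germline_hit = 1 if patient.has_germline_hit else 0
    retained_germ = None
    if patient.germline_status == "pathogenic_variant":
        gv = patient.germline_variant.with_effect()
        retained_germ = retained_20aars_for_effect(gv.effect, model)
    elif patient.germline_status == "whole_gene_deletion":
        retained_germ = 0

    cna_hit = 0
    if patient.germline_status != "whole_gene_deletion":
        for cna in polyp.cna_calls:
            if getattr(cna, "gene", None) == gene and getattr(cna, "call", None) == "loss":
                cna_hit = 1
                break

    return HitProfile(
        polyp_id=polyp.polyp_id,
        germline_hit=germline_hit,
        somatic_hits=len(somatic),
        cna_hit=cna_hit,
        somatic_in_mcr=in_mcr_flags,
        retained_20aars_germline=retained_germ,
        retained_20aars_somatic=retained_som,
    )


def mcr_rate(profiles: Iterable[HitProfile]) -> Optional[float]:
    """Fraction of somatically mutated polyps whose mutation lies in the MCR.

    Numerator: polyps with >=1 somatic APC mutation inside the MCR;
    denominator: polyps with >=1 somatic APC mutation.  Returns ``None``
    (undefined) when no polyp carries a somatic mutation.
    """
    mutated = [p for p in profiles if p.somatic_hits > 0]
    if not mutated:
        return None
    hit = sum(1 for p in mutated if any(p.somatic_in_mcr))
    return hit / len(mutated)


# ---------------------------------------------------------------------------
# mutation-class tallies and substitution spectrum

_SNV_RE = re.compile(r"^c\.\d+(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class MutationTally:
    class_counts: Counter
    spectrum: Counter
    n_spectrum_skipped: int

    @property
    def indel_count(self) -> int:
        """Insertions and/or deletions: frameshift plus in-frame indels."""
        return self.class_counts["frameshift"] + self.class_counts["inframe_indel"]


def fold_substitution(ref: str, alt: str) -> str:
    """Fold a substitution onto the pyrimidine reference (6-class spectrum)."""
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def mutation_class_tally(calls: Sequence[VariantCall]) -> MutationTally:
    """Count mutation classes and the pyrimidine-folded substitution spectrum."""
    classes: Counter = Counter({c: 0 for c in ("nonsense", "frameshift", "missense",
                                               "inframe_indel", "splice",
                                               "synonymous", "other")})
    spectrum: Counter = Counter({s: 0 for s in SPECTRUM_CLASSES})
    skipped = 0
    for call in calls:
        call = call.with_effect()
        classes[call.effect.mutation_class] += 1
        m = _SNV_RE.match(call.hgvs_c.strip())
        if m:
            spectrum[fold_substitution(m.group("ref"), m.group("alt"))] += 1
        else:
            skipped += 1
    return MutationTally(classes, spectrum, skipped)


# ---------------------------------------------------------------------------
# MUTYH germline screening

def screen_mutyh_germline(
    germline_calls_by_patient: Mapping[str, Sequence[VariantCall]],
    homozygous_vaf_min: float = 0.8,
) -> Dict[str, str]:
    """Classify each patient's MUTYH germline state: biallelic/monoallelic/none.

    Counts pathogenic-flagged MUTYH germline calls, distinct by hgvs_c; two or
    more distinct variants, or a single variant at VAF consistent with
    homozygosity (>= ``homozygous_vaf_min``), is biallelic.
    """
    out: Dict[str, str] = {}
    for patient_id, calls in germline_calls_by_patient.items():
        mutyh = {
            c.hgvs_c: c
            for c in calls
            if c.gene == "MUTYH" and c.pathogenic and c.origin in {"germline", "unknown"}
        }
        if not mutyh:
            out[patient_id] = "none"
        elif len(mutyh) >= 2 or any(c.vaf >= homozygous_vaf_min for c in mutyh.values()):
            out[patient_id] = "biallelic"
        else:
            out[patient_id] = "monoallelic"
    return out
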