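"""APC protein coordinate system and variant-position classification.

The tumor suppressor APC (2843 amino acids) is inactivated in colorectal
adenomas by truncating mutations.  Somatic truncations concentrate in the
mutation cluster region (MCR, codons 1286-1513); the number of intact
20-amino-acid beta-catenin-binding repeats (20AARs) retained by a truncated
allele calibrates residual Wnt regulation and is the quantity the two-hit
genotype analysis cross-tabulates.

All coordinates are 1-based and intervals are closed on both ends (HGVS
convention).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

__all__ = [
    "GeneModel",
    "VariantEffect",
    "HgvsParseError",
    "GeneModelError",
    "load_gene_model",
    "default_apc_model",
    "parse_variant_effect",
    "in_mcr",
    "retained_20aars",
    "classify_hit_allele",
    "MUTATION_CLASSES",
    "HIT_LABELS",
]

MUTATION_CLASSES = (
    "nonsense",
    "frameshift",
    "missense",
    "inframe_indel",
    "splice",
    "synonymous",
    "other",
)

#: Allele-level hit labels in decreasing order of severity.
HIT_LABELS = ("truncating_hit", "deletion_hit", "nontruncating_hit", "no_hit")

TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift", "splice"})


class GeneModelError(ValueError):
    """Raised when a gene model violates its structural invariants."""


class HgvsParseError(ValueError):
    """Raised when an HGVS notation cannot be parsed; names the offending token."""

    def __init__(self, token: str, message: str):
        self.token = token
        super().__init__(f"cannot parse HGVS token {token!r}: {message}")


@dataclass(frozen=True)
class GeneModel:
    """Protein-space model of a gene: length, MCR and ordered 20AAR intervals."""

    gene_name: str
    protein_length: int
    mcr: Tuple[int, int]
    repeats_20aar: Tuple[Tuple[int, int], ...]
    annotation_source: str = ""

    def __post_init__(self):
        if self.protein_length <= 0:
            raise GeneModelError("protein_length must be positive")
        intervals = [self.mcr, *self.repeats_20aar]
        for lo, hi in intervals:
            if not (1 <= lo <= hi <= self.protein_length):
                raise GeneModelError(
                    f"interval [{lo}, {hi}] outside [1, {self.protein_length}]"
                )
        reps = list(self.repeats_20aar)
        if reps != sorted(reps, key=lambda iv: iv[0]):
            raise GeneModelError("20AAR intervals must be sorted by start")
        for (_, hi_a), (lo_b, _) in zip(reps, reps[1:]):
            if lo_b <= hi_a:
                raise GeneModelError("20AAR intervals must be pairwise non-overlapping")
        if reps and not any(
            lo <= self.mcr[1] and hi >= self.mcr[0] for lo, hi in reps
        ):
            raise GeneModelError("MCR does not overlap the 20AAR region")


@dataclass(frozen=True)
class VariantEffect:
    """Protein-level consequence of a small variant.

    ``codon`` is the 1-based protein position; for nonsense and frameshift
    variants it is the truncation position (the first altered codon, not the
    downstream stop gained by a frameshift).
    """

    codon: int
    mutation_class: str
    cdna_position: Optional[int] = None

    def __post_init__(self):
        if self.codon < 1:
            raise ValueError("codon must be >= 1")
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")

    @property
    def is_truncating(self) -> bool:
        return self.mutation_class in TRUNCATING_CLASSES


# ---------------------------------------------------------------------------
# model loading

def load_gene_model(path: str | Path) -> GeneModel:
    """Load a gene model from a YAML config (key/value + interval lists)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return GeneModel(
            gene_name=str(raw["gene_name"]),
            protein_length=int(raw["protein_length"]),
            mcr=(int(raw["mcr"][0]), int(raw["mcr"][1])),
            repeats_20aar=tuple(
                (int(lo), int(hi)) for lo, hi in raw["repeats_20aar"]
            ),
            annotation_source=str(raw.get("annotation_source", "")),
        )
    except KeyError as exc:
        raise GeneModelError(f"gene model config missing key {exc}") from exc


def default_apc_model() -> GeneModel:
    """The bundled APC model (2843 aa, MCR 1286-1513, seven 20AARs)."""
    ref = resources.files("apchits").joinpath("data/apc_gene_model.yaml")
    with resources.as_file(ref) as path:
        return load_gene_model(path)


# ---------------------------------------------------------------------------
# HGVS subset parsing

# protein notations like p.Q473*, p.S1068Gfs*57, p.(M330Vfs*9), p.A123T,
# p.C520del, p.T123=
_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|"
    "Tyr|Val|Ter|Sec"
)
_P_RE = re.compile(
    rf"^p\.\(?(?P<ref>{_AA3}|[A-Z\*])(?P<pos>\d+)(?P<rest>[^)]*)\)?$"
)
# coding-DNA notations: substitutions, del, dup, ins, delins on plain coding
# positions (intronic +/- offsets and UTR */- positions are rejected)
_C_POS = r"(?P<pos>\d+)"
_C_RE = re.compile(
    rf"^c\.{_C_POS}(?:_(?P<pos2>\d+))?"
    r"(?P<op>(?:delins|del|dup|ins)(?P<seq1>[ACGTacgt]*)|"
    r"(?P<ref>[ACGTacgt])>(?P<alt>[ACGTacgt]))$"
)
_C_DELINS_RE = re.compile(
    rf"^c\.{_C_POS}(?:_(?P<pos2>\d+))?del(?P<dseq>[ACGTacgt]*)ins(?P<iseq>[ACGTacgt]+)$"
)
_C_BAD_POS_RE = re.compile(r"^c\.[\d\*\-]*[+\-\*]")


def _classify_protein_rest(rest: str, ref: str) -> str:
    rest = rest.strip()
    if rest in {"*", "Ter"}:
        return "nonsense"
    if "fs" in rest:
        return "frameshift"
    if rest == "=":
        return "synonymous"
    if rest.startswith(("del", "dup", "ins")):
        return "inframe_indel"
    if re.fullmatch(rf"(?:{_AA3}|[A-Z])", rest):
        return "missense"
    raise HgvsParseError(rest or ref, "unrecognized protein-notation suffix")


def _parse_protein(hgvs_p: str) -> Tuple[int, str]:
    m = _P_RE.match(hgvs_p.strip())
    if not m:
        raise HgvsParseError(hgvs_p, "not a supported p. notation")
    return int(m.group("pos")), _classify_protein_rest(m.group("rest"), m.group("ref"))


def _parse_cdna(hgvs_c: str) -> Tuple[int, Optional[str]]:
    """Return (cdna position, mutation class or None when indeterminable)."""
    text = hgvs_c.strip()
    if _C_BAD_POS_RE.match(text):
        raise HgvsParseError(text, "intronic/UTR cDNA positions are not supported")
    m = _C_DELINS_RE.match(text)
    if m:
        pos, pos2 = int(m.group("pos")), int(m.group("pos2") or m.group("pos"))
        removed = pos2 - pos + 1
        net = len(m.group("iseq")) - removed
        return pos, ("inframe_indel" if net % 3 == 0 else "frameshift")
    m = _C_RE.match(text)
    if not m:
        raise HgvsParseError(text, "not a supported c. notation")
    pos = int(m.group("pos"))
    if m.group("ref"):  # substitution: class depends on the protein change
        return pos, None
    pos2 = int(m.group("pos2") or pos)
    op = m.group("op")
    seq = m.group("seq1") or ""
    if op.startswith(("del", "dup")):
        length = pos2 - pos + 1 if not seq or op.startswith("dup") else len(seq)
        if op.startswith("dup"):
            length = pos2 - pos + 1
    else:  # ins
        length = len(seq)
    return pos, ("inframe_indel" if length % 3 == 0 else "frameshift")


def parse_variant_effect(hgvs_p: str = "", hgvs_c: str = "") -> VariantEffect:
    """Parse an HGVS protein and/or cDNA notation into a :class:`VariantEffect`.

    The codon comes from the protein notation when present, else it is derived
    from the cDNA position as ``ceil(position / 3)``.  When both notations are
    given and disagree by more than one codon a warning is emitted and the
    protein notation wins (the +/-1 tolerance absorbs frameshifts whose first
    altered residue lies one codon downstream of the nucleotide change).
    """
    hgvs_p = (hgvs_p or "").strip()
    hgvs_c = (hgvs_c or "").strip()
    if not hgvs_p and not hgvs_c:
        raise HgvsParseError("", "at least one of hgvs_p / hgvs_c is required")

    cdna_pos = None
    c_class = None
    if hgvs_c:
        cdna_pos, c_class = _parse_cdna(hgvs_c)

    if hgvs_p:
        codon, p_class = _parse_protein(hgvs_p)
        if cdna_pos is not None:
            c_codon = math.ceil(cdna_pos / 3)
            if abs(c_codon - codon) > 1:
                warnings.warn(
                    f"codon disagreement between {hgvs_p!r} (codon {codon}) and "
                    f"{hgvs_c!r} (codon {c_codon}); protein notation wins",
                    stacklevel=2,
                )
        return VariantEffect(codon=codon, mutation_class=p_class, cdna_position=cdna_pos)

    assert cdna_pos is not None
    return VariantEffect(
        codon=math.ceil(cdna_pos / 3),
        mutation_class=c_class if c_class is not None else "other",
        cdna_position=cdna_pos,
    )


# ---------------------------------------------------------------------------
# positional classification

def in_mcr(codon: int, model: GeneModel) -> bool:
    """True iff ``codon`` lies inside the mutation cluster region (inclusive)."""
    if not (1 <= codon <= model.protein_length):
        raise ValueError(f"codon {codon} outside [1, {model.protein_length}]")
    return model.mcr[0] <= codon <= model.mcr[1]


def retained_20aars(truncation_codon: int, model: GeneModel) -> int:
    """Number of 20AARs fully upstream of a truncation (``end < codon``).

    Applies to truncating consequences (nonsense/frameshift/splice); a
    missense allele leaves all repeats intact, which callers handle by using
    the full repeat count instead of this function.
    """
    if not model.repeats_20aar:
        raise GeneModelError("gene model has no 20AAR intervals configured")
    if not (1 <= truncation_codon <= model.protein_length):
        raise ValueError(
            f"codon {truncation_codon} outside [1, {model.protein_length}]"
        )
    return sum(1 for _, hi in model.repeats_20aar if hi < truncation_codon)


def retained_20aars_for_effect(effect: VariantEffect, model: GeneModel) -> int:
    """Retained 20AARs for an allele: full count unless the allele truncates."""
    if effect.is_truncating:
        return retained_20aars(effect.codon, model)
    return len(model.repeats_20aar)


def classify_hit_allele(
    effect: Optional[VariantEffect] = None,
    is_whole_gene_deletion: bool = False,
) -> str:
    """Label one allele as truncating / deletion / nontruncating / no hit."""
    if is_whole_gene_deletion:
        if effect is not None:
            raise ValueError("supply either an effect or the deletion flag, not both")
        return "deletion_hit"
    if effect is None:
        raise ValueError("supply either an effect or the deletion flag")
    if effect.is_truncating:
        return "truncating_hit"
    if effect.mutation_class in {"missense", "inframe_indel", "other"}:
        return "nontruncating_hit"
    return "no_hit"
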