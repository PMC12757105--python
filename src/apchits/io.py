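"""Readers, writers and run configuration.

Conventions: variant/metadata/report tables are TSV; amplicon annotations
are BED-like (genomic coordinates 0-based half-open); protein coordinates
are 1-based closed.  VAF columns are auto-detected as fractions or percent
(any value above 1 means the column is in percent).  A minimal single-sample
VCF can substitute for the variant TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cna import AmpliconCountMatrix
from .gene_model import GeneModel, HgvsParseError, parse_variant_effect
from .variants import HitProfile, PatientRecord, PolypRecord, VariantCall

logger = logging.getLogger("apchits")

__all__ = [
    "RunConfig",
    "read_variant_table",
    "write_variant_table",
    "read_vcf_variants",
    "read_amplicon_matrix",
    "write_amplicon_matrix",
    "read_patient_table",
    "write_patient_table",
    "read_polyp_table",
    "write_polyp_table",
    "export_mutation_map",
    "write_hit_report",
    "write_cross_tab",
]

VARIANT_COLUMNS = ["sample_id", "patient_id", "gene", "hgvs_c", "hgvs_p",
                   "vaf", "depth", "filter"]


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run."""

    output_dir: Path = Path("apchits-out")
    seed: int = 0
    vaf_min: float = 0.05
    normal_vaf_min: float = 0.25
    cna_alpha: float = 0.05
    cna_loss_log2: float = -0.32
    cna_gain_log2: float = 0.26
    mosaic_vaf_max: float = 0.4
    gene_model_path: Optional[Path] = None
    log_level: str = "INFO"

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        for name in ("vaf_min", "normal_vaf_min", "cna_alpha", "mosaic_vaf_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cna_loss_log2 >= 0 or self.cna_gain_log2 <= 0:
            raise ValueError("loss threshold must be negative, gain positive")
        if self.gene_model_path is not None:
            self.gene_model_path = Path(self.gene_model_path)
            if not self.gene_model_path.exists():
                raise FileNotFoundError(self.gene_model_path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _normalize_vaf(series: pd.Series) -> pd.Series:
    """Fractions as-is; a column with any value > 1 is treated as percent."""
    vals = pd.to_numeric(series, errors="coerce")
    if (vals > 1.0).any():
        vals = vals / 100.0
    return vals


def read_variant_table(path: str | Path) -> List[VariantCall]:
    """Read a variant TSV into typed calls.

    Required columns: sample_id, gene, hgvs_c, vaf, depth.  Optional:
    patient_id, hgvs_p, filter, origin, pathogenic.  Malformed rows are
    skipped with their 1-based row number logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "gene", "hgvs_c", "vaf", "depth"):
        if col not in df.columns:
            raise ValueError(f"variant table {path} is missing column {col!r}")
    df["vaf"] = _normalize_vaf(df["vaf"])
    calls: List[VariantCall] = []
    skipped: List[int] = []
    for i, row in df.iterrows():
        try:
            calls.append(VariantCall(
                sample_id=str(row["sample_id"]),
                patient_id=str(row.get("patient_id", "") or ""),
                gene=str(row["gene"]),
                hgvs_c=str(row["hgvs_c"] or ""),
                hgvs_p=str(row.get("hgvs_p", "") or "") if pd.notna(row.get("hgvs_p")) else "",
                vaf=float(row["vaf"]),
                depth=int(float(row["depth"])),
                origin=str(row.get("origin") or "unknown"),
                pathogenic=str(row.get("pathogenic", "true")).lower()
                in {"true", "1", "yes"},
            ))
        except (ValueError, TypeError):
            skipped.append(i + 2)  # 1-based incl. header
    if skipped:
        logger.warning("variant table %s: skipped %d malformed rows: %s",
                       path, len(skipped), skipped[:20])
    logger.info("read %d variant calls from %s (%d skipped)",
                len(calls), path, len(skipped))
    return calls


def write_variant_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    rows = [{
        "sample_id": c.sample_id, "patient_id": c.patient_id, "gene": c.gene,
        "hgvs_c": c.hgvs_c, "hgvs_p": c.hgvs_p, "vaf": repr(c.vaf),
        "depth": c.depth, "filter": "PASS", "origin": c.origin,
        "pathogenic": str(c.pathogenic).lower(),
    } for c in calls]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["origin", "pathogenic"]).to_csv(
        path, sep="\t", index=False)


def read_vcf_variants(path: str | Path, sample_id: Optional[str] = None,
                      patient_id: str = "") -> List[VariantCall]:
    """Minimal single-sample VCF reader; VAF from INFO/AF or FORMAT AD."""
    import pysam

    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample_id is None:
            sample_id = samples[0] if samples else Path(path).stem
        for rec in vcf:
            vaf = None
            depth = rec.info.get("DP", 0)
            if "AF" in rec.info:
                af = rec.info["AF"]
                vaf = float(af[0] if isinstance(af, tuple) else af)
            elif samples:
                fmt = rec.samples[samples[0]]
                ad = fmt.get("AD")
                if ad and sum(ad) > 0:
                    vaf = ad[1] / sum(ad)
                    depth = depth or sum(ad)
            if vaf is None:
                logger.warning("VCF record %s:%s has no AF/AD; skipped",
                               rec.chrom, rec.pos)
                continue
            hgvs_c = str(rec.info.get("HGVSC", "") or "")
            hgvs_p = str(rec.info.get("HGVSP", "") or "")
            gene = str(rec.info.get("GENE", "") or "")
            calls.append(VariantCall(
                sample_id=sample_id, patient_id=patient_id, gene=gene,
                hgvs_c=hgvs_c, hgvs_p=hgvs_p, vaf=min(max(vaf, 0.0), 1.0),
                depth=int(depth or 0),
            ))
    return calls


# ---------------------------------------------------------------------------
# amplicon matrices

def read_amplicon_matrix(annotation_path: str | Path, counts_path: str | Path,
                         roles: Mapping[str, str]) -> AmpliconCountMatrix:
    """Annotation TSV (amplicon_id, gene, pool_id, chrom, start, end; BED-style
    0-based half-open) plus a counts TSV (amplicon_id x samples)."""
    amplicons = pd.read_csv(annotation_path, sep="\t", comment="#")
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    return AmpliconCountMatrix(amplicons=amplicons, counts=counts,
                               sample_roles=dict(roles))


def write_amplicon_matrix(matrix: AmpliconCountMatrix, annotation_path: str | Path,
                          counts_path: str | Path) -> None:
    with open(annotation_path, "w") as fh:
        fh.write("# BED-style genomic coordinates: 0-based, half-open\n")
        matrix.amplicons.to_csv(fh, sep="\t", index=False)
    matrix.counts.rename_axis("amplicon_id").to_csv(counts_path, sep="\t")


# ---------------------------------------------------------------------------
# metadata tables

def write_patient_table(patients: Sequence[PatientRecord], path: str | Path) -> None:
    rows = [{
        "patient_id": p.patient_id, "pedigree_id": p.pedigree_id,
        "cohort": p.cohort, "sex": p.sex, "age": p.age,
        "germline_status": p.germline_status,
        "germline_hgvs_c": p.germline_variant.hgvs_c if p.germline_variant else "",
        "germline_hgvs_p": p.germline_variant.hgvs_p if p.germline_variant else "",
        "phenotype": p.phenotype, "mosaic": str(p.mosaic).lower(),
    } for p in patients]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_patient_table(path: str | Path) -> List[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    patients = []
    for _, row in df.iterrows():
        gv = None
        if row["germline_status"] == "pathogenic_variant":
            gv = VariantCall(
                sample_id=f"{row['patient_id']}-N", patient_id=row["patient_id"],
                gene="APC", hgvs_c=row.get("germline_hgvs_c", ""),
                hgvs_p=row.get("germline_hgvs_p", ""), vaf=0.5, depth=0,
                origin="germline",
            )
        patients.append(PatientRecord(
            patient_id=row["patient_id"], pedigree_id=row.get("pedigree_id", ""),
            cohort=row["cohort"], sex=row.get("sex", ""),
            germline_status=row["germline_status"], germline_variant=gv,
            phenotype=row.get("phenotype") or
            ("not_applicable" if row["cohort"] == "sporadic" else "sparse"),
            mosaic=row.get("mosaic", "false") == "true",
            age=float(row["age"]) if row.get("age") else None,
        ))
    return patients


def write_polyp_table(polyps: Sequence[PolypRecord], path: str | Path) -> None:
    rows = [{
        "polyp_id": p.polyp_id, "patient_id": p.patient_id,
        "histology": p.histology, "location": p.location,
        "age_at_resection": p.age_at_resection,
    } for p in polyps]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_polyp_table(path: str | Path) -> List[PolypRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    return [PolypRecord(
        polyp_id=row["polyp_id"], patient_id=row["patient_id"],
        histology=row["histology"], location=row["location"] or "unknown",
        age_at_resection=float(row["age_at_resection"] or 0.0),
    ) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# exports and reports

def export_mutation_map(calls: Sequence[VariantCall], path: str | Path,
                        gene: Optional[str] = "APC") -> int:
    """Write a MAF-like, codon-sorted table loadable by lollipop plotters.

    Returns the number of rows written; calls without a derivable codon (or
    outside the gene filter) are excluded and counted in the log.
    """
    rows = []
    excluded = 0
    for c in calls:
        if gene is not None and c.gene != gene:
            excluded += 1
            continue
        try:
            c = c.with_effect()
        except HgvsParseError:
            excluded += 1
            continue
        rows.append({
            "Hugo_Symbol": c.gene,
            "Sample_ID": c.sample_id,
            "Protein_Change": c.hgvs_p or c.hgvs_c,
            "Codon": c.effect.codon,
            "Mutation_Class": c.effect.mutation_class,
            "VAF": c.vaf,
        })
    rows.sort(key=lambda r: r["Codon"])
    pd.DataFrame(rows, columns=["Hugo_Symbol", "Sample_ID", "Protein_Change",
                                "Codon", "Mutation_Class", "VAF"]).to_csv(
        path, sep="\t", index=False)
    if excluded:
        logger.info("mutation map export: excluded %d calls", excluded)
    return len(rows)


def write_hit_report(profiles: Sequence[HitProfile],
                     polyps: Mapping[str, PolypRecord],
                     path: str | Path) -> pd.DataFrame:
    """Hit-count report binned 0/1/2/3+ with percentages (1 dp)."""
    rows = [{
        "polyp_id": p.polyp_id,
        "histology": polyps[p.polyp_id].histology if p.polyp_id in polyps else "",
        "location": polyps[p.polyp_id].location if p.polyp_id in polyps else "",
        "germline_hit": p.germline_hit, "somatic_hits": p.somatic_hits,
        "cna_hit": p.cna_hit, "total_hits": p.total_hits, "hit_bin": p.hit_bin,
    } for p in profiles]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_cross_tab(table, path: str | Path) -> None:
    """Write a contingency table with row/column totals and percentages."""
    frame = table.to_frame()
    frame["Total"] = frame.sum(axis=1)
    total = frame["Total"].sum()
    pct = (100.0 * frame / max(total, 1)).round(1)
    out = frame.astype(str) + " (" + pct.astype(str) + ")"
    out.to_csv(path, sep="\t")
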