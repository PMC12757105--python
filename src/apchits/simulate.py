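"""Synthetic FAP / sporadic polyp cohorts with known ground truth.

The generator emits the same objects and tables the pipeline consumes —
patients, polyps, per-sample variant calls and amplicon count matrices —
together with a truth record, so every stage (filtering, partitioning, hit
counting, CNA calling, mosaicism flagging) can be validated end to end.

Sampling model, in draw order from a single seeded generator:

* pedigree structure and cohort sizes;
* per FAP patient, a germline state (pathogenic variant / whole-gene
  deletion / none) and, for variant carriers, a germline codon drawn from
  5'/MCR/3' region weights;
* per polyp, histology, location, a somatic APC hit count, somatic codons
  (MCR-concentrated for FAP, dispersed for sporadic), an optional KRAS hit,
  and a tumor purity;
* read-level noise: germline VAF ~ Binomial(depth, 0.5)/depth (or the
  configured mosaic fraction for mosaic patients), somatic VAF ~
  Binomial(depth, purity * ccf / 2)/depth;
* amplicon counts ~ negative binomial around per-amplicon efficiency x
  per-pool sample total, times any spiked copy-number ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cna import AmpliconCountMatrix
from .gene_model import GeneModel, default_apc_model
from .variants import PatientRecord, PolypRecord, VariantCall

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_amplicon_counts",
    "default_panel",
]

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Generator parameters; every rate has the study-like default."""

    seed: int
    n_fap_pedigrees: int = 17
    pedigree_size_probs: Tuple[float, ...] = (0.85, 0.10, 0.05)  # P(1,2,3 patients)
    n_sporadic: int = 13
    mean_polyps_fap: float = 6.0
    mean_polyps_sporadic: float = 2.8
    # germline mix over (pathogenic_variant, whole_gene_deletion, none_detected)
    germline_mix: Tuple[float, float, float] = (0.75, 0.10, 0.15)
    # germline codon region weights over (5', MCR, 3')
    germline_region_weights: Tuple[float, float, float] = (0.8, 0.0, 0.2)
    # somatic APC hit-count probabilities per polyp
    somatic_count_probs_fap: Tuple[float, ...] = (0.25, 0.66, 0.09)
    somatic_count_probs_sporadic: Tuple[float, ...] = (0.306, 0.444, 0.222, 0.028)
    # probability a somatic APC mutation falls inside the MCR
    somatic_mcr_weight_fap: float = 0.633
    somatic_mcr_weight_sporadic: float = 0.444
    kras_rate: Mapping[str, float] = field(
        default_factory=lambda: {"low_grade": 0.24, "high_grade": 0.78, "carcinoma": 0.78}
    )
    histology_probs: Tuple[float, float, float] = (0.85, 0.04, 0.11)  # LG / HG / Ca
    location_probs: Tuple[float, float, float] = (0.36, 0.39, 0.25)  # prox / dist / rect
    purity_beta: Tuple[float, float] = (8.0, 2.0)
    ccf: float = 1.0
    mean_depth: int = 800
    mosaic_rate: float = 0.0
    mosaic_fraction: float = 0.17
    # amplicon panel / count model
    n_genes: int = 9
    n_amplicons: int = 325
    n_pools: int = 2
    pool_mean_reads: float = 200_000.0
    nb_dispersion: float = 0.1
    cna_spikes: Tuple[Tuple[str, str, float], ...] = ()  # (gene, sample_id, ratio)
    noise_free: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("pedigree_size_probs", "germline_mix",
                     "somatic_count_probs_fap", "somatic_count_probs_sporadic",
                     "germline_region_weights", "histology_probs", "location_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0,
                                                             abs_tol=1e-9):
                raise ValueError(f"{name} must be a probability mixture summing to 1")


@dataclass
class SyntheticTruth:
    """Ground truth per polyp and per sample, aligned with the emitted tables."""

    hit_counts: Dict[str, int] = field(default_factory=dict)  # polyp_id -> total hits
    somatic_counts: Dict[str, int] = field(default_factory=dict)
    germline_hits: Dict[str, int] = field(default_factory=dict)
    origins: Dict[Tuple[str, str, str], str] = field(default_factory=dict)
    # (sample_id, gene, hgvs_c) -> germline/somatic
    cna_ratios: Dict[Tuple[str, str], float] = field(default_factory=dict)
    mosaic_patients: Dict[str, float] = field(default_factory=dict)  # -> true fraction


@dataclass
class SimulatedCohort:
    patients: List[PatientRecord]
    polyps: List[PolypRecord]
    normal_calls: Dict[str, List[VariantCall]]  # patient_id -> reference-sample calls
    truth: SyntheticTruth
    config: SimConfig


PANEL_GENES = ("APC", "KRAS", "ARID1A", "FBXW7", "CTNNB1", "BRAF", "NRAS",
               "MUTYH", "PIK3CA")

# 5' / MCR / 3' codon windows used for drawing APC positions
_REGIONS = {"5prime": (50, 1285), "mcr": (1286, 1513), "3prime": (1514, 2800)}


def _draw_vaf(rng: np.random.Generator, depth: int, p: float, noise_free: bool) -> float:
    p = min(max(p, 0.0), 1.0)
    if noise_free:
        return p
    return rng.binomial(depth, p) / depth if depth > 0 else 0.0


def _apc_variant_notation(rng: np.random.Generator, codon: int,
                          truncating_kind: Optional[str] = None) -> Tuple[str, str]:
    """Fabricate a consistent (hgvs_c, hgvs_p) pair truncating at ``codon``."""
    kind = truncating_kind or ("nonsense" if rng.random() < 0.55 else "frameshift")
    aa = "QLSEYCKRGW"[int(rng.integers(0, 10))]
    if kind == "nonsense":
        pos = 3 * codon - 2
        ref, alt = ("C", "T") if rng.random() < 0.6 else ("C", "A")
        return f"c.{pos}{ref}>{alt}", f"p.{aa}{codon}*"
    pos = 3 * codon - 1
    base = _BASES[int(rng.integers(0, 4))]
    nstop = int(rng.integers(2, 60))
    aa2 = "VGCLS"[int(rng.integers(0, 5))]
    return f"c.{pos}del{base}", f"p.{aa}{codon}{aa2}fs*{nstop}"


def _draw_codon(rng: np.random.Generator, region: str) -> int:
    lo, hi = _REGIONS[region]
    return int(rng.integers(lo, hi + 1))


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full cohort; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()
    patients: List[PatientRecord] = []
    polyps: List[PolypRecord] = []
    normal_calls: Dict[str, List[VariantCall]] = {}

    # --- FAP pedigrees -----------------------------------------------------
    pidx = 0
    for ped in range(config.n_fap_pedigrees):
        size = 1 + int(rng.choice(len(config.pedigree_size_probs),
                                  p=config.pedigree_size_probs))
        status_i = int(rng.choice(3, p=config.germline_mix))
        status = ("pathogenic_variant", "whole_gene_deletion", "none_detected")[status_i]
        germ_notation = None
        if status == "pathogenic_variant":
            region = ("5prime", "mcr", "3prime")[
                int(rng.choice(3, p=config.germline_region_weights))
            ]
            codon = _draw_codon(rng, region)
            germ_notation = _apc_variant_notation(rng, codon)
        for _ in range(size):
            pidx += 1
            patient_id = f"FAP{pidx}"
            mosaic = bool(rng.random() < config.mosaic_rate) and status == "pathogenic_variant"
            het_p = config.mosaic_fraction if mosaic else 0.5
            gv = None
            if status == "pathogenic_variant":
                depth = _draw_depth(rng, config)
                gv = VariantCall(
                    sample_id=f"{patient_id}-N", patient_id=patient_id, gene="APC",
                    hgvs_c=germ_notation[0], hgvs_p=germ_notation[1],
                    vaf=_draw_vaf(rng, depth, het_p, config.noise_free),
                    depth=depth, origin="germline",
                )
            patient = PatientRecord(
                patient_id=patient_id, pedigree_id=f"ped{ped + 1}", cohort="FAP",
                sex="F" if rng.random() < 0.7 else "M",
                germline_status=status, germline_variant=gv,
                phenotype="sparse", mosaic=mosaic,
                age=float(rng.integers(15, 75)),
            )
            patients.append(patient)
            normal_calls[patient_id] = [gv] if gv is not None else []
            if mosaic:
                truth.mosaic_patients[patient_id] = het_p
            _simulate_polyps(rng, config, patient, het_p, polyps, truth)

    # --- sporadic patients -------------------------------------------------
    for i in range(config.n_sporadic):
        patient_id = f"SP{i + 1}"
        patient = PatientRecord(
            patient_id=patient_id, pedigree_id="", cohort="sporadic",
            sex="M" if rng.random() < 0.67 else "F",
            germline_status="none_detected", phenotype="not_applicable",
            age=float(rng.integers(45, 80)),
        )
        patients.append(patient)
        normal_calls[patient_id] = []
        _simulate_polyps(rng, config, patient, 0.5, polyps, truth)

    return SimulatedCohort(patients, polyps, normal_calls, truth, config)


def _draw_depth(rng: np.random.Generator, config: SimConfig) -> int:
    if config.noise_free:
        return config.mean_depth
    return max(int(rng.poisson(config.mean_depth)), 1)


def _simulate_polyps(
    rng: np.random.Generator,
    config: SimConfig,
    patient: PatientRecord,
    het_p: float,
    polyps: List[PolypRecord],
    truth: SyntheticTruth,
) -> None:
    fap = patient.cohort == "FAP"
    mean_polyps = config.mean_polyps_fap if fap else config.mean_polyps_sporadic
    n_polyps = max(int(rng.poisson(mean_polyps)), 1)
    count_probs = (config.somatic_count_probs_fap if fap
                   else config.somatic_count_probs_sporadic)
    mcr_w = config.somatic_mcr_weight_fap if fap else config.somatic_mcr_weight_sporadic

    for j in range(n_polyps):
        polyp_id = f"{patient.patient_id}-P{j + 1}"
        histology = HISTOLOGY_LEVELS[int(rng.choice(3, p=config.histology_probs))]
        location = LOCATION_LEVELS[int(rng.choice(3, p=config.location_probs))]
        purity = (1.0 if config.noise_free
                  else float(rng.beta(*config.purity_beta)))
        calls: List[VariantCall] = []

        # germline variant re-observed in the lesion
        if patient.germline_variant is not None:
            depth = _draw_depth(rng, config)
            calls.append(replace(
                patient.germline_variant,
                sample_id=polyp_id,
                vaf=_draw_vaf(rng, depth, het_p, config.noise_free),
                depth=depth,
            ))

        n_somatic = int(rng.choice(len(count_probs), p=count_probs))
        seen = {patient.germline_variant.hgvs_c} if patient.germline_variant else set()
        emitted = 0
        for _ in range(n_somatic):
            for _attempt in range(20):
                region = "mcr" if rng.random() < mcr_w else (
                    "5prime" if rng.random() < 0.7 else "3prime")
                codon = _draw_codon(rng, region)
                hgvs_c, hgvs_p = _apc_variant_notation(rng, codon)
                if hgvs_c not in seen:
                    break
            seen.add(hgvs_c)
            depth = _draw_depth(rng, config)
            vaf = _draw_vaf(rng, depth, purity * config.ccf / 2, config.noise_free)
            calls.append(VariantCall(
                sample_id=polyp_id, patient_id=patient.patient_id, gene="APC",
                hgvs_c=hgvs_c, hgvs_p=hgvs_p, vaf=vaf, depth=depth,
                origin="unknown",
            ))
            truth.origins[(polyp_id, "APC", hgvs_c)] = "somatic"
            emitted += 1

        if rng.random() < config.kras_rate.get(histology, 0.0):
            depth = _draw_depth(rng, config)
            calls.append(VariantCall(
                sample_id=polyp_id, patient_id=patient.patient_id, gene="KRAS",
                hgvs_c="c.35G>A", hgvs_p="p.G12D",
                vaf=_draw_vaf(rng, depth, purity * config.ccf / 2, config.noise_free),
                depth=depth, origin="unknown",
            ))
            truth.origins[(polyp_id, "KRAS", "c.35G>A")] = "somatic"

        polyp = PolypRecord(
            polyp_id=polyp_id, patient_id=patient.patient_id,
            histology=histology, location=location,
            age_at_resection=float(patient.age or 40.0),
            variants=calls,
        )
        polyps.append(polyp)
        germ_hit = 1 if patient.has_germline_hit else 0
        truth.germline_hits[polyp_id] = germ_hit
        truth.somatic_counts[polyp_id] = emitted
        truth.hit_counts[polyp_id] = germ_hit + emitted


HISTOLOGY_LEVELS = ("low_grade", "high_grade", "carcinoma")
LOCATION_LEVELS = ("proximal", "distal", "rectum")


# ---------------------------------------------------------------------------
# amplicon counts

def default_panel(n_genes: int = 9, n_amplicons: int = 325, n_pools: int = 2) -> pd.DataFrame:
    """Panel annotation mirroring a 9-gene / 325-amplicon, 2-pool design.

    Amplicons are distributed round-robin over the genes and alternate
    between primer pools; genomic coordinates are synthetic placeholders
    (0-based half-open) that preserve within-gene ordering.
    """
    genes = list(PANEL_GENES[:n_genes])
    rows = []
    per_gene = {g: 0 for g in genes}
    for i in range(n_amplicons):
        gene = genes[i % len(genes)]
        per_gene[gene] += 1
        rows.append({
            "amplicon_id": f"AMP_{i + 1:04d}",
            "gene": gene,
            "pool_id": f"pool{(i % n_pools) + 1}",
            "chrom": f"chr{(genes.index(gene) % 22) + 1}",
            "start": 1000 * per_gene[gene],
            "end": 1000 * per_gene[gene] + 150,
        })
    return pd.DataFrame(rows)


def simulate_amplicon_counts(
    config: SimConfig,
    sample_roles: Mapping[str, str],
    panel: Optional[pd.DataFrame] = None,
    spikes: Optional[Sequence[Tuple[str, str, float]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[AmpliconCountMatrix, Dict[Tuple[str, str], float]]:
    """Draw an amplicon x sample count matrix with optional spiked CNAs.

    Counts are negative binomial around (per-amplicon efficiency) x
    (per-pool sample total) x (spiked copy ratio); normal-reference samples
    always have ratio 1.  Returns the matrix and the true (gene, sample) ->
    ratio map.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if panel is None:
        panel = default_panel(config.n_genes, config.n_amplicons, config.n_pools)
    spikes = list(spikes if spikes is not None else config.cna_spikes)
    ratio_map: Dict[Tuple[str, str], float] = {}
    for gene, sample_id, ratio in spikes:
        if sample_roles.get(sample_id) == "normal_reference":
            raise ValueError("cannot spike a CNA into a normal_reference sample")
        ratio_map[(gene, sample_id)] = float(ratio)

    samples = list(sample_roles)
    eff = rng.lognormal(mean=0.0, sigma=0.4, size=len(panel))
    disp = config.nb_dispersion
    counts = np.zeros((len(panel), len(samples)), dtype=int)
    pool_ids = panel["pool_id"].to_numpy()
    genes = panel["gene"].to_numpy()
    for si, sample in enumerate(samples):
        pool_totals = {p: rng.lognormal(np.log(config.pool_mean_reads), 0.2)
                       for p in dict.fromkeys(pool_ids)}
        for ai in range(len(panel)):
            ratio = ratio_map.get((genes[ai], sample), 1.0)
            mean = eff[ai] * pool_totals[pool_ids[ai]] / (len(panel) / config.n_pools) * ratio
            if disp <= 0:
                counts[ai, si] = rng.poisson(mean)
            else:
                r = 1.0 / disp
                counts[ai, si] = rng.negative_binomial(r, r / (r + mean))
    matrix = AmpliconCountMatrix(
        amplicons=panel,
        counts=pd.DataFrame(counts, index=panel["amplicon_id"], columns=samples),
        sample_roles=dict(sample_roles),
    )
    return matrix, ratio_map
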