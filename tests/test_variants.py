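"""Variant filtering, germline/somatic partitioning and hit counting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apchits.cna import CNACall
from apchits.variants import (
    HitProfile,
    PatientRecord,
    PolypRecord,
    VariantCall,
    count_apc_hits,
    filter_by_vaf,
    mcr_rate,
    mutation_class_tally,
    partition_germline_somatic,
    screen_mutyh_germline,
)


def vc(hgvs_c="c.1417C>T", hgvs_p="p.Q473*", vaf=0.3, gene="APC", sample="T1",
       origin="unknown", depth=500, pathogenic=True, patient_id="PT1"):
    return VariantCall(sample_id=sample, patient_id=patient_id, gene=gene,
                       hgvs_c=hgvs_c, hgvs_p=hgvs_p, vaf=vaf, depth=depth,
                       origin=origin, pathogenic=pathogenic)


def fap_patient(codon=473, status="pathogenic_variant", patient_id="PT1"):
    gv = None
    if status == "pathogenic_variant":
        gv = vc(hgvs_c=f"c.{3 * codon - 2}C>T", hgvs_p=f"p.Q{codon}*", vaf=0.5,
                sample=f"{patient_id}-N", origin="germline", patient_id=patient_id)
    return PatientRecord(patient_id=patient_id, cohort="FAP", sex="F",
                         germline_status=status, germline_variant=gv,
                         phenotype="sparse")


class TestFilterByVaf:
    def test_inclusive_cutoff(self):
        kept = filter_by_vaf([vc(vaf=0.050), vc(vaf=0.049)], 0.05)
        assert [c.vaf for c in kept] == [0.050]

    def test_empty_and_order(self):
        assert filter_by_vaf([], 0.05) == []
        calls = [vc(vaf=0.5, hgvs_c="c.3C>T"), vc(vaf=0.2, hgvs_c="c.9C>T")]
        assert [c.hgvs_c for c in filter_by_vaf(calls, 0.05)] == ["c.3C>T", "c.9C>T"]

    def test_input_unmodified(self):
        calls = [vc(vaf=0.01)]
        filter_by_vaf(calls, 0.05)
        assert calls[0].vaf == 0.01


class TestPartition:
    def test_matched_in_normal_is_germline(self):
        germ, som = partition_germline_somatic(
            [vc(vaf=0.48)], [vc(vaf=0.47, sample="N")], 0.25)
        assert len(germ) == 1 and not som
        assert germ[0].origin == "germline"

    def test_absent_from_normal_is_somatic(self):
        germ, som = partition_germline_somatic([vc(vaf=0.30)], [], 0.25)
        assert not germ and som[0].origin == "somatic"

    def test_low_normal_vaf_is_somatic(self):
        germ, som = partition_germline_somatic(
            [vc(vaf=0.30)], [vc(vaf=0.02, sample="N")], 0.25)
        assert not germ and len(som) == 1

    def test_missing_normal_marks_unknown_with_warning(self):
        with pytest.warns(UserWarning, match="no matched normal"):
            germ, som = partition_germline_somatic([vc(vaf=0.3)], None)
        assert not som and germ[0].origin == "unknown"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 60), st.floats(0.05, 1.0)), max_size=20),
           st.lists(st.tuples(st.integers(1, 60), st.floats(0.0, 1.0)), max_size=20))
    def test_partition_is_exhaustive(self, tumor_spec, normal_spec):
        tumor = [vc(hgvs_c=f"c.{3 * c}A>T", hgvs_p="", vaf=round(v, 3))
                 for c, v in tumor_spec]
        normal = [vc(hgvs_c=f"c.{3 * c}A>T", hgvs_p="", vaf=round(v, 3), sample="N")
                  for c, v in normal_spec]
        germ, som = partition_germline_somatic(tumor, normal, 0.25)
        assert len(germ) + len(som) == len(tumor)
        assert all(c.origin == "germline" for c in germ)
        assert all(c.origin == "somatic" for c in som)


class TestCountApcHits:
    def polyp(self, calls, cna=()):
        return PolypRecord(polyp_id="T1", patient_id="PT1", histology="low_grade",
                           location="proximal", age_at_resection=36.0,
                           variants=list(calls), cna_calls=list(cna))

    def test_germline_plus_one_somatic_is_two_hits(self, apc_model):
        polyp = self.polyp([vc(origin="germline", vaf=0.5),
                            vc(hgvs_c="c.4000C>T", hgvs_p="p.Q1334*", origin="somatic")])
        prof = count_apc_hits(polyp, fap_patient(), apc_model)
        assert (prof.germline_hit, prof.somatic_hits, prof.cna_hit) == (1, 1, 0)
        assert prof.total_hits == 2

    def test_three_hit_genotype(self, apc_model):
        polyp = self.polyp([
            vc(hgvs_c="c.4000C>T", hgvs_p="p.Q1334*", origin="somatic"),
            vc(hgvs_c="c.4300C>T", hgvs_p="p.Q1434*", origin="somatic"),
        ])
        assert count_apc_hits(polyp, fap_patient(), apc_model).total_hits == 3

    def test_whole_gene_deletion_counts_as_germline_hit(self, apc_model):
        polyp = self.polyp([
            vc(hgvs_c="c.4000C>T", hgvs_p="p.Q1334*", origin="somatic"),
            vc(hgvs_c="c.4300C>T", hgvs_p="p.Q1434*", origin="somatic"),
        ])
        prof = count_apc_hits(polyp, fap_patient(status="whole_gene_deletion"),
                              apc_model)
        assert prof.total_hits == 3
        assert prof.retained_20aars_germline == 0

    def test_no_hits(self, apc_model):
        prof = count_apc_hits(self.polyp([]), fap_patient(status="none_detected"),
                              apc_model)
        assert prof.total_hits == 0

    def test_duplicate_hgvs_counts_once(self, apc_model):
        polyp = self.polyp([
            vc(hgvs_c="c.4000C>T", hgvs_p="p.Q1334*", origin="somatic", vaf=0.2),
            vc(hgvs_c="c.4000C>T", hgvs_p="p.Q1334*", origin="somatic", vaf=0.4),
        ])
        assert count_apc_hits(polyp, fap_patient(), apc_model).somatic_hits == 1

    def test_other_gene_ignored(self, apc_model):
        polyp = self.polyp([vc(gene="KRAS", hgvs_c="c.35G>A", hgvs_p="p.G12D",
                               origin="somatic")])
        assert count_apc_hits(polyp, fap_patient(), apc_model).somatic_hits == 0

    def test_cna_loss_is_a_hit_unless_germline_deletion(self, apc_model):
        loss = CNACall(gene="APC", sample_id="T1", n_amplicons=12,
                       mean_log2_ratio=-1.0, t_statistic=-9.0,
                       degrees_of_freedom=11, p_value=1e-6, call="loss")
        polyp = self.polyp([], cna=[loss])
        assert count_apc_hits(polyp, fap_patient(), apc_model).cna_hit == 1
        assert count_apc_hits(polyp, fap_patient(status="whole_gene_deletion"),
                              apc_model).cna_hit == 0

    def test_truncating_only_switch(self, apc_model):
        polyp = self.polyp([vc(hgvs_c="c.4000G>A", hgvs_p="p.A1334T",
                               origin="somatic")])
        assert count_apc_hits(polyp, fap_patient(), apc_model).somatic_hits == 1
        assert count_apc_hits(polyp, fap_patient(), apc_model,
                              include_nontruncating=False).somatic_hits == 0

    def test_mcr_and_retained_annotations(self, apc_model):
        polyp = self.polyp([vc(hgvs_c="c.4000C>T", hgvs_p="p.Q1334*",
                               origin="somatic")])
        prof = count_apc_hits(polyp, fap_patient(codon=1928), apc_model)
        assert prof.somatic_in_mcr == [True]
        assert prof.retained_20aars_somatic == [1]
        assert prof.retained_20aars_germline == 5


class TestMcrRate:
    def profile(self, polyp_id, in_mcr_flags):
        return HitProfile(polyp_id=polyp_id, germline_hit=1,
                          somatic_hits=len(in_mcr_flags), cna_hit=0,
                          somatic_in_mcr=list(in_mcr_flags),
                          retained_20aars_somatic=[0] * len(in_mcr_flags))

    def test_all_and_none(self):
        assert mcr_rate([self.profile("a", [True]), self.profile("b", [True])]) == 1.0
        assert mcr_rate([self.profile("a", [False])]) == 0.0

    def test_undefined_when_no_somatic(self):
        assert mcr_rate([self.profile("a", [])]) is None

    def test_study_rate(self):
        profiles = [self.profile(f"m{i}", [True]) for i in range(38)]
        profiles += [self.profile(f"w{i}", [False]) for i in range(22)]
        assert mcr_rate(profiles) == pytest.approx(38 / 60)


class TestMutationTally:
    def test_spectrum_folding(self):
        calls = [vc(hgvs_c="c.100C>T", hgvs_p="p.Q34*"),
                 vc(hgvs_c="c.103C>T", hgvs_p="p.Q35*"),
                 vc(hgvs_c="c.106C>A", hgvs_p="p.S36*"),
                 vc(hgvs_c="c.109G>A", hgvs_p="p.A37T")]
        tally = mutation_class_tally(calls)
        assert tally.spectrum["C>T"] == 3  # G>A folds to C>T
        assert tally.spectrum["C>A"] == 1
        assert tally.n_spectrum_skipped == 0

    def test_non_snv_skipped_in_spectrum(self):
        tally = mutation_class_tally([vc(hgvs_c="c.100delC", hgvs_p="p.S34Vfs*2")])
        assert tally.n_spectrum_skipped == 1
        assert tally.class_counts["frameshift"] == 1
        assert tally.indel_count == 1

    def test_empty(self):
        tally = mutation_class_tally([])
        assert sum(tally.class_counts.values()) == 0
        assert sum(tally.spectrum.values()) == 0


class TestMutyhScreen:
    def test_no_calls_is_none(self):
        assert screen_mutyh_germline({"PT1": []}) == {"PT1": "none"}

    def test_single_het_is_monoallelic(self):
        calls = [vc(gene="MUTYH", hgvs_c="c.536A>G", hgvs_p="p.Y179C", vaf=0.5,
                    origin="germline")]
        assert screen_mutyh_germline({"PT1": calls}) == {"PT1": "monoallelic"}

    def test_high_vaf_is_biallelic(self):
        calls = [vc(gene="MUTYH", hgvs_c="c.536A>G", hgvs_p="p.Y179C", vaf=0.95,
                    origin="germline")]
        assert screen_mutyh_germline({"PT1": calls}) == {"PT1": "biallelic"}

    def test_two_distinct_variants_is_biallelic(self):
        calls = [vc(gene="MUTYH", hgvs_c="c.536A>G", hgvs_p="p.Y179C", vaf=0.5,
                    origin="germline"),
                 vc(gene="MUTYH", hgvs_c="c.1187G>A", hgvs_p="p.G396D", vaf=0.5,
                    origin="germline")]
        assert screen_mutyh_germline({"PT1": calls}) == {"PT1": "biallelic"}

    def test_nonpathogenic_ignored(self):
        calls = [vc(gene="MUTYH", hgvs_c="c.64G>A", hgvs_p="p.V22M", vaf=0.5,
                    origin="germline", pathogenic=False)]
        assert screen_mutyh_germline({"PT1": calls}) == {"PT1": "none"}
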