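"""Family-call cascade: planted diagnostics, verdicts, naming, overrides."""

import numpy as np
import pytest

from cuticula.config import RunConfig
from cuticula.cp_classifier import (
    FamilyCall,
    apply_overrides,
    assign_names,
    classify_all,
    classify_cpap,
    classify_cpr,
    classify_low_complexity,
    classify_protein,
    classify_tweedle,
)
from cuticula.homology import OrthologMap
from cuticula.motif_engine import DEFAULT_MOTIFS
from cuticula.sequence_io import GeneLocus, ProteinRecord

from conftest import random_protein
from test_motif_engine import instantiate


class TestCpr:
    def test_planted_rr1_consensus(self, reference, config):
        seq = "MKVL" + instantiate(DEFAULT_MOTIFS["rr1_consensus"], "A") + "GGWL"
        call = classify_cpr(ProteinRecord("p", seq), reference=reference,
                            config=config)
        assert (call.family, call.subfamily) == ("CPR", "RR-1")

    def test_planted_rr2_consensus(self, reference, config):
        seq = "MKVL" + instantiate(DEFAULT_MOTIFS["rr2_consensus"], "G") + "GGWL"
        call = classify_cpr(ProteinRecord("p", seq), reference=reference,
                            config=config)
        assert (call.family, call.subfamily) == ("CPR", "RR-2")

    def test_near_tied_scores_give_rr_nc(self, reference, config):
        # both consensus regions present verbatim: scores tie at 1.0
        seq = (instantiate(DEFAULT_MOTIFS["rr1_consensus"], "A")
               + instantiate(DEFAULT_MOTIFS["rr2_consensus"], "G"))
        call = classify_cpr(ProteinRecord("p", seq), reference=reference,
                            config=config)
        assert (call.family, call.subfamily) == ("CPR", "RR-NC")

    def test_rr3_by_exemplar_identity(self, reference, config, rng):
        exemplar = reference.by_subfamily("RR-3")[0].record.sequence
        seq = list(exemplar)
        seq[4] = "W" if seq[4] != "W" else "Y"
        call = classify_cpr(ProteinRecord("p", "".join(seq)),
                            reference=reference, config=config)
        assert (call.family, call.subfamily) == ("CPR", "RR-3")

    def test_random_protein_is_none(self, reference, config, rng):
        assert classify_cpr(random_protein(rng, 100),
                            reference=reference, config=config) is None


class TestCpap:
    def test_three_spacing_instances_are_cpap3(self, rng, config):
        domains = [instantiate(DEFAULT_MOTIFS["cpap3_spacing"], "A")
                   for _ in range(3)]
        seq = "MKVWLYQERT".join(domains)
        call = classify_cpap(ProteinRecord("p", seq), config=config)
        assert call.family == "CPAP3"

    def test_one_spacing_instance_is_cpap1(self, config):
        seq = "MKVL" + instantiate(DEFAULT_MOTIFS["cpap1_spacing"], "A") + "WY"
        call = classify_cpap(ProteinRecord("p", seq), config=config)
        assert call.family == "CPAP1"

    def test_cysteine_free_protein_is_none(self, config):
        assert classify_cpap(ProteinRecord("p", "MKVLAG" * 20),
                             config=config) is None


class TestTweedle:
    @staticmethod
    def blocks():
        return [instantiate(DEFAULT_MOTIFS[f"tweedle_block_{i}"], "A")
                for i in (1, 2, 3, 4)]

    def test_all_blocks_in_order(self, config):
        seq = "MKVWLYQERTLL".join(self.blocks())
        call = classify_tweedle(ProteinRecord("p", seq), config=config)
        assert call.family == "CPT"

    def test_shuffled_blocks_rejected(self, config):
        b = self.blocks()
        seq = "MKVWLYQERTLL".join([b[3], b[2], b[1], b[0]])
        # blocks present but out of order: fewer than 3 chain in order
        call = classify_tweedle(ProteinRecord("p", seq), config=config)
        assert call is None

    def test_single_block_rejected(self, config):
        seq = "MMMM" + self.blocks()[1] + "WWWW"
        assert classify_tweedle(ProteinRecord("p", seq), config=config) is None


class TestLowComplexity:
    def test_two_cx5c_repeats_are_cpcfc(self, reference, config):
        seq = "MKVLWQ" + "CAAAAAC" + "GGWLYERT" + "CAAAAAC" + "MKVL"
        call = classify_low_complexity(ProteinRecord("p", seq), reference, config)
        assert call.family == "CPCFC"

    def test_proline_rich_dipeptides_are_cplcp(self, reference, config):
        seq = "MKVL" + "PVAPYG" * 8 + "WLQE"
        call = classify_low_complexity(ProteinRecord("p", seq), reference, config)
        assert call.family == "CPLCP"

    def test_glycine_rich_repeats_are_cpg(self, reference, config):
        seq = "GGAGL" * 4 + "GGYGG" + "AWLGG" + "GGYGG" + "LY" + "GGYGG"
        call = classify_low_complexity(ProteinRecord("p", seq), reference, config)
        assert call.family == "CPG"

    def test_aap_repeats_are_cph(self, reference, config):
        seq = "MKVLWQ" + "AAPVWLYERQ" + "AAPAMKVLYE" + "AAPLWQ"
        call = classify_low_complexity(ProteinRecord("p", seq), reference, config)
        assert call.family == "CPH"

    def test_reference_identity_gives_cpf(self, reference, config, rng):
        ref_seq = reference.by_family("CPF")[0].record.sequence
        seq = list(ref_seq)
        for i in range(0, len(seq), 12):
            seq[i] = "W" if seq[i] != "W" else "Y"
        call = classify_low_complexity(ProteinRecord("p", "".join(seq)),
                                       reference, config)
        assert call.family == "CPF"


class TestClassifyAll:
    def test_empty_proteome(self, reference, config):
        assert classify_all([], reference, config) == []

    def test_deterministic_and_partition(self, reference, config, rng):
        proteome = [random_protein(rng, 80, f"p{i}") for i in range(10)]
        c1 = classify_all(proteome, reference, config)
        c2 = classify_all(proteome, reference, config)
        assert [(c.family, c.subfamily) for c in c1] == \
            [(c.family, c.subfamily) for c in c2]
        assert len(c1) == len(proteome)  # exactly one call per protein

    def test_random_proteome_is_mostly_not_cp(self, reference, config):
        """False-positive rate on uniform-random proteins stays below 5%
        (measured over 300 proteins; chance C-x(5)-C pairs dominate it)."""
        not_cp = total = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            proteome = [random_protein(rng, 100, f"s{seed}p{i}")
                        for i in range(100)]
            calls = classify_all(proteome, reference, config)
            not_cp += sum(1 for c in calls if c.family == "not-CP")
            total += len(calls)
        assert not_cp / total >= 0.95

    def test_chtbd2_takes_precedence_over_consensus(self, reference, config):
        # a protein with both a ChtBD2 spacing and an R&R consensus is CPAP
        seq = (instantiate(DEFAULT_MOTIFS["cpap1_spacing"], "A")
               + instantiate(DEFAULT_MOTIFS["rr1_consensus"], "A"))
        call = classify_protein(ProteinRecord("p", seq), reference, config)
        assert call.family == "CPAP1"

    def test_monotone_evidence_under_demutation(self, reference, config):
        """If a mutated planted protein classifies correctly, the
        unmutated (stronger-evidence) version does too."""
        from cuticula.synthetic_data import make_proteome
        recs_mut, ref, truth = make_proteome(
            {"RR-1": 2, "CPAP1": 2, "CPT": 2, "CPG": 2}, mutation_rate=0.05,
            seed=3, n_decoys=0)
        recs_clean, _, _ = make_proteome(
            {"RR-1": 2, "CPAP1": 2, "CPT": 2, "CPG": 2}, mutation_rate=0.0,
            seed=3, n_decoys=0)
        for mut, clean, row in zip(recs_mut, recs_clean, truth.itertuples()):
            expected = (row.family, row.subfamily or None)
            got_mut = classify_protein(mut, ref, config)
            got_clean = classify_protein(clean, ref, config)
            if (got_mut.family, got_mut.subfamily) == expected:
                assert (got_clean.family, got_clean.subfamily) == expected


class TestNamingAndOverrides:
    def test_rbh_partner_name_inherited(self, config):
        calls = [FamilyCall("q1", "CPF", None, [("reference_identity", 0.8)])]
        class FakeRef:
            def __iter__(self):
                return iter([type("E", (), {
                    "record": ProteinRecord("REF_RefCPF", "MKV"),
                    "name": "RefCPF"})()])
        omap = OrthologMap(pairs=[("q1", "REF_RefCPF", 0.8, "1:1")])
        named = assign_names(calls, FakeRef(), omap, config=config)
        assert named[0].assigned_name == "ApCPF"

    def test_unnamed_genes_numbered_in_genomic_order(self, config):
        calls = [FamilyCall("b", "CPG", None, [("x", 1)]),
                 FamilyCall("a", "CPG", None, [("x", 1)])]
        loci = [GeneLocus("a", "chr9", 100, 200),
                GeneLocus("b", "chr5", 100, 200)]
        named = assign_names(calls, [], None, loci, config)
        by_id = {c.protein_id: c.assigned_name for c in named}
        assert by_id == {"b": "ApCPG1", "a": "ApCPG2"}  # chr5 before chr9

    def test_duplicate_ortholog_assignment_is_error(self, config):
        calls = [FamilyCall("q1", "CPF", None, [("x", 1)]),
                 FamilyCall("q2", "CPF", None, [("x", 1)])]
        class FakeRef:
            def __iter__(self):
                return iter([type("E", (), {
                    "record": ProteinRecord("r", "MKV"), "name": "RefCPF"})()])
        omap = OrthologMap(pairs=[("q1", "r", 0.9, "1:1"),
                                  ("q2", "r", 0.8, "1:1")])
        with pytest.raises(ValueError, match="collision"):
            assign_names(calls, FakeRef(), omap, config=config)

    def test_override_applied_and_flagged(self, tmp_path):
        calls = [FamilyCall("g1", "CPR", "RR-1", [("rr1_score", 0.9)])]
        ov = tmp_path / "ov.tsv"
        ov.write_text("id\tfamily\tsubfamily\ng1\tCPR\tRR-2\n")
        out = apply_overrides(calls, ov)
        assert out[0].subfamily == "RR-2" and out[0].override
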