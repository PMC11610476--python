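import pytest

from zfx import synthetic
from zfx.classify import (
    MOTIF_PCYCC,
    MOTIF_QALGGH,
    MOTIF_SATALL_BLOCK,
    assign_set,
    assign_subgroup_C,
    classify_protein,
    classify_proteome,
    detect_motif,
)
from zfx.fingerscan import group_arrays, scan_fingers
from zfx.io_core import ProteinRecord
from zfx.synthetic import ARCHITECTURE_TEMPLATES, make_protein


def planted(label: str, seed: int = 11) -> ProteinRecord:
    return make_protein(ARCHITECTURE_TEMPLATES[label], seed=seed, protein_id=label)


def scan_and_group(record):
    fingers = scan_fingers(record)
    arrays, isolated = group_arrays(fingers)
    return fingers, arrays, isolated


class TestAssignSet:
    def test_single_finger_is_c(self):
        assert assign_set(*scan_and_group(planted("C1-1"))) == "C"

    def test_tandem_array_is_a(self):
        assert assign_set(*scan_and_group(planted("A1b"))) == "A"

    def test_nine_finger_two_arrays_is_b(self):
        assert assign_set(*scan_and_group(planted("B"))) == "B"

    def test_dispersed_fingers_are_c(self):
        assert assign_set(*scan_and_group(planted("C1-5"))) == "C"

    def test_zero_fingers_unclassified(self):
        assert assign_set([], [], []) == "unclassified"


class TestSubgroupC:
    def test_h_gap_four_is_c2(self):
        fingers, _, _ = scan_and_group(planted("C2"))
        assert assign_subgroup_C(fingers)[:2] == ("C2", "none")

    def test_h_gap_five_is_c3(self):
        fingers, _, _ = scan_and_group(planted("C3"))
        assert assign_subgroup_C(fingers)[:2] == ("C3", "none")

    def test_mixture_three_four_is_c1c2mixed(self):
        fingers, _, _ = scan_and_group(planted("C1C2mixed"))
        assert assign_subgroup_C(fingers)[:2] == ("C1", "C1C2mixed")

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_pure_c1_subset_is_finger_count(self, k):
        fingers, _, _ = scan_and_group(planted(f"C1-{k}"))
        assert assign_subgroup_C(fingers)[:2] == ("C1", f"C1-{k}")


class TestSubgroupA:
    @pytest.mark.parametrize("label", ["A1a", "A1b", "A1c", "A1d"])
    def test_a1_subsets_from_templates(self, label):
        rec = classify_protein(planted(label))
        assert (rec.set_label, rec.subgroup, rec.subset) == ("A", "A1", label)

    def test_a1a_requires_satall(self):
        rec = classify_protein(planted("A1b"))
        assert not rec.has_satall and rec.subset == "A1b"

    def test_a1d_carries_pcycc(self):
        rec = classify_protein(planted("A1d"))
        assert rec.has_pcycc

    def test_a2_dispersed_over_two_runs(self):
        rec = classify_protein(planted("A2"))
        assert (rec.subgroup, len(rec.arrays), len(rec.isolated)) == ("A2", 1, 1)

    def test_a4_single_compact_array(self):
        rec = classify_protein(planted("A4"))
        assert (rec.subgroup, len(rec.arrays), len(rec.isolated)) == ("A4", 1, 0)


class TestDetectMotif:
    def test_qalggh_found_only_in_helix(self):
        rec = planted("C1-1")  # generated with QALGGH in its helix
        fingers = scan_fingers(rec)
        present, positions = detect_motif(rec, MOTIF_QALGGH, region="helix", fingers=fingers)
        assert present
        helix_start = fingers[0].c2 + 1
        assert positions == [helix_start]
        # same motif outside any helix is not a Q-type hit
        outside = ProteinRecord("m", "AAAQALGGHAAA" * 3)
        assert not detect_motif(outside, MOTIF_QALGGH, region="helix",
                                fingers=scan_fingers(outside))[0]

    def test_satall_block_at_c_terminus(self):
        rec = planted("A1a")
        assert rec.sequence.endswith(MOTIF_SATALL_BLOCK)
        present, _ = detect_motif(rec, MOTIF_SATALL_BLOCK, region="c_terminal",
                                  fingers=scan_fingers(rec))
        assert present

    def test_satall_prefix_suffices(self):
        assert detect_motif(ProteinRecord("m", "AAASATALLAAA"), "SATALLQKAAQMGS")[0]

    def test_absent_motif(self):
        assert not detect_motif(ProteinRecord("m", "MKLVAAAG"), MOTIF_PCYCC)[0]


class TestClassifyProteome:
    def test_empty_input(self):
        summary, records = classify_proteome([])
        assert summary.n_proteins == 0
        assert summary.set_counts == {}
        assert records == []

    def test_planted_composition_recovered(self):
        records, truth = synthetic.make_proteome(
            [("A1a", 3), ("B", 1), ("C1-1", 6)], seed=5
        )
        summary, _ = classify_proteome(records)
        assert summary.set_counts == {"A": 3, "B": 1, "C": 6}
        assert summary.n_tandem_proteins == 4

    def test_partition_invariant(self, study_proteome):
        records, _ = study_proteome
        summary, per_protein = classify_proteome(records)
        assert sum(summary.set_counts.values()) + summary.n_unclassified == len(records)
        assert sum(summary.subset_counts[s] for s in
                   ["C1-1", "C1-2", "C1-3", "C1-4", "C1-5", "C1C2mixed"]) \
            == summary.subgroup_counts["C1"]
        labels = {r.protein_id: r.set_label for r in per_protein}
        assert len(labels) == len(records)

    def test_unclassified_protein_does_not_abort(self):
        fingerless = ProteinRecord("bare", "MKLVAAAGGG")
        with pytest.warns(UserWarning, match="unclassified"):
            summary, records = classify_proteome([fingerless])
        assert summary.n_unclassified == 1
        assert records[0].set_label == "unclassified"

    def test_flanking_sequence_never_changes_class(self):
        for label in ["A1a", "A2", "B", "C1-2", "C2"]:
            short = synthetic.ARCHITECTURE_TEMPLATES[label]
            long = synthetic.ArchitectureSpec(
                label=short.label,
                finger_signatures=short.finger_signatures,
                linkers=short.linkers,
                has_qalggh=short.has_qalggh,
                has_satall=short.has_satall,
                has_pcycc=short.has_pcycc,
                background_length=(200, 200),
            )
            a = classify_protein(make_protein(short, seed=3, protein_id="s"))
            b = classify_protein(make_protein(long, seed=3, protein_id="l"))
            assert (a.set_label, a.subgroup, a.subset) == (b.set_label, b.subgroup, b.subset)
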