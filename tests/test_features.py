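import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhhkit.alignment import Alignment
from dhhkit.errors import ValidationError
from dhhkit.features import (
    MAX_ENTROPY_BITS,
    CladeFeatureVector,
    ClassifierRules,
    anchor_positions,
    classify_clade,
    column_entropy,
    entropy_table,
    extract_features,
    feature_table,
    linker_class,
    logo_matrix,
)
from dhhkit.sequences import AMINO_ACIDS, ProteinRecord, scan_motifs, segment_domains


class TestAnchorPositions:
    def test_gap_free_identity_mapping(self):
        row = "A" * 300
        aln = Alignment(["ref"], [row])
        anchor = anchor_positions(aln, "ref", (285,))
        assert anchor.column_of_position[285] == 285

    def test_gap_offset(self):
        row = "-----" + "A" * 295
        aln = Alignment(["ref"], [row])
        anchor = anchor_positions(aln, "ref", (285,))
        assert anchor.column_of_position[285] == 290

    def test_position_beyond_length_rejected(self):
        aln = Alignment(["ref"], ["ACDE"])
        with pytest.raises(ValidationError):
            anchor_positions(aln, "ref", (5,))

    def test_missing_reference_rejected(self):
        aln = Alignment(["x"], ["ACDE"])
        with pytest.raises(ValidationError):
            anchor_positions(aln, "ref", (1,))


def _record_with_tail(tail, rid="r"):
    seq = "A" * 100 + "DHH" + "A" * 50 + "GGGH" + "A" * 30 + tail
    rec = ProteinRecord(id=rid, sequence=seq)
    seg = segment_domains(rec, scan_motifs(rec))
    assert seg.cterm_length == len(tail)
    return rec, seg


class TestExtractFeatures:
    def test_tail_charge_statistics(self):
        rec, seg = _record_with_tail("KKRAAE")
        aln = Alignment([rec.id], [rec.sequence])
        anchor = anchor_positions(aln, rec.id, (100,))
        fv = extract_features(rec, seg, anchor, aln, 100)
        assert fv.cterm_positive_fraction == pytest.approx(0.5)
        assert fv.cterm_net_charge == 2
        assert fv.signature_residue == "A"

    def test_empty_tail_conventions(self):
        seq = "A" * 100 + "DHH" + "A" * 50 + "GGGH" + "A" * 30
        rec = ProteinRecord(id="r", sequence=seq)
        seg = segment_domains(rec, scan_motifs(rec))
        aln = Alignment([rec.id], [rec.sequence])
        anchor = anchor_positions(aln, rec.id, (100,))
        fv = extract_features(rec, seg, anchor, aln, 100)
        assert fv.cterm_positive_fraction == 0.0
        assert fv.cterm_net_charge == 0

    def test_gap_at_signature_column(self):
        rec, seg = _record_with_tail("KKRAAE")
        other = ProteinRecord(id="o", sequence=rec.sequence)
        other_seg = segment_domains(other, scan_motifs(other))
        # other row has a gap at the reference's column 100
        ref_row = rec.sequence
        other_row = rec.sequence[:99] + "-" + rec.sequence[100:]
        aln = Alignment([rec.id, "o"], [ref_row, other_row])
        anchor = anchor_positions(aln, rec.id, (100,))
        fv = extract_features(other, other_seg, anchor, aln, 100)
        assert fv.signature_residue == "-"
        call = classify_clade(fv, ClassifierRules(signature_position=100))
        assert "signature_other" not in call.evidence

    def test_absent_record_rejected(self):
        rec, seg = _record_with_tail("KKR")
        aln = Alignment(["zzz"], [rec.sequence])
        anchor = anchor_positions(aln, "zzz", (100,))
        with pytest.raises(ValidationError):
            extract_features(rec, seg, anchor, aln, 100)


def fv(sig="K", ct=120, frac=0.25, linker=100, rid="x"):
    return CladeFeatureVector(
        id=rid,
        linker_length=linker,
        cterm_length=ct,
        signature_residue=sig,
        cterm_positive_fraction=frac,
        cterm_net_charge=0,
    )


class TestClassifyClade:
    def test_clade_a_full_evidence(self):
        call = classify_clade(fv(sig="K", ct=120, frac=0.25))
        assert call.call == "A"
        assert call.scores == {"A": 3, "B": 0, "C": 0}
        assert len(call.evidence) == 3

    def test_clade_b(self):
        call = classify_clade(fv(sig="N", ct=30, frac=0.0))
        assert call.call == "B"
        assert call.scores == {"A": 0, "B": 2, "C": 1}

    def test_clade_c(self):
        call = classify_clade(fv(sig="G", ct=30, frac=0.0))
        assert call.call == "C"
        assert call.scores == {"A": 0, "B": 1, "C": 2}

    def test_margin_tie_unclassified(self):
        call = classify_clade(fv(sig="K", ct=30, frac=0.0))
        assert call.scores == {"A": 1, "B": 1, "C": 1}
        assert call.call == "unclassified"

    def test_all_zero_unclassified(self):
        call = classify_clade(fv(sig="-", ct=75, frac=0.0))
        assert call.call == "unclassified"

    def test_long_tail_boundary_strict(self):
        rules = ClassifierRules()
        at = classify_clade(fv(sig="-", ct=100, frac=0.0), rules)
        above = classify_clade(fv(sig="-", ct=101, frac=0.0), rules)
        assert at.scores["A"] == 0
        assert above.scores["A"] == 1

    def test_short_tail_boundary_strict(self):
        rules = ClassifierRules()
        below = classify_clade(fv(sig="-", ct=49, frac=0.0), rules)
        at = classify_clade(fv(sig="-", ct=50, frac=0.0), rules)
        assert below.scores["B"] == 1
        assert at.scores["B"] == 0

    def test_deterministic_and_total(self):
        for sig, ct, frac in itertools.product(
            ["K", "N", "G", "-"], [10, 50, 100, 150], [0.0, 0.2]
        ):
            a = classify_clade(fv(sig=sig, ct=ct, frac=frac))
            b = classify_clade(fv(sig=sig, ct=ct, frac=frac))
            assert a == b
            assert a.call in {"A", "B", "C", "unclassified"}

    def test_linker_binarization(self):
        assert linker_class(200) == "short"
        assert linker_class(201) == "long"


class TestColumnEntropy:
    def test_single_residue_zero_bits(self):
        aln = Alignment(list("abcd"), ["A", "A", "A", "A"])
        profile = column_entropy(aln)
        assert profile.entropy_bits[0] == pytest.approx(0.0)

    def test_two_equiprobable_one_bit(self):
        aln = Alignment(list("abcd"), ["A", "A", "K", "K"])
        profile = column_entropy(aln)
        assert profile.entropy_bits[0] == pytest.approx(1.0)

    def test_uniform_maximum(self):
        aln = Alignment([f"r{i}" for i in range(20)], list(AMINO_ACIDS))
        profile = column_entropy(aln)
        assert profile.entropy_bits[0] == pytest.approx(math.log2(20))

    def test_gap_fraction_tracked(self):
        aln = Alignment(list("abcd"), ["A", "-", "A", "-"])
        profile = column_entropy(aln)
        assert profile.gap_fraction[0] == pytest.approx(0.5)
        assert profile.entropy_bits[0] == pytest.approx(0.0)

    def test_all_gap_flagged(self):
        aln = Alignment(list("ab"), ["-A", "-A"])
        profile = column_entropy(aln)
        assert profile.all_gap[0]
        assert not profile.all_gap[1]

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.text(alphabet=AMINO_ACIDS + "-", min_size=6, max_size=6),
            min_size=1,
            max_size=8,
        )
    )
    def test_bounds_and_normalization(self, rows):
        aln = Alignment([f"r{i}" for i in range(len(rows))], rows)
        profile = column_entropy(aln)
        assert np.all(profile.entropy_bits >= -1e-12)
        assert np.all(profile.entropy_bits <= MAX_ENTROPY_BITS + 1e-12)
        sums = profile.frequencies.sum(axis=1)
        for total, empty in zip(sums, profile.all_gap):
            assert total == pytest.approx(0.0 if empty else 1.0)


class TestLogoMatrix:
    def test_fully_conserved_height(self):
        aln = Alignment(list("abcd"), ["A", "A", "A", "A"])
        logo = logo_matrix(aln)
        assert logo.loc[1, "A"] == pytest.approx(math.log2(20))

    def test_half_split_heights(self):
        aln = Alignment(list("abcd"), ["A", "A", "K", "K"])
        logo = logo_matrix(aln)
        expected = 0.5 * (math.log2(20) - 1.0)
        assert logo.loc[1, "A"] == pytest.approx(expected)
        assert logo.loc[1, "K"] == pytest.approx(expected)

    def test_single_member_restriction(self):
        aln = Alignment(["a", "b"], ["AK", "CK"])
        logo = logo_matrix(aln, clade_members={"a"})
        assert logo.loc[1, "A"] == pytest.approx(math.log2(20))

    def test_empty_member_set_rejected(self):
        aln = Alignment(["a"], ["AK"])
        with pytest.raises(ValidationError):
            logo_matrix(aln, clade_members={"zzz"})

    def test_all_gap_columns_dropped(self):
        aln = Alignment(["a", "b"], ["-A", "-C"])
        logo = logo_matrix(aln)
        assert list(logo.index) == [2]


class TestTables:
    def test_feature_table_columns(self):
        vec = fv()
        call = classify_clade(vec)
        table = feature_table([vec], [call])
        assert table.loc[0, "call"] == "A"
        assert table.loc[0, "linker_class"] == "short"

    def test_entropy_table_shape(self):
        aln = Alignment(list("ab"), ["AK", "AC"])
        table = entropy_table(aln)
        assert list(table.columns) == [
            "column",
            "entropy_bits",
            "information_bits",
            "gap_fraction",
            "all_gap",
        ]
        assert len(table) == 2


class TestPipelineClassification:
    def test_accuracy_on_default_dataset(self, pipeline_result, default_dataset):
        calls = pipeline_result.calls
        labels = default_dataset.labels
        correct = sum(1 for c in calls if c.call == labels[c.id])
        assert correct / len(calls) >= 0.95
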