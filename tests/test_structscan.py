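import numpy as np
import pytest

from plastoscan import Alignment
from plastoscan.structscan import (
    ArrangementSpec,
    classify_read_pairs,
    classify_spanning_pairs,
    identity_windows,
    map_read,
    pairs_from_sam,
    reorient_segment,
    revcomp,
)
from plastoscan.seqsim import (
    simulate_alignment,
    simulate_arrangement_spec,
    simulate_ir_library,
    default_model,
)
from plastoscan.treelik import parse_newick
from plastoscan.substmodel import JC69


def toy_spec():
    """60 bp genome, two 5 bp IR copies flanking a 20 bp segment."""
    left = "TTTTTTTTTT"                      # 1-10
    ir = "ACGCA"                             # 11-15
    middle = "GGATCCGGAATTCCGGATCC"          # 16-35
    ir_rc = revcomp(ir)                      # 36-40
    right = "CCCCCCCCCCCCCCCCCCCC"           # 41-60
    return ArrangementSpec(left + ir + middle + ir_rc + right, (11, 15), (36, 40))


class TestReorient:
    def test_matches_hand_built_string(self):
        spec = toy_spec()
        out = reorient_segment(spec.genome, spec)
        expected = (
            "TTTTTTTTTT" + "ACGCA" + revcomp("GGATCCGGAATTCCGGATCC")
            + revcomp("ACGCA")[::-1][::-1] + "C" * 20
        )
        # flipping [11, 40] maps IR2 onto revcomp(IR1) == IR2's own sequence
        assert out[:10] == spec.genome[:10]
        assert out[40:] == spec.genome[40:]
        assert out[10:15] == spec.genome[10:15]   # IR1 unchanged
        assert out[35:40] == spec.genome[35:40]   # IR2 unchanged
        assert out[15:35] == revcomp(spec.genome[15:35])
        assert out == expected[:60]

    def test_involution_and_length(self):
        spec = toy_spec()
        once = reorient_segment(spec.genome, spec)
        assert len(once) == len(spec.genome)
        assert reorient_segment(once, spec) == spec.genome

    def test_bad_coordinates_rejected(self):
        with pytest.raises(ValueError):
            ArrangementSpec("ACGTACGT", (1, 2), (7, 9))

    def test_non_ir_copies_rejected(self):
        with pytest.raises(ValueError, match="reverse complement"):
            ArrangementSpec("AAAACCCCGGGGTTTT", (1, 4), (9, 12))

    def test_config_round_trip(self):
        spec = toy_spec()
        again = ArrangementSpec.from_config(spec.to_config(), spec.genome)
        assert (again.ir1, again.ir2) == (spec.ir1, spec.ir2)


class TestMapper:
    def test_finds_forward_and_reverse_placements(self):
        ref = "AAGGCCTTACGT"
        assert map_read("GGCC", ref) == [(2, 6, 1), (2, 6, -1)]  # palindromic
        # AAGG occurs forward at 0; its reverse complement CCTT at 4
        assert map_read("AAGG", ref) == [(0, 4, 1), (4, 8, -1)]
        assert map_read("CCTT", ref) == [(4, 8, 1), (0, 4, -1)]
        assert map_read("GGGG", ref) == []


class TestClassification:
    def test_pure_source_has_no_opposite_support(self):
        spec = simulate_arrangement_spec(seed=1)
        pairs, _ = simulate_ir_library(spec, fraction_B=0.0, n_pairs=300,
                                       seed=2, span_only=True)
        ev = classify_read_pairs(pairs, spec)
        assert ev.supports_B == 0
        assert ev.supports_A > 250
        assert ev.ambiguous <= 5

    def test_mixture_fraction_recovered(self):
        spec = simulate_arrangement_spec(seed=1)
        pairs, truth = simulate_ir_library(spec, fraction_B=0.976,
                                           n_pairs=834, seed=3, span_only=True)
        ev = classify_read_pairs(pairs, spec)
        n_true_a = sum(1 for v in truth.values() if v == "A")
        assert ev.supports_A == n_true_a
        # a handful of pairs may fall outside the 4-sigma insert bounds
        assert 825 <= ev.total <= 834

    def test_reads_confined_to_ir_are_not_spanning(self):
        spec = toy_spec()
        # both mates inside the 5 bp IR (shorter than min_flank)
        pairs = [("p1", spec.genome[10:14], revcomp(spec.genome[11:15]))]
        ev = classify_read_pairs(pairs, spec, min_flank=3, insert_bounds=(0, 30))
        assert ev.total == 0

    def test_invariant_to_read_order_and_mate_swap(self):
        spec = simulate_arrangement_spec(seed=4)
        pairs, _ = simulate_ir_library(spec, fraction_B=0.5, n_pairs=120,
                                       seed=5, span_only=True)
        ev = classify_read_pairs(pairs, spec)
        shuffled = [(r, m2, m1) for r, m1, m2 in reversed(pairs)]
        ev2 = classify_read_pairs(shuffled, spec)
        assert (ev.supports_A, ev.supports_B) == (ev2.supports_A, ev2.supports_B)

    def test_missing_mate_skipped_and_counted(self):
        spec = simulate_arrangement_spec(seed=4)
        pairs, _ = simulate_ir_library(spec, fraction_B=1.0, n_pairs=10,
                                       seed=6, span_only=True)
        mapped_a = {r: (map_read(m1, spec.seq_A), []) for r, m1, m2 in pairs}
        mapped_b = {r: (map_read(m1, spec.seq_B), []) for r, m1, m2 in pairs}
        ev = classify_spanning_pairs(mapped_a, mapped_b, spec,
                                     insert_bounds=(200, 600))
        assert ev.total == 0
        assert ev.n_skipped == 10

    def test_sam_round_trip(self, tmp_path):
        spec = simulate_arrangement_spec(seed=7)
        pairs, _ = simulate_ir_library(spec, fraction_B=0.0, n_pairs=40,
                                       seed=8, span_only=True)
        sams = {}
        for ref_name, ref in (("A", spec.seq_A), ("B", spec.seq_B)):
            lines = [
                "@HD\tVN:1.6\tSO:unsorted",
                f"@SQ\tSN:genome_{ref_name}\tLN:{len(ref)}",
            ]
            for rid, m1, m2 in pairs:
                for mate_i, seq in ((1, m1), (2, m2)):
                    hits = map_read(seq, ref)
                    for start, end, strand in hits:
                        flag = 1 | (64 if mate_i == 1 else 128)
                        if strand == -1:
                            flag |= 16
                            seq_out = revcomp(seq)
                        else:
                            seq_out = seq
                        lines.append(
                            f"{rid}\t{flag}\tgenome_{ref_name}\t{start + 1}\t60"
                            f"\t{len(seq)}M\t*\t0\t0\t{seq_out}\t*"
                        )
            path = tmp_path / f"{ref_name}.sam"
            path.write_text("\n".join(lines) + "\n")
            sams[ref_name] = pairs_from_sam(path)
        ev_sam = classify_spanning_pairs(sams["A"], sams["B"], spec)
        ev_direct = classify_read_pairs(pairs, spec)
        assert ev_sam.supports_A == ev_direct.supports_A
        assert ev_sam.supports_B == ev_direct.supports_B == 0


class TestIdentityWindows:
    def test_identical_rows_are_100_percent(self):
        aln = Alignment.from_sequences(["a", "b", "c"],
                                       ["ACGT" * 300, "ACGT" * 300, "TTTT" * 300])
        _, _, ident = identity_windows(aln, "a", "b", window=400, step=400)
        assert np.allclose(ident, 100.0)

    def test_single_mismatch_arithmetic(self):
        s = "A" * 1000
        t = "A" * 499 + "C" + "A" * 500
        aln = Alignment.from_sequences(["a", "b"], [s, t])
        _, _, ident = identity_windows(aln, "a", "b", window=1000, step=1000)
        assert ident[0] == pytest.approx(99.9)

    def test_gapped_columns_excluded_and_sparse_windows_missing(self):
        s = "ACGT" * 25
        t = "-" * 96 + s[96:]
        aln = Alignment.from_sequences(["a", "b"], [s, t])
        _, _, ident = identity_windows(aln, "a", "b", window=100, step=100,
                                       min_comparable=0.10)
        assert np.isnan(ident[0])  # only 4 comparable columns

    def test_symmetric_in_rows(self):
        aln = Alignment.from_sequences(
            ["a", "b"], ["ACGTAC" * 200, "ACTTAC" * 200]
        )
        _, _, i1 = identity_windows(aln, "a", "b", window=300, step=300)
        _, _, i2 = identity_windows(aln, "b", "a", window=300, step=300)
        assert np.allclose(i1, i2)

    def test_same_taxon_rejected(self, toy_alignment):
        with pytest.raises(ValueError):
            identity_windows(toy_alignment, "t1", "t1", window=2, step=2)

    def test_divergence_matches_jc_expectation(self):
        # 2-taxon JC tree, path length 0.05
        tree = parse_newick("(A:0.025,B:0.025);")
        aln = simulate_alignment(tree, JC69, 50000, seed=17)
        _, _, ident = identity_windows(aln, "A", "B", window=1000, step=1000)
        expected = 100.0 * (1 - 0.75 * (1 - np.exp(-4 * 0.05 / 3)))
        assert abs(np.nanmean(ident) - expected) < 1.0
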