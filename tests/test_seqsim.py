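import numpy as np
import pytest

from plastoscan.conflictscan import call_regions, delta_profile, window_scan
from plastoscan.seqsim import (
    ChimeraSpec,
    alternative_topology,
    backbone_topology,
    default_model,
    inject_indels,
    simulate_alignment,
    simulate_chimera,
    simulate_ir_library,
    simulate_arrangement_spec,
    write_fastq,
)
from plastoscan.substmodel import JC69
from plastoscan.treelik import parse_newick, site_loglik
from plastoscan.alnfilter import gap_column_fraction


class TestSimulateAlignment:
    def test_zero_length_tree_gives_identical_rows(self):
        tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = simulate_alignment(tree, default_model(), 500, seed=1)
        assert all((aln.data[0] == aln.data[i]).all() for i in range(4))

    def test_reproducible_under_seed(self):
        tree = backbone_topology()
        a = simulate_alignment(tree, default_model(), 1000, seed=9)
        b = simulate_alignment(tree, default_model(), 1000, seed=9)
        assert (a.data == b.data).all()
        c = simulate_alignment(tree, default_model(), 1000, seed=10)
        assert (a.data != c.data).any()

    def test_base_frequencies_near_stationary(self):
        tree = backbone_topology()
        model = default_model()
        aln = simulate_alignment(tree, model, 100000, seed=2)
        freqs = [(aln.data == k).mean() for k in range(4)]
        assert np.allclose(freqs, model.freqs, atol=0.005)

    def test_pairwise_distance_matches_jc_closed_form(self):
        tree = parse_newick("(A:0.05,B:0.05);")
        aln = simulate_alignment(tree, JC69, 100000, seed=3)
        mismatch = (aln.data[0] != aln.data[1]).mean()
        expected = 0.75 * (1 - np.exp(-4 * 0.1 / 3))
        se = np.sqrt(expected * (1 - expected) / 100000)
        assert abs(mismatch - expected) < 3 * se


class TestChimera:
    def test_zero_width_segment_equals_backbone_simulation(self):
        spec = ChimeraSpec(seed=5, length=2000, segment=(1000, 999))
        aln, truth = simulate_chimera(spec)
        plain = simulate_alignment(spec.backbone, spec.model, 2000, seed=5)
        assert (aln.data == plain.data).all()
        assert truth["segment"] == [1000, 999]

    def test_topologies_share_leaf_set(self):
        assert set(backbone_topology().leaf_labels) == \
            set(alternative_topology().leaf_labels)
        with pytest.raises(ValueError):
            ChimeraSpec(backbone=parse_newick("(A:1,B:1);"),
                        alternative=parse_newick("(A:1,C:1);"),
                        segment=(10, 20), length=100)

    def test_segment_signal_has_opposite_sign(self):
        spec = ChimeraSpec(seed=6, length=40000, segment=(10000, 20000))
        aln, _ = simulate_chimera(spec)
        p_alt = site_loglik(aln, spec.alternative, spec.model, "alt")
        p_back = site_loglik(aln, spec.backbone, spec.model, "back")
        d = delta_profile(p_alt, p_back)
        inside = d.delta[9999:20000].mean()
        outside = np.delete(d.delta, np.s_[9999:20000]).mean()
        assert inside > 0 > outside

    def test_identical_topologies_look_like_plain_simulation(self):
        # site-pattern frequency distributions should be indistinguishable
        from collections import Counter
        from scipy.stats import chi2_contingency

        tree = backbone_topology()
        spec = ChimeraSpec(backbone=tree, alternative=tree.copy(), seed=7,
                           length=20000, segment=(5000, 15000))
        chim, _ = simulate_chimera(spec)
        plain = simulate_alignment(tree, spec.model, 20000, seed=117)

        def pattern_counts(aln):
            return Counter(map(bytes, aln.data.T))

        c1, c2 = pattern_counts(chim), pattern_counts(plain)
        keys = [k for k in set(c1) | set(c2) if c1[k] + c2[k] >= 10]
        rows = np.array([
            [c1[k] for k in keys] + [sum(c1.values()) - sum(c1[k] for k in keys)],
            [c2[k] for k in keys] + [sum(c2.values()) - sum(c2[k] for k in keys)],
        ])
        p = chi2_contingency(rows).pvalue
        assert p > 0.01

    def test_truth_bed_is_zero_based(self):
        spec = ChimeraSpec(seed=1, length=1000, segment=(101, 200))
        assert spec.truth_bed().split("\t")[1:3] == ["100", "200"]


class TestInjectIndels:
    def test_rate_zero_is_identity(self):
        aln = simulate_alignment(backbone_topology(), default_model(), 500, seed=8)
        out = inject_indels(aln, rate=0.0, seed=9)
        assert (out.data == aln.data).all()

    def test_gapped_column_count_near_expectation(self):
        aln = simulate_alignment(backbone_topology(), default_model(), 20000, seed=10)
        rate, mean_len, n = 0.001, 4.0, aln.n_taxa
        out = inject_indels(aln, rate=rate, mean_length=mean_len, seed=11)
        frac = gap_column_fraction(out)
        # a column escapes gaps if no run from any taxon covers it;
        # run start coverage per taxon-column ~ rate * mean_len
        p_col = 1.0 - (1.0 - rate * mean_len) ** n
        se = np.sqrt(p_col * (1 - p_col) / 20000)
        assert abs(frac - p_col) < 0.3 * p_col + 3 * se

    def test_hotspot_multiplier_enriches_gaps(self):
        hits = 0
        for seed in range(30):
            aln = simulate_alignment(backbone_topology(), default_model(),
                                     4000, seed=100 + seed)
            out = inject_indels(aln, rate=0.002,
                                hotspots=[((1001, 3000), 4.0)], seed=seed)
            inside = out.take_columns(np.arange(1000, 3000))
            outside = out.take_columns(np.r_[0:1000, 3000:4000])
            if gap_column_fraction(inside) > gap_column_fraction(outside):
                hits += 1
        assert hits >= 28

    def test_rows_keep_length(self):
        aln = simulate_alignment(backbone_topology(), default_model(), 300, seed=12)
        out = inject_indels(aln, rate=0.05, seed=13)
        assert out.data.shape == aln.data.shape

    def test_invalid_rate_rejected(self):
        aln = simulate_alignment(backbone_topology(), default_model(), 10, seed=1)
        with pytest.raises(ValueError):
            inject_indels(aln, rate=0.9)


class TestIRLibrary:
    def test_truth_labels_cover_every_pair(self):
        spec = simulate_arrangement_spec(seed=1)
        pairs, truth = simulate_ir_library(spec, fraction_B=0.3, n_pairs=50, seed=2)
        assert len(pairs) == 50
        assert set(truth) == {rid for rid, _, _ in pairs}
        assert set(truth.values()) <= {"A", "B"}

    def test_fastq_files_have_two_lines_per_read(self, tmp_path):
        spec = simulate_arrangement_spec(seed=1)
        pairs, _ = simulate_ir_library(spec, fraction_B=0.5, n_pairs=20, seed=3)
        f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq(pairs, f1, f2)
        assert len(f1.read_text().splitlines()) == 80
        assert len(f2.read_text().splitlines()) == 80

    def test_insert_below_read_length_rejected(self):
        spec = simulate_arrangement_spec(seed=1)
        with pytest.raises(ValueError):
            simulate_ir_library(spec, fraction_B=0.5, n_pairs=5,
                                read_len=150, insert_mean=100.0)

    def test_reproducible(self):
        spec = simulate_arrangement_spec(seed=1)
        a, _ = simulate_ir_library(spec, fraction_B=0.4, n_pairs=30, seed=5)
        b, _ = simulate_ir_library(spec, fraction_B=0.4, n_pairs=30, seed=5)
        assert a == b


class TestEndToEndScan:
    def test_chimera_recovered_at_reduced_scale(self):
        # 40 kb genome with a 8 kb alternative-topology segment
        spec = ChimeraSpec(seed=42, length=40000, segment=(15000, 23000))
        aln, _ = simulate_chimera(spec)
        p_alt = site_loglik(aln, spec.alternative, spec.model, "alt")
        p_back = site_loglik(aln, spec.backbone, spec.model, "back")
        scan = window_scan(delta_profile(p_alt, p_back), 2000, 40)
        regions = call_regions(scan)
        assert len(regions) == 1
        assert regions[0].direction == "alt"
        assert abs(regions[0].start - 15000) <= 1000
        assert abs(regions[0].end - 23000) <= 1000
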