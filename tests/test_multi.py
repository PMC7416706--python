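import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from repkit import (
    ValidationError,
    build_repertoire,
    clonal_space_homeostasis,
    cluster_samples,
    clonotype_tracking,
    compare_groups,
    compare_homeostasis,
    diversity,
    rarefied_diversity,
    similarity_matrix,
)
from repkit.multi import (
    DEFAULT_BIN_EDGES,
    SIMILARITY_INDICES,
    SimilarityMatrix,
    benjamini_hochberg,
    pair_similarity,
)
from repkit.simulate import (
    LongitudinalScript,
    SimulationParams,
    TimepointSpec,
    simulate_longitudinal,
)
import oracles
from conftest import make_sim, rec


def freq_rep(freq_count, sample_id="x"):
    """Build a repertoire with exact frequencies from (count) integers."""
    rows = [
        rec(nt=f"{'ACGT'[i % 4] * 3}{'ACGT'[i // 4 % 4] * 3}{i:03d}".replace(
            "0", "A").replace("1", "C").replace("2", "G").replace(
            "3", "T").replace("4", "A").replace("5", "C").replace(
            "6", "G").replace("7", "T").replace("8", "A").replace("9", "C"),
            aa=f"X{i}", count=c)
        for i, c in enumerate(freq_count)
    ]
    return build_repertoire(rows, "nt", sample_id=sample_id)


class TestHomeostasis:
    def test_direct_binning(self):
        rep = freq_rep([50, 30, 15, 5])  # freqs 0.5, 0.3, 0.15, 0.05
        prof = clonal_space_homeostasis(rep)
        by_label = dict(zip(prof.bin_labels, prof.mass_per_bin))
        assert by_label["hyperexpanded"] == pytest.approx(0.95)
        assert by_label["expanded"] == pytest.approx(0.05)
        assert sum(v for k, v in by_label.items()
                   if k not in ("hyperexpanded", "expanded")) == 0

    def test_single_clone_top_bin(self):
        prof = clonal_space_homeostasis(freq_rep([100]))
        assert prof.mass_per_bin[-1] == pytest.approx(1.0)
        assert prof.reads_per_bin[-1] == 100

    def test_edge_inclusive_upper(self):
        # freq exactly 0.1 belongs to (0.01, 0.1], not the hyperexpanded bin
        rep = freq_rep([10, 90])
        prof = clonal_space_homeostasis(rep)
        by_label = dict(zip(prof.bin_labels, prof.mass_per_bin))
        assert by_label["expanded"] == pytest.approx(0.1)
        assert by_label["hyperexpanded"] == pytest.approx(0.9)

    def test_brute_force_scan(self):
        rep = make_sim(61, n_clones=400, depth=20000)
        prof = clonal_space_homeostasis(rep)
        mass, reads = oracles.brute_homeostasis(
            [(r.freq, r.count) for r in rep.records], DEFAULT_BIN_EDGES)
        assert list(prof.mass_per_bin) == pytest.approx(mass, abs=1e-12)
        assert list(prof.reads_per_bin) == reads

    def test_mass_and_reads_conserved(self):
        for seed in range(5):
            rep = make_sim(70 + seed)
            prof = clonal_space_homeostasis(rep)
            assert sum(prof.mass_per_bin) == pytest.approx(1.0, abs=1e-9)
            assert sum(prof.reads_per_bin) == rep.total_reads

    def test_invalid_edges(self):
        rep = freq_rep([1])
        with pytest.raises(ValidationError):
            clonal_space_homeostasis(rep, bin_edges=(0.5, 0.2, 1.0))
        with pytest.raises(ValidationError):
            clonal_space_homeostasis(rep, bin_edges=(0.5, 0.9))  # must end at 1


class TestCompareHomeostasis:
    def _profile(self, reads, sample_id="p"):
        # synthetic profile with given per-bin reads
        from repkit.multi import HomeostasisProfile

        total = sum(reads)
        return HomeostasisProfile(
            sample_id=sample_id,
            bin_edges=tuple(DEFAULT_BIN_EDGES[: len(reads) - 1]) + (1.0,),
            bin_labels=tuple(f"b{i}" for i in range(len(reads))),
            mass_per_bin=tuple(r / total for r in reads),
            reads_per_bin=tuple(reads),
        )

    def test_hand_evaluated_chi2(self):
        chi2, df, p = compare_homeostasis(self._profile([10, 20]), self._profile([20, 10]))
        assert chi2 == pytest.approx(6.6667, abs=5e-5)
        assert df == 1
        ref_chi2, ref_df = oracles.brute_chi2([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(ref_chi2, abs=1e-12)

    def test_identical_profiles(self):
        prof = self._profile([5, 10, 15])
        chi2, df, p = compare_homeostasis(prof, prof)
        assert chi2 == 0.0 and p == 1.0

    def test_simulated_pair_matches_reference(self):
        a = clonal_space_homeostasis(make_sim(81, n_clones=200, depth=8000))
        b = clonal_space_homeostasis(make_sim(82, n_clones=200, depth=8000))
        chi2, df, p = compare_homeostasis(a, b)
        table = [list(a.reads_per_bin), list(b.reads_per_bin)]
        keep = [i for i in range(len(table[0])) if table[0][i] + table[1][i] > 0]
        table = [[row[i] for i in keep] for row in table]
        ref_chi2, _ = oracles.brute_chi2(table)
        ref_p = float(sps.chi2.sf(ref_chi2, df))
        assert chi2 == pytest.approx(ref_chi2, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)

    def test_empty_bins_dropped_df_reduced(self):
        chi2, df, p = compare_homeostasis(
            self._profile([10, 20, 0]), self._profile([20, 10, 0]))
        assert df == 1

    def test_single_bin_undefined(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            compare_homeostasis(self._profile([10, 0]), self._profile([20, 0]))

    def test_different_edges_rejected(self):
        with pytest.raises(ValidationError, match="bin edges"):
            compare_homeostasis(self._profile([10, 20]), self._profile([1, 2, 3]))


class TestTracking:
    def test_two_samples_single_clone(self):
        a = freq_rep([10, 90], "a")
        b = freq_rep([1, 99], "b")
        m = clonotype_tracking([a, b], n=1, key_mode="nt")
        assert m.values.shape == (1, 2)
        assert m.values[0, 0] == pytest.approx(0.9)
        assert m.values[0, 1] == pytest.approx(0.99)

    def test_absent_clone_zero(self):
        a = build_repertoire([rec(nt="AAATTT", aa="KF", count=1)], "nt", sample_id="a")
        b = build_repertoire([rec(nt="CCCGGG", aa="PG", count=1)], "nt", sample_id="b")
        m = clonotype_tracking([a, b], n=5, key_mode="nt")
        assert (m.values == 0).sum() == 2  # each clone absent from one sample

    def test_anchor_selection(self):
        a = freq_rep([60, 40], "a")
        b = freq_rep([5, 95], "b")
        m = clonotype_tracking([a, b], select="top_n_from_sample", n=1,
                               anchor="b", key_mode="nt")
        assert m.values[0, 1] == pytest.approx(0.95)

    def test_missing_anchor_rejected(self):
        a, b = freq_rep([1], "a"), freq_rep([1], "b")
        with pytest.raises(ValidationError, match="anchor"):
            clonotype_tracking([a, b], select="top_n_from_sample", n=1,
                               anchor="zzz", key_mode="nt")

    def test_longitudinal_pattern_recovered(self):
        base = SimulationParams(n_clones=100, depth=20000, alpha=1.0, seed=90)
        tps = [
            TimepointSpec("t1"),
            TimepointSpec("t2", {i: 10.0 for i in range(5)}),
            TimepointSpec("t3"),
            TimepointSpec("t4", {i: 0.2 for i in range(5)}),
            TimepointSpec("t5"),
        ]
        reps = simulate_longitudinal(LongitudinalScript(base=base, timepoints=tps))
        m = clonotype_tracking(reps, n=5, key_mode="nt+vj")
        assert m.sample_ids == ["t1", "t2", "t3", "t4", "t5"]
        for row in m.values:
            assert int(np.argmax(row)) == 1  # every tracked clone peaks at t2
            assert row[3] < row[2]  # contraction at t4


class TestSimilarity:
    def test_self_similarity_one(self):
        a = make_sim(101, sample_id="a")
        b = make_sim(101, sample_id="b")
        for index in SIMILARITY_INDICES:
            assert pair_similarity(a, b, index) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_zero(self):
        a = build_repertoire([rec(nt="AAATTT", aa="KF")], "nt", sample_id="a")
        b = build_repertoire([rec(nt="CCCGGG", aa="PG")], "nt", sample_id="b")
        for index in SIMILARITY_INDICES:
            assert pair_similarity(a, b, index) == 0.0

    def test_jaccard_enumeration(self):
        a = freq_rep([1, 1, 1], "a")       # clones 0,1,2
        b_rows = freq_rep([1, 1, 1, 1], "b").records[:]
        # construct {b,c,d}: drop clone 0, keep 1,2, add new
        a_keys = freq_rep([1, 1, 1], "a")
        b = build_repertoire(
            a_keys.records[1:] + [rec(nt="GGGGGGAAA", aa="GGK", count=1)],
            "nt", sample_id="b")
        assert pair_similarity(a_keys, b, "jaccard") == pytest.approx(0.5)

    def test_oracle_equivalence(self):
        a = make_sim(103, sample_id="a")
        b = make_sim(104, sample_id="b")
        fa, fb = a.freq_by_key(), b.freq_by_key()
        assert pair_similarity(a, b, "jaccard") == pytest.approx(
            oracles.brute_jaccard(fa, fb), abs=1e-10)
        assert pair_similarity(a, b, "overlap_coefficient") == pytest.approx(
            oracles.brute_overlap_coefficient(fa, fb), abs=1e-10)
        assert pair_similarity(a, b, "morisita_horn") == pytest.approx(
            oracles.brute_morisita_horn(fa, fb), abs=1e-10)
        assert pair_similarity(a, b, "bhattacharyya") == pytest.approx(
            oracles.brute_bhattacharyya(fa, fb), abs=1e-10)

    def test_matrix_symmetric_unit_diagonal(self):
        reps = [make_sim(110 + i, sample_id=f"s{i}") for i in range(4)]
        for index in SIMILARITY_INDICES:
            m = similarity_matrix(reps, index)
            assert np.allclose(m.values, m.values.T)
            assert np.allclose(np.diag(m.values), 1.0, atol=1e-9)
            assert ((m.values >= -1e-12) & (m.values <= 1 + 1e-12)).all()

    def test_jaccard_le_overlap_coefficient(self):
        for seed in range(5):
            a = make_sim(120 + seed, sample_id="a")
            b = make_sim(140 + seed, sample_id="b")
            assert (pair_similarity(a, b, "jaccard")
                    <= pair_similarity(a, b, "overlap_coefficient") + 1e-12)

    def test_unknown_index_lists_options(self):
        a, b = make_sim(1, sample_id="a"), make_sim(2, sample_id="b")
        with pytest.raises(ValidationError, match="morisita_horn"):
            similarity_matrix([a, b], "nope")


class TestClusterSamples:
    def _matrix(self, labels, values):
        return SimilarityMatrix(index_name="test", sample_ids=labels,
                                values=np.array(values, dtype=float))

    def test_two_samples_single_merge(self):
        m = self._matrix(["A", "B"], [[1.0, 0.4], [0.4, 1.0]])
        tree = cluster_samples(m)
        assert tree.merges == [("A", "B", pytest.approx(0.6))]
        assert tree.newick == "(A:0.6,B:0.6);"

    def test_closest_pair_merged_first(self):
        m = self._matrix(
            ["A", "B", "C"],
            [[1.0, 0.9, 0.2], [0.9, 1.0, 0.3], [0.2, 0.3, 1.0]],
        )
        tree = cluster_samples(m)
        assert tree.merges[0][:2] == ("A", "B")

    @pytest.mark.parametrize("link", ["average", "complete", "single"])
    def test_matches_scipy_heights(self, link):
        rng = np.random.default_rng(7)
        n = 6
        raw = rng.uniform(0.1, 0.9, size=(n, n))
        sim = (raw + raw.T) / 2
        np.fill_diagonal(sim, 1.0)
        labels = [f"s{i}" for i in range(n)]
        tree = cluster_samples(self._matrix(labels, sim), link)
        ref = scipy_linkage(squareform(1.0 - sim, checks=False), method=link)
        assert sorted(h for _, _, h in tree.merges) == pytest.approx(
            sorted(ref[:, 2].tolist()), abs=1e-10)

    def test_matches_brute_oracle(self):
        rng = np.random.default_rng(13)
        n = 6
        raw = rng.uniform(0.1, 0.9, size=(n, n))
        sim = (raw + raw.T) / 2
        np.fill_diagonal(sim, 1.0)
        labels = [f"s{i}" for i in range(n)]
        dist = (1.0 - sim).tolist()
        for link in ("average", "complete", "single"):
            tree = cluster_samples(self._matrix(labels, sim), link)
            ref = oracles.brute_agglomerate(labels, dist, link)
            assert [(a, b) for a, b, _ in tree.merges] == [(a, b) for a, b, _ in ref]
            assert [h for _, _, h in tree.merges] == pytest.approx(
                [h for _, _, h in ref], abs=1e-12)

    def test_nonfinite_rejected(self):
        m = self._matrix(["A", "B"], [[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValidationError, match="non-finite"):
            cluster_samples(m)


class TestDiversity:
    def test_uniform_closed_form(self):
        rep = freq_rep([25, 25, 25, 25])
        assert diversity(rep, "shannon").value == pytest.approx(math.log(4), abs=1e-12)
        assert diversity(rep, "inverse_simpson").value == pytest.approx(4.0, abs=1e-12)
        assert diversity(rep, "clonality").value == pytest.approx(0.0, abs=1e-12)
        assert diversity(rep, "normalized_shannon").value == pytest.approx(1.0, abs=1e-12)

    def test_single_clone(self):
        rep = freq_rep([10])
        assert diversity(rep, "shannon").value == 0.0
        assert diversity(rep, "clonality").value == 1.0
        assert diversity(rep, "normalized_shannon").value == 0.0
        assert diversity(rep, "inverse_simpson").value == pytest.approx(1.0)

    def test_direct_summation(self):
        rep = freq_rep([70, 20, 10])
        assert diversity(rep, "shannon").value == pytest.approx(0.801819, abs=1e-6)

    def test_chao1_formula(self):
        # S=10, f1=3, f2=2 -> 10 + 9/4 = 12.25
        counts = [1, 1, 1, 2, 2, 3, 4, 5, 6, 7]
        rep = freq_rep(counts)
        assert diversity(rep, "chao1").value == pytest.approx(12.25)

    def test_chao1_bias_corrected_no_doubletons(self):
        counts = [1, 1, 1, 3, 4]  # f1=3, f2=0 -> 5 + 3*2/2 = 8
        rep = freq_rep(counts)
        assert diversity(rep, "chao1").value == pytest.approx(8.0)

    def test_oracle_equivalence(self):
        rep = make_sim(150, n_clones=200, depth=6000)
        freqs = [r.freq for r in rep.records]
        counts = [r.count for r in rep.records]
        assert diversity(rep, "shannon").value == pytest.approx(
            oracles.brute_shannon(freqs), abs=1e-10)
        assert diversity(rep, "gini_simpson").value == pytest.approx(
            oracles.brute_gini_simpson(freqs), abs=1e-10)
        assert diversity(rep, "chao1").value == pytest.approx(
            oracles.brute_chao1(counts), abs=1e-10)
        assert diversity(rep, "d50").value == oracles.brute_d50(freqs)

    def test_bounds(self):
        for seed in range(5):
            rep = make_sim(160 + seed, alpha=1.5)
            s = rep.n_clones
            h = diversity(rep, "shannon").value
            inv = diversity(rep, "inverse_simpson").value
            assert 0 <= h <= math.log(s) + 1e-12
            assert 1 - 1e-12 <= inv <= s + 1e-12
            assert 0 <= diversity(rep, "clonality").value <= 1


class TestRarefiedDiversity:
    def test_full_depth_equals_plain(self, sim_rep):
        plain = diversity(sim_rep, "shannon").value
        rare = rarefied_diversity(sim_rep, "shannon", sim_rep.total_reads, 5, seed=1)
        assert rare.rarefaction.mean == pytest.approx(plain, abs=1e-12)
        assert rare.rarefaction.sd == 0.0

    def test_deterministic(self, sim_rep):
        a = rarefied_diversity(sim_rep, "shannon", 1000, 10, seed=9)
        b = rarefied_diversity(sim_rep, "shannon", 1000, 10, seed=9)
        assert a.rarefaction.mean == b.rarefaction.mean
        assert a.rarefaction.sd == b.rarefaction.sd

    def test_uniform_within_monte_carlo_band(self):
        from repkit import downsample

        rep = freq_rep([20] * 50)  # uniform, 50 clones
        depth = rep.total_reads // 2
        rare = rarefied_diversity(rep, "shannon", depth, 30, seed=4)
        assert rare.rarefaction.mean <= math.log(50) + 1e-12
        # independent resampling oracle with different seeds
        ref = []
        for s in range(200, 260):
            d = downsample(rep, depth, seed=s)
            ref.append(oracles.brute_shannon([r.freq for r in d.records]))
        ref = np.array(ref)
        band = 4 * ref.std(ddof=1) / math.sqrt(rare.rarefaction.n_resamples)
        assert abs(rare.rarefaction.mean - ref.mean()) < band + 1e-9


class TestCompareGroups:
    def test_exact_p_separated_groups(self):
        stat, p, method = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert stat == 0.0
        assert p == pytest.approx(0.1)
        assert method == "mann-whitney-exact"

    def test_enumeration_oracle(self):
        xs, ys = [1.5, 3.2, 0.7, 9.1], [2.2, 5.5, 7.7]
        _, p, method = compare_groups({"a": xs, "b": ys})
        assert method == "mann-whitney-exact"
        assert p == pytest.approx(oracles.brute_mannwhitney_exact_p(xs, ys), abs=1e-12)

    def test_identical_groups_p_one(self):
        stat, p, method = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert p == pytest.approx(1.0)
        assert "normal" in method

    def test_large_groups_use_approximation(self):
        xs = list(range(10))
        ys = [x + 0.5 for x in range(10)]
        _, _, method = compare_groups({"a": xs, "b": ys})
        assert method == "mann-whitney-normal-tie-corrected"

    def test_more_than_two_groups_rejected(self):
        with pytest.raises(ValidationError, match="pairwise"):
            compare_groups({"a": [1], "b": [2], "c": [3]})

    def test_degenerate_constant_groups(self):
        stat, p, method = compare_groups({"a": [5.0, 5.0], "b": [5.0] * 9})
        assert p == 1.0


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        raw = [0.001, 0.02, 0.04, 0.7, 0.5]
        adj = benjamini_hochberg(raw)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= r for a, r in zip(adj, raw))

    def test_known_values(self):
        adj = benjamini_hochberg([0.01, 0.04, 0.03, 0.005])
        assert adj == pytest.approx([0.02, 0.04, 0.04, 0.02])
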