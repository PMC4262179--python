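import itertools

import networkx as nx
import numpy as np
import pytest

from contactzone.popgen import (
    AmbiguousSequenceError,
    GenotypeMatrix,
    SequenceAlignment,
    build_msn,
    collapse_haplotypes,
    filter_alignment_sites,
    fst_permutation_test,
    pairwise_differences,
    read_fasta_alignment,
    read_genepop,
    read_genotype_table,
    rflp_assign,
    wc_fst,
    write_fasta_alignment,
    write_genotype_table,
)


class TestSiteFiltering:
    def test_gap_and_n_columns_removed(self):
        aln = SequenceAlignment({"s1": "AC-GT", "s2": "ACNGT", "s3": "ACAGT"})
        out = filter_alignment_sites(aln)
        assert out.length == 4
        assert out.records == {"s1": "ACGT", "s2": "ACGT", "s3": "ACGT"}

    def test_clean_alignment_unchanged(self):
        aln = SequenceAlignment({"s1": "ACGT", "s2": "TGCA"})
        assert filter_alignment_sites(aln).records == aln.records

    def test_iupac_ambiguity_counts_as_unresolved(self):
        aln = SequenceAlignment({"s1": "ARGT", "s2": "AAGT"})
        assert filter_alignment_sites(aln).length == 3

    def test_idempotent(self):
        aln = SequenceAlignment({"s1": "A-CRGT", "s2": "AACNGT"})
        once = filter_alignment_sites(aln)
        twice = filter_alignment_sites(once)
        assert once.records == twice.records

    def test_all_columns_filtered_is_error(self):
        with pytest.raises(ValueError, match="survive"):
            filter_alignment_sites(SequenceAlignment({"s1": "-N", "s2": "AC"}))


class TestHaplotypes:
    def test_identical_sequences_merge(self):
        haps = collapse_haplotypes(SequenceAlignment({"s1": "ACG", "s2": "ACG", "s3": "ACT"}))
        assert haps.n_haplotypes == 2
        assert sorted(haps.counts.values()) == [1, 2]
        assert haps.membership["s1"] == haps.membership["s2"]

    def test_case_insensitive(self):
        haps = collapse_haplotypes(SequenceAlignment({"s1": "acg", "s2": "ACG"}))
        assert haps.n_haplotypes == 1

    def test_all_distinct(self):
        haps = collapse_haplotypes(SequenceAlignment({"s1": "ACG", "s2": "AGG", "s3": "TCG"}))
        assert haps.n_haplotypes == 3

    def test_unfiltered_alignment_rejected(self):
        with pytest.raises(AmbiguousSequenceError, match="filter"):
            collapse_haplotypes(SequenceAlignment({"s1": "AC-"}))

    def test_recovers_constructed_template_count(self, rng):
        # 204 records built from 48 distinct templates
        templates = set()
        while len(templates) < 48:
            templates.add("".join(rng.choice(list("ACGT"), size=30)))
        templates = sorted(templates)
        records = {f"r{i}": templates[rng.integers(0, 48)] for i in range(204)}
        for i in range(48):  # guarantee every template appears
            records[f"t{i}"] = templates[i]
        haps = collapse_haplotypes(SequenceAlignment(records))
        assert haps.n_haplotypes == 48
        assert sum(haps.counts.values()) == len(records)


class TestDistances:
    def test_hamming_examples(self):
        haps = collapse_haplotypes(SequenceAlignment({"a": "ACG", "b": "ACT", "c": "ACG"}))
        d = pairwise_differences(haps)
        assert d.loc["H1", "H2"] == 1
        assert d.loc["H1", "H1"] == 0
        assert (d.to_numpy() == d.to_numpy().T).all()

    def test_triangle_inequality(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=20)) for i in range(8)}
        haps = collapse_haplotypes(SequenceAlignment(seqs))
        d = pairwise_differences(haps).to_numpy()
        n = d.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j]


class TestMSN:
    def test_three_node_unique_tree(self):
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]])
        net = build_msn(d)
        assert sorted((a, b) for a, b, _ in net.edges) == [("H1", "H2"), ("H2", "H3")]
        assert net.total_weight == 3

    def test_single_haplotype(self):
        net = build_msn(np.zeros((1, 1)))
        assert len(net.nodes) == 1 and net.edges == []

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_msn(np.array([[0, 1], [2, 0]]))

    def test_tree_weight_matches_exhaustive_minimum(self, rng):
        for _ in range(50):
            n = rng.integers(3, 8)
            d = rng.integers(1, 10, size=(n, n))
            d = np.triu(d, 1)
            d = d + d.T
            net = build_msn(d)
            g = nx.Graph()
            for i in range(n):
                for j in range(i + 1, n):
                    g.add_edge(i, j, weight=int(d[i, j]))
            best = next(iter(nx.SpanningTreeIterator(g)))  # independent minimum
            oracle = sum(g[u][v]["weight"] for u, v in best.edges)
            assert net.total_weight == oracle

    def test_alternative_edges_equal_bottleneck(self, rng):
        n = 6
        d = rng.integers(1, 5, size=(n, n))
        d = np.triu(d, 1)
        d = d + d.T
        net = build_msn(d)
        ids = [f"H{i+1}" for i in range(n)]
        g = nx.Graph()
        for a, b, w in net.edges:
            g.add_edge(a, b, weight=w)
        for a, b, w in net.alternative_edges:
            path = nx.shortest_path(g, a, b)
            bottleneck = max(g[u][v]["weight"] for u, v in zip(path, path[1:]))
            assert w == bottleneck
        # completeness: every equal-bottleneck non-tree pair is listed
        listed = {(a, b) for a, b, _ in net.alternative_edges}
        tree_pairs = {tuple(sorted((a, b))) for a, b, _ in net.edges}
        for i in range(n):
            for j in range(i + 1, n):
                pair = tuple(sorted((ids[i], ids[j])))
                if pair in tree_pairs:
                    continue
                path = nx.shortest_path(g, *pair)
                bottleneck = max(g[u][v]["weight"] for u, v in zip(path, path[1:]))
                assert (pair in listed) == (d[i, j] == bottleneck)

    def test_pipeline_invariant_to_record_order(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=25)) for i in range(30)}
        def net_for(items):
            aln = SequenceAlignment(dict(items))
            haps = collapse_haplotypes(filter_alignment_sites(aln))
            d = pairwise_differences(haps)
            net = build_msn(d, haps.counts)
            # with tied weights the tree itself is label-dependent, but the
            # union of tree edges and equal-weight alternatives is not, nor
            # is the total tree weight; compare by sequence content
            seq_of = haps.haplotypes
            union = {
                tuple(sorted((seq_of[a], seq_of[b]))) + (w,)
                for a, b, w in [*net.edges, *net.alternative_edges]
            }
            return net.total_weight, union
        forward = net_for(list(seqs.items()))
        backward = net_for(list(seqs.items())[::-1])
        assert forward == backward


class TestRFLP:
    def test_motif_present_cuts(self):
        assert rflp_assign("AAGTTAACA") == "cut"

    def test_motif_absent_uncut(self):
        assert rflp_assign("AAAAAA") == "uncut"

    def test_lowercase_handled(self):
        assert rflp_assign("aagttaaca") == "cut"

    def test_n_in_candidate_window_indeterminate(self):
        with pytest.raises(AmbiguousSequenceError):
            rflp_assign("AAGTNAACA")

    def test_n_away_from_any_candidate_window_is_fine(self):
        assert rflp_assign("GTTAACNCCCCCCC") == "cut"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            rflp_assign("")


class TestFst:
    def _matrix(self, genos, pops):
        n = len(genos)
        inds = [f"i{k}" for k in range(n)]
        return GenotypeMatrix(np.array(genos), inds, ["L1"], dict(zip(inds, pops)))

    def test_fixed_difference_gives_one(self):
        g = self._matrix([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]], ["A", "A", "B", "B"])
        assert wc_fst(g, "A", "B") == pytest.approx(1.0)

    def test_hand_worked_variance_components(self):
        # pop A: (1,1), (1,2); pop B: (2,2), (2,2) -> a=1/2, b=0, c=1/4 summed
        g = self._matrix([[[1, 1]], [[1, 2]], [[2, 2]], [[2, 2]]], ["A", "A", "B", "B"])
        assert wc_fst(g, "A", "B") == pytest.approx(2.0 / 3.0)

    def test_duplicated_population_is_near_zero(self, rng):
        genos = rng.integers(1, 9, size=(100, 10, 2))
        genos = np.concatenate([genos, genos])
        inds = [f"i{k}" for k in range(200)]
        pops = {i: ("A" if k < 100 else "B") for k, i in enumerate(inds)}
        g = GenotypeMatrix(genos, inds, [f"L{j}" for j in range(10)], pops)
        assert abs(wc_fst(g, "A", "B")) < 0.02

    def test_monomorphic_locus_rejected(self):
        g = self._matrix([[[1, 1]], [[1, 1]], [[1, 1]], [[1, 1]]], ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="polymorphic"):
            wc_fst(g, "A", "B")

    def test_missing_data_excluded_per_locus(self):
        g = self._matrix(
            [[[1, 1]], [[1, 2]], [[0, 1]], [[2, 2]], [[2, 2]], [[0, 2]]],
            ["A", "A", "A", "B", "B", "B"],
        )
        # the 0-coded individuals drop out, leaving the hand-worked table
        assert wc_fst(g, "A", "B") == pytest.approx(2.0 / 3.0)

    def test_permutation_p_lower_bound_and_maximal_statistic(self):
        g = self._matrix([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]], ["A", "A", "B", "B"])
        res = fst_permutation_test(g, "A", "B", n_perm=999, seed=0)
        assert res.theta == pytest.approx(1.0)
        # theta=1 can only be tied by the 2 of C(4,2)=6 splits that
        # reproduce the fixed difference, so p converges to 1/3
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=0.06)
        assert res.p_value >= 1.0 / 1000.0

    def test_permutation_reproducible(self, rng):
        genos = rng.integers(1, 5, size=(30, 4, 2))
        inds = [f"i{k}" for k in range(30)]
        pops = {i: ("A" if k < 15 else "B") for k, i in enumerate(inds)}
        g = GenotypeMatrix(genos, inds, [f"L{j}" for j in range(4)], pops)
        r1 = fst_permutation_test(g, "A", "B", n_perm=100, seed=7)
        r2 = fst_permutation_test(g, "A", "B", n_perm=100, seed=7)
        assert r1.p_value == r2.p_value


class TestIO:
    def test_fasta_round_trip(self, tmp_path):
        aln = SequenceAlignment({"s1": "ACGT", "s2": "AC-T"})
        path = write_fasta_alignment(aln, tmp_path / "a.fasta")
        assert read_fasta_alignment(path).records == aln.records

    def test_genotype_table_round_trip(self, tmp_path, rng):
        genos = rng.integers(1, 9, size=(10, 3, 2))
        inds = [f"i{k}" for k in range(10)]
        g = GenotypeMatrix(genos, inds, ["A", "B", "C"], {i: "P1" for i in inds})
        path = write_genotype_table(g, tmp_path / "g.tsv")
        back = read_genotype_table(path)
        np.testing.assert_array_equal(back.genotypes, g.genotypes)
        assert back.loci == g.loci

    def test_genepop_parsing(self, tmp_path):
        text = (
            "Title line\n"
            "Loc1\nLoc2\n"
            "POP\n"
            "ind1 , 0101 0203\n"
            "popA , 0102 0202\n"
            "POP\n"
            "popB , 0303 0101\n"
        )
        path = tmp_path / "g.gen"
        path.write_text(text)
        g = read_genepop(path)
        assert g.loci == ["Loc1", "Loc2"]
        assert g.pop["ind1"] == "popA"
        assert g.pop["popB"] == "popB"
        np.testing.assert_array_equal(g.genotypes[0, 0], [1, 1])
        np.testing.assert_array_equal(g.genotypes[2, 1], [1, 1])
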