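import numpy as np
import pytest
from scipy.stats import binomtest

from contactzone.matechoice import (
    Brood,
    MatingRecord,
    assign_paternity,
    binomial_assortment_test,
    read_brood_tables,
    replicate_tests,
    tally_matings,
)
from contactzone.simulate import GeneticSimConfig, gen_matechoice


def brood_of(mother, fry, bid="b1", rep="1"):
    return Brood(bid, "mom", np.array(mother), np.array(fry), rep)


class TestLocusExclusion:
    def test_single_compatible_candidate_assigned(self):
        # mother (1,1), fry (1,2): the sire must carry allele 2
        brood = brood_of([[1, 1]], [[[1, 2]]])
        recs = assign_paternity(
            brood,
            {"dad": np.array([[2, 2]]), "not": np.array([[3, 3]])},
            lineages={"dad": "north", "not": "south"},
            mother_lineage="north",
        )
        assert len(recs) == 1
        assert recs[0].status == "assigned"
        assert recs[0].assigned_father_id == "dad"
        assert recs[0].homotypic is True

    def test_both_compatible_is_ambiguous(self):
        brood = brood_of([[1, 1]], [[[1, 2]]])
        recs = assign_paternity(brood, {"a": np.array([[2, 3]]), "b": np.array([[2, 4]])})
        assert recs[0].status == "ambiguous"

    def test_missing_allele_is_uninformative(self):
        # fry has a missing allele at the only locus, so nobody is excluded
        brood = brood_of([[1, 1]], [[[0, 2]]])
        recs = assign_paternity(brood, {"a": np.array([[2, 2]]), "b": np.array([[3, 3]])})
        assert recs[0].status == "ambiguous"

    def test_true_father_never_excluded(self, rng):
        # property: Mendelian fry can always be explained by their real sire
        for _ in range(200):
            n_loci = 5
            mother = rng.integers(1, 9, size=(n_loci, 2))
            father = rng.integers(1, 9, size=(n_loci, 2))
            fry = np.stack(
                [
                    np.stack(
                        [
                            np.array([mother[l, rng.integers(2)], father[l, rng.integers(2)]])
                            for l in range(n_loci)
                        ]
                    )
                    for _ in range(6)
                ]
            )
            brood = brood_of(mother, fry)
            recs = assign_paternity(brood, {"real": father})
            assert recs[0].status == "assigned"
            assert recs[0].assigned_father_id == "real"

    def test_mismatch_tolerance_rescues_one_bad_locus(self):
        mother = [[1, 1], [3, 3]]
        fry = [[[1, 2], [3, 9]]]  # allele 9 matches nobody at locus 2
        cands = {"dad": np.array([[2, 2], [4, 4]])}
        assert assign_paternity(brood_of(mother, fry), cands)[0].status == "excluded"
        tolerant = assign_paternity(brood_of(mother, fry), cands, mismatch_tolerance=1)
        assert tolerant[0].status == "assigned"

    def test_multiple_paternity_split_into_two_sires(self):
        mother = [[1, 1]]
        # half the fry need allele 2, half need allele 3; no single sire fits
        fry = [[[1, 2]], [[1, 2]], [[1, 3]], [[1, 3]]]
        cands = {"s2": np.array([[2, 2]]), "s3": np.array([[3, 3]])}
        recs = assign_paternity(brood_of(mother, fry), cands)
        assert len(recs) == 2
        assert all(r.multiple_paternity for r in recs)
        assert {r.assigned_father_id for r in recs} == {"s2", "s3"}

    def test_no_explanation_is_excluded(self):
        brood = brood_of([[1, 1]], [[[1, 2]]])
        recs = assign_paternity(brood, {"a": np.array([[3, 3]])})
        assert recs[0].status == "excluded"

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidate"):
            assign_paternity(brood_of([[1, 1]], [[[1, 1]]]), {})

    def test_locus_set_mismatch_names_candidate(self):
        with pytest.raises(ValueError, match="'c1'"):
            assign_paternity(
                brood_of([[1, 1]], [[[1, 1]]]), {"c1": np.array([[1, 1], [2, 2]])}
            )


class TestTally:
    def _rec(self, rep, female, male, status="assigned"):
        return MatingRecord(
            "b", status, "f", female_lineage=female, male_lineage=male, replicate_id=rep
        )

    def test_counts_and_pooled_row(self):
        recs = [
            self._rec("1", "north", "north"),
            self._rec("1", "north", "south"),
            self._rec("2", "south", "south"),
            self._rec("2", "south", "south"),
        ]
        t = tally_matings(recs).set_index("replicate")
        assert t.loc["1", "k_heterotypic"] == 1 and t.loc["1", "n_assigned"] == 2
        assert t.loc["2", "k_heterotypic"] == 0
        assert t.loc["pooled", "n_assigned"] == 4
        assert t.loc["pooled", "heterotypic_pct"] == pytest.approx(25.0)

    def test_unassigned_records_do_not_count(self):
        recs = [self._rec("1", "north", "north"), self._rec("1", None, None, "excluded")]
        t = tally_matings(recs).set_index("replicate")
        assert t.loc["1", "n_assigned"] == 1

    def test_homotypic_undefined_for_unassigned(self):
        with pytest.raises(ValueError, match="assigned"):
            _ = MatingRecord("b", "excluded").homotypic


class TestBinomial:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (1, 11, 12 / 2048),  # field replicate values reproduced exactly
            (1, 9, 10 / 512),
            (1, 8, 9 / 256),
        ],
    )
    def test_reference_tail_probabilities(self, k, n, expected):
        res = binomial_assortment_test(k, n, p0=0.5)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
    def test_matches_independent_oracle(self, rng, alternative):
        for _ in range(60):
            n = int(rng.integers(1, 31))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            ours = binomial_assortment_test(k, n, p0, alternative).p_value
            oracle = binomtest(k, n, p0, alternative).pvalue
            assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_assortment_test(5, 4)
        with pytest.raises(ValueError):
            binomial_assortment_test(1, 4, p0=0.0)
        with pytest.raises(ValueError):
            binomial_assortment_test(1, 4, alternative="sideways")

    def test_replicate_tests_table(self):
        recs = [
            MatingRecord("b%d" % i, "assigned", "f", female_lineage="north",
                         male_lineage="north" if i else "south", replicate_id="1")
            for i in range(11)
        ]
        df = replicate_tests(recs).set_index("replicate")
        assert df.loc["1", "p_value"] == pytest.approx(12 / 2048, abs=1e-12)


class TestEndToEnd:
    def test_simulated_matings_recovered(self, tmp_path):
        cfg = GeneticSimConfig(seed=12)
        data = gen_matechoice(cfg)
        correct = 0
        total = 0
        for brood in data.broods:
            cands = data.candidates_for(brood.replicate_id)
            recs = assign_paternity(
                brood,
                cands,
                lineages=data.candidate_lineage,
                mother_lineage=data.mother_lineage[brood.brood_id],
            )
            for r in recs:
                if r.status == "assigned" and not r.multiple_paternity:
                    total += 1
                    correct += r.assigned_father_id == data.true_sire[brood.brood_id]
        assert total >= 40
        assert correct / total >= 0.9

    def test_brood_table_round_trip(self, tmp_path):
        from contactzone.simulate import write_matechoice_tables

        cfg = GeneticSimConfig(seed=7)
        data = gen_matechoice(cfg)
        bpath = tmp_path / "broods.tsv"
        cpath = tmp_path / "candidates.tsv"
        write_matechoice_tables(data, bpath, cpath)
        broods, candidates, cand_lin, mom_lin = read_brood_tables(bpath, cpath)
        assert len(broods) == len(data.broods)
        by_id = {b.brood_id: b for b in broods}
        for orig in data.broods:
            back = by_id[orig.brood_id]
            np.testing.assert_array_equal(back.mother, orig.mother)
            np.testing.assert_array_equal(back.fry, orig.fry)
            assert back.replicate_id == orig.replicate_id
        assert cand_lin == data.candidate_lineage
        assert mom_lin == data.mother_lineage
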