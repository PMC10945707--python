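import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrestome.complexes import (
    ComplexScore,
    MergedComplex,
    complex_enrichment_pipeline,
    iqm,
    iqm_score,
    merge_complexes,
    overlap_coefficient,
    permutation_pvalue,
    prune_complexes,
    quartile_ranks,
)
from arrestome.data_model import ComplexDatabase, HighConfidenceNetwork, ProteinComplex
from arrestome.simulate import SimulationConfig, evaluate_complex_recovery, simulate_dataset
from arrestome import interactome as net

from conftest import make_scored


def brute_force_iqm(scores):
    """Direct evaluation: sort ascending, average ranks Q1..Q3 with
    Q1 = floor(N/4)+1 and Q3 = floor(3N/4)."""
    s = sorted(scores)
    n = len(s)
    q1 = n // 4 + 1
    q3 = max((3 * n) // 4, q1)
    vals = [s[i - 1] for i in range(q1, q3 + 1)]
    return sum(vals) / len(vals)


def brute_force_merge(subunit_sets, threshold=0.5):
    """Recompute-everything greedy agglomeration returning the final
    partition as a set of frozensets of source ids."""
    current = {cid: (frozenset({cid}), frozenset(s)) for cid, s in subunit_sets.items()}
    while len(current) > 1:
        pairs = []
        for a, b in itertools.combinations(sorted(current), 2):
            sa, sb = current[a][1], current[b][1]
            coef = len(sa & sb) / min(len(sa), len(sb))
            pairs.append((coef, a, b))
        best_coef = max(c for c, _, _ in pairs)
        if best_coef <= threshold:
            break
        _, a, b = min((p for p in pairs if p[0] == best_coef), key=lambda p: (p[1], p[2]))
        ids_a, sa = current.pop(a)
        ids_b, sb = current.pop(b)
        current[f"{a}+{b}"] = (ids_a | ids_b, sa | sb)
    return {ids for ids, _ in current.values()}


class TestOverlapCoefficient:
    def test_identical_sets(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_hand_counted(self):
        assert overlap_coefficient({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(2 / 3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.sets(st.integers(0, 20), min_size=1, max_size=10),
        y=st.sets(st.integers(0, 20), min_size=1, max_size=10),
    )
    def test_bounded_and_symmetric(self, x, y):
        c = overlap_coefficient(x, y)
        assert 0.0 <= c <= 1.0
        assert c == overlap_coefficient(y, x)


class TestIqmScore:
    def test_constant_scores(self):
        cs = iqm_score(["a", "b", "c", "d"], dict.fromkeys("abcd", 1.0))
        assert cs.iqm == pytest.approx(1.0)
        assert (cs.q1, cs.q3) == (2, 3)

    def test_four_sorted_scores(self):
        score_of = dict(zip("abcd", [0.1, 0.4, 0.6, 0.9]))
        assert iqm_score("abcd", score_of).iqm == pytest.approx(0.5)

    def test_undetected_subunits_score_zero(self):
        cs = iqm_score(["a", "b", "c", "d"], {})
        assert cs.iqm == 0.0
        assert cs.n_subunits == 4

    def test_small_complex_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            iqm_score(["a", "b"], {})

    def test_matches_brute_force_over_sizes(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(3, 13))
            scores = rng.random(n)
            assert iqm(scores) == pytest.approx(brute_force_iqm(scores.tolist()))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=16))
    def test_order_invariant_and_bounded(self, scores):
        shuffled = list(reversed(scores))
        assert iqm(np.array(scores)) == pytest.approx(iqm(np.array(shuffled)))
        assert min(scores) - 1e-12 <= iqm(np.array(scores)) <= max(scores) + 1e-12

    def test_equals_mean_when_multiple_of_four_and_constant(self):
        for k in (1, 2, 3):
            scores = np.full(4 * k, 0.37)
            assert iqm(scores) == pytest.approx(0.37)


class TestPermutationPvalue:
    def test_add_one_floor(self):
        universe = [f"u{i}" for i in range(30)]
        score_of = {u: 0.0 for u in universe}
        target = ["t1", "t2", "t3"]
        score_of.update(dict.fromkeys(target, 1.0))
        p, obs = permutation_pvalue(target, universe + target, score_of, n_perm=200, seed=1)
        assert obs == 1.0
        assert p == pytest.approx(1 / 201)

    def test_zero_observed_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        p, obs = permutation_pvalue(
            universe[:3], universe, {u: 0.5 for u in universe}, n_perm=100, seed=0
        )
        assert obs == 0.5  # constant scores: every null equals the observed
        assert p == 1.0

    def test_universe_smaller_than_complex_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            permutation_pvalue(["a", "b", "c"], ["a", "b"], {}, n_perm=10, seed=0)

    def test_monte_carlo_matches_enumeration_on_tiny_universe(self):
        rng = np.random.default_rng(7)
        universe = [f"u{i}" for i in range(5)]
        score_of = {u: float(rng.random()) for u in universe}
        members = universe[:2]
        obs = iqm(np.array([score_of[m] for m in members]))
        null = [
            iqm(np.array([score_of[m] for m in combo]))
            for combo in itertools.combinations(universe, 2)
        ]
        p_exact = np.mean([v >= obs for v in null])
        n_perm = 5000
        p_mc, _ = permutation_pvalue(members, universe, score_of, n_perm=n_perm, seed=3)
        expected = (1 + n_perm * p_exact) / (n_perm + 1)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - expected) <= 3 * se + 1e-9

    def test_null_network_pvalues_near_uniform(self):
        # i.i.d. scores: permutation p-values of random decoy complexes
        # should be approximately uniform
        rng = np.random.default_rng(2024)
        universe = [f"u{i}" for i in range(60)]
        score_of = {u: float(rng.random()) for u in universe}
        pvals = []
        for k in range(100):
            size = int(rng.integers(3, 9))
            members = rng.choice(universe, size=size, replace=False).tolist()
            p, _ = permutation_pvalue(members, universe, score_of, n_perm=500, seed=k)
            pvals.append(p)
        ps = np.sort(pvals)
        ecdf = np.arange(1, len(ps) + 1) / len(ps)
        assert np.max(np.abs(ecdf - ps)) < 0.15


class TestMergeComplexes:
    def _db(self, subunit_sets):
        db = ComplexDatabase()
        for cid, s in subunit_sets.items():
            db.add(ProteinComplex(cid, frozenset(s)))
        return db

    def test_below_threshold_is_fixed_point(self):
        sets = {"c1": {"a", "b", "c", "d"}, "c2": {"c", "d", "e", "f"}}  # coef 0.5
        merged = merge_complexes(self._db(sets), threshold=0.5)
        assert {m.merged_id for m in merged} == {"c1", "c2"}
        assert all(m.provenance == () for m in merged)

    def test_identical_complexes_merge_once(self):
        sets = {"c1": {"a", "b", "c"}, "c2": {"a", "b", "c"}}
        merged = merge_complexes(self._db(sets))
        assert len(merged) == 1
        assert merged[0].members == ("c1", "c2")
        assert merged[0].subunits == frozenset({"a", "b", "c"})

    def test_chain_matches_brute_force(self):
        sets = {
            "c1": {"a", "b", "c"},
            "c2": {"b", "c", "d"},
            "c3": {"d", "e", "f", "g", "h", "i"},
        }
        merged = merge_complexes(self._db(sets))
        got = {frozenset(m.members) for m in merged}
        assert got == brute_force_merge(sets)

    def test_random_databases_match_oracle(self):
        rng = np.random.default_rng(99)
        proteins = [f"p{i}" for i in range(15)]
        for case in range(60):
            n_cplx = int(rng.integers(2, 13))
            sets = {
                f"c{j}": set(
                    rng.choice(proteins, size=int(rng.integers(3, 7)), replace=False)
                )
                for j in range(n_cplx)
            }
            merged = merge_complexes(self._db(sets))
            got = {frozenset(m.members) for m in merged}
            assert got == brute_force_merge(sets), f"case {case} diverged"

    def test_order_independent(self):
        rng = np.random.default_rng(5)
        proteins = [f"p{i}" for i in range(12)]
        sets = {
            f"c{j}": set(rng.choice(proteins, size=4, replace=False)) for j in range(8)
        }
        forward = merge_complexes(self._db(sets))
        backward = merge_complexes(self._db(dict(reversed(list(sets.items())))))
        assert {frozenset(m.members) for m in forward} == {
            frozenset(m.members) for m in backward
        }

    def test_terminates_in_at_most_n_minus_one_merges(self):
        sets = {f"c{j}": {"a", "b", "c"} for j in range(6)}
        merged = merge_complexes(self._db(sets))
        assert len(merged) == 1
        assert len(merged[0].provenance) == 5

    def test_provenance_records_coefficients_above_threshold(self):
        sets = {"c1": {"a", "b", "c"}, "c2": {"b", "c", "d"}, "c3": {"x", "y", "z"}}
        merged = merge_complexes(self._db(sets))
        for m in merged:
            for _, _, coef in m.provenance:
                assert coef > 0.5


def hc_network(pairs, score=0.9):
    return HighConfidenceNetwork(
        make_scored([(b, p, score, 0.01, (6, 6)) for b, p in pairs]), 0.85, 6
    )


class TestPruneComplexes:
    def _merged(self, cid, subunits, edges):
        return MergedComplex(cid, (cid,), frozenset(subunits), frozenset(edges))

    def test_boundary_pass(self):
        c = self._merged("c", {"a", "b", "d"}, {("a", "b"), ("b", "d"), ("a", "d")})
        network = hc_network([("B1", "a"), ("B1", "b")])
        assert len(prune_complexes([c], network)) == 1

    def test_isolated_subunit_dropped(self):
        c = self._merged("c", {"a", "b", "d", "e"}, {("a", "b"), ("b", "d"), ("a", "d")})
        network = hc_network([("B1", "a"), ("B1", "b")])
        out = prune_complexes([c], network)
        assert out[0].subunits == frozenset({"a", "b", "d"})

    def test_too_few_bait_links_removed(self):
        c = self._merged("c", {"a", "b", "d"}, {("a", "b"), ("b", "d"), ("a", "d")})
        network = hc_network([("B1", "a")])
        assert prune_complexes([c], network) == []

    def test_too_few_subunits_removed(self):
        c = self._merged("c", {"a", "b", "d"}, {("a", "b")})  # d isolated -> 2 left
        network = hc_network([("B1", "a"), ("B1", "b")])
        assert prune_complexes([c], network) == []

    def test_intra_complex_ppi_rule(self):
        c = self._merged("c", {"a", "b", "d"}, {("a", "b"), ("b", "d")})
        network = hc_network([("B1", "a"), ("B1", "b")])
        assert len(prune_complexes([c], network, ppi_rule="intra-complex")) == 1

    def test_missing_edge_set_policy(self):
        c = MergedComplex("c", ("c",), frozenset({"a", "b", "d"}))
        network = hc_network([("B1", "a"), ("B1", "b")])
        assert len(prune_complexes([c], network, missing_edges="keep")) == 1
        with pytest.raises(ValueError):
            prune_complexes([c], network, missing_edges="reject")


class TestEnrichmentPipeline:
    def test_null_network_yields_nothing(self, default_dataset):
        empty = HighConfidenceNetwork([], 0.85, 6)
        results, _ = complex_enrichment_pipeline(
            empty, [default_dataset.complexes], n_perm=200, seed=0
        )
        assert results == []

    def test_planted_complex_passes_all_stages(self, default_dataset, default_network):
        results, merged = complex_enrichment_pipeline(
            default_network, [default_dataset.complexes], n_perm=500, seed=4
        )
        sens, fdr = evaluate_complex_recovery(results, merged, default_dataset.truth)
        assert sens == 1.0
        assert fdr == 0.0

    def test_same_seed_identical_output(self, default_dataset, default_network):
        runs = [
            complex_enrichment_pipeline(
                default_network, [default_dataset.complexes], n_perm=300, seed=8
            )
            for _ in range(2)
        ]
        a, b = (
            [(r.bait, r.complex_id, r.iqm, r.p, r.q) for r in res]
            for res, _ in runs
        )
        assert a == b
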