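import math
from itertools import chain, combinations

import numpy as np
import pytest

from genesieve import (
    ClassifierSpec,
    DecompositionConfig,
    GeneSet,
    GeneSubsetSelector,
    SubsetRecord,
    count_subsets,
    enumerate_subsets,
    extend_seeds,
    gene_frequencies,
    run_decomposition,
    select_seed_pool,
    total_subsets,
)
from genesieve.decompose import DecompositionLog, read_log


class TestCountSubsets:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (36, 3, 7140),  # the 36-gene worked example
            (5, 2, 10),     # brute force: len(list(combinations(range(5),2)))
            (7, 0, 1),
            (7, 7, 1),
        ],
    )
    def test_known_counts(self, n, k, expected):
        assert count_subsets(n, k) == expected

    def test_matches_enumeration(self):
        for n in range(1, 8):
            for k in range(1, n + 1):
                assert count_subsets(n, k) == len(
                    list(combinations(range(n), k))
                )

    @pytest.mark.parametrize("n,k", [(3, 4), (-1, 0), (5, -2)])
    def test_domain_errors(self, n, k):
        with pytest.raises(ValueError):
            count_subsets(n, k)

    def test_total_subsets_is_sum_of_binomials(self):
        for n in range(1, 12):
            assert total_subsets(n) == sum(
                math.comb(n, k) for k in range(1, n + 1)
            ) == 2**n - 1


class TestEnumerateSubsets:
    def test_pairs_lexicographic(self):
        subs = enumerate_subsets(["D", "B", "A", "C"], 2)
        assert subs == [
            ("A", "B"), ("A", "C"), ("A", "D"),
            ("B", "C"), ("B", "D"), ("C", "D"),
        ]

    def test_k_equals_n(self):
        assert enumerate_subsets(["B", "A"], 2) == [("A", "B")]

    def test_36_choose_3_length(self):
        genes = [f"G{i:02d}" for i in range(36)]
        assert len(enumerate_subsets(genes, 3)) == 7140

    def test_oversized_k_errors(self):
        with pytest.raises(ValueError):
            enumerate_subsets(["A", "B"], 3)


class TestExtendSeeds:
    def test_collision_free_90_seeds_yield_2970(self):
        """90 pairwise-disjoint-extension seeds over 36 genes: the worked
        example's m4 = 90 * (36 - 3) = 2970 children."""
        genes = [f"G{i:02d}" for i in range(36)]
        full = GeneSet("FULL", tuple(genes))
        rng = np.random.default_rng(0)
        # triples chosen so no two seeds share 2 genes -> no collisions
        seeds = []
        seen_pairs = set()
        while len(seeds) < 90:
            cand = tuple(sorted(rng.choice(36, 3, replace=False)))
            pairs = {p for p in combinations(cand, 2)}
            if pairs & seen_pairs:
                continue
            seen_pairs |= pairs
            seeds.append(tuple(genes[i] for i in cand))
        children = extend_seeds(seeds, full)
        assert len(children) == 2970

    def test_overlapping_seeds_deduplicate(self):
        full = GeneSet("F", ("A", "B", "C", "D"))
        children = extend_seeds([("A", "B"), ("A", "C")], full)
        # brute force over the 4 raw children: ABC, ABD, ABC, ACD
        assert children == [("A", "B", "C"), ("A", "B", "D"), ("A", "C", "D")]

    def test_single_seed_of_size_n_minus_1(self):
        full = GeneSet("F", ("A", "B", "C"))
        assert extend_seeds([("A", "B")], full) == [("A", "B", "C")]

    def test_foreign_seed_rejected(self):
        full = GeneSet("F", ("A", "B", "C"))
        with pytest.raises(ValueError, match="X"):
            extend_seeds([("A", "X")], full)

    def test_mixed_sizes_rejected(self):
        full = GeneSet("F", ("A", "B", "C", "D"))
        with pytest.raises(ValueError, match="identical size"):
            extend_seeds([("A",), ("B", "C")], full)


def _records(pairs):
    return [SubsetRecord(genes=g, accuracy=a) for g, a in pairs]


class TestSelectSeedPool:
    def test_pool_size_m_plus_half(self):
        genes = [f"G{i:02d}" for i in range(20)]
        recs = _records(
            [(s, float(i % 17) / 17) for i, s in enumerate(combinations(genes, 3))]
        )
        cfg = DecompositionConfig(M=60, rng_seed=1)
        pool = select_seed_pool(recs, cfg)
        assert len(pool) == 90
        assert len(set(pool)) == 90

    def test_saturation_takes_all(self):
        recs = _records([(("A", "B"), 0.5), (("A", "C"), 0.6), (("B", "C"), 0.7)])
        cfg = DecompositionConfig(M=60)
        assert len(select_seed_pool(recs, cfg)) == 3

    def test_tie_broken_lexicographically(self):
        recs = _records([(("B", "C"), 0.9), (("A", "B"), 0.9), (("A", "C"), 0.1)])
        cfg = DecompositionConfig(M=1, random_seed_fraction=0.0)
        assert select_seed_pool(recs, cfg) == [("A", "B")]

    def test_top_m_are_best_by_accuracy(self):
        recs = _records(
            [(("A", chr(66 + i)), 0.1 * i) for i in range(9)]
        )
        cfg = DecompositionConfig(M=3, random_seed_fraction=0.0)
        pool = select_seed_pool(recs, cfg)
        assert sorted(pool) == sorted(r.genes for r in recs if r.accuracy >= 0.6)

    def test_mixed_sizes_rejected(self):
        recs = _records([(("A",), 0.1), (("B", "C"), 0.2)])
        with pytest.raises(ValueError):
            select_seed_pool(recs, DecompositionConfig())


def brute_force_best(scorer, genes, k):
    """Best subset of size k over the full power set restriction."""
    return min(
        combinations(sorted(genes), k),
        key=lambda s: (-scorer(s), s),
    )


class TestRunDecomposition:
    @pytest.fixture()
    def small_set(self, planted_gem):
        gem, labels, truth = planted_gem
        others = [g for g in gem.gene_ids if g not in truth][:4]
        return GeneSet("SMALL", tuple(truth[:2]) + tuple(others))

    def test_all_exhaustive_when_m_large(self, planted_gem, small_set):
        """With M >= C(n,k) everywhere the heuristic never prunes: subset
        counts equal binomials at every size (here n=6)."""
        gem, labels, _ = planted_gem
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=2, rng_seed=0)
        log = run_decomposition(
            gem, labels, small_set, cspec,
            DecompositionConfig(M=1000, exhaustive_k_max=3, rng_seed=0),
        )
        n = small_set.n
        assert log.m == {k: math.comb(n, k) for k in range(1, n + 1)}

    def test_n2_smallest_legal_run(self, planted_gem):
        gem, labels, truth = planted_gem
        gs = GeneSet("PAIR", tuple(truth[:2]))
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=2, rng_seed=0)
        log = run_decomposition(gem, labels, gs, cspec, DecompositionConfig(M=5))
        assert log.m == {1: 2, 2: 1}
        assert log.iterations[2][0].genes == tuple(sorted(truth[:2]))

    def test_dedup_bound_and_final_iteration(self, planted_gem):
        gem, labels, truth = planted_gem
        others = [g for g in gem.gene_ids if g not in truth][:8]
        gs = GeneSet("TWELVE", tuple(truth) + tuple(others))
        cfg = DecompositionConfig(M=10, exhaustive_k_max=3, rng_seed=3)
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=2, rng_seed=1)
        log = run_decomposition(gem, labels, gs, cspec, cfg)
        n = gs.n
        for k in range(1, 4):
            assert log.m[k] == math.comb(n, k)
        for k in range(4, n + 1):
            assert log.m[k] <= (3 * cfg.M // 2) * (n - (k - 1))
        assert log.m[n] == 1

    def test_monotone_coverage(self, planted_gem):
        """Every iteration-(k+1) subset contains at least one iteration-k
        subset (its seed) as a sub-tuple."""
        gem, labels, truth = planted_gem
        others = [g for g in gem.gene_ids if g not in truth][:6]
        gs = GeneSet("TEN", tuple(truth) + tuple(others))
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=2, rng_seed=1)
        log = run_decomposition(
            gem, labels, gs, cspec, DecompositionConfig(M=8, rng_seed=2)
        )
        for k in range(3, gs.n):
            prev = {r.genes for r in log.iterations[k]}
            for rec in log.iterations[k + 1]:
                subs = {
                    tuple(sorted(set(rec.genes) - {g})) for g in rec.genes
                }
                assert subs & prev

    def test_replay_determinism(self, planted_gem, small_set):
        gem, labels, _ = planted_gem
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=3, rng_seed=5)
        cfg = DecompositionConfig(M=4, rng_seed=9)
        a = run_decomposition(gem, labels, small_set, cspec, cfg)
        b = run_decomposition(gem, labels, small_set, cspec, cfg)
        assert a.to_frame().equals(b.to_frame())

    def test_subset_order_within_evaluation_is_irrelevant(self, planted_gem):
        """Reversing the gene order of the input set leaves each subset's
        accuracy unchanged (subsets are keyed by sorted tuple)."""
        gem, labels, truth = planted_gem
        others = [g for g in gem.gene_ids if g not in truth][:3]
        genes = tuple(truth[:2]) + tuple(others)
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=2, rng_seed=5)
        cfg = DecompositionConfig(M=100, rng_seed=0)
        fwd = run_decomposition(gem, labels, GeneSet("F", genes), cspec, cfg)
        rev = run_decomposition(gem, labels, GeneSet("R", genes[::-1]), cspec, cfg)
        for k in fwd.iterations:
            fa = {r.genes: r.accuracy for r in fwd.iterations[k]}
            ra = {r.genes: r.accuracy for r in rev.iterations[k]}
            assert fa.keys() == ra.keys()
            for g in fa:
                assert fa[g] == pytest.approx(ra[g], abs=1e-6)

    def test_injected_scorer_matches_brute_force(self, planted_gem):
        """With a deterministic scorer and no pruning, the best subset per
        size must equal brute-force search over all 2^n - 1 subsets."""
        gem, labels, truth = planted_gem
        others = [g for g in gem.gene_ids if g not in truth][:3]
        gs = GeneSet("ORACLE", tuple(truth[:3]) + tuple(others))
        planted = set(truth[:3])

        def scorer(subset):
            return len(planted & set(subset)) / len(subset)

        log = run_decomposition(
            gem, labels, gs, None,
            DecompositionConfig(M=10**6, rng_seed=0),
            scorer=scorer,
        )
        for k in range(1, gs.n + 1):
            assert log.best(k).genes == brute_force_best(scorer, gs.genes, k)

    def test_budget_guard_reduces_exhaustive_depth(self, planted_gem):
        gem, labels, truth = planted_gem
        others = [g for g in gem.gene_ids if g not in truth][:10]
        gs = GeneSet("BUDGET", tuple(truth) + tuple(others))
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=2, rng_seed=1)
        cfg = DecompositionConfig(M=5, exhaustive_k_max=3, exhaustive_budget=50)
        with pytest.warns(UserWarning, match="budget"):
            log = run_decomposition(gem, labels, gs, cspec, cfg)
        assert log.m[1] == gs.n
        assert log.m[2] <= (3 * cfg.M // 2) * (gs.n - 1)

    def test_log_round_trip(self, planted_gem, small_set, tmp_path):
        gem, labels, _ = planted_gem
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=2, rng_seed=0)
        log = run_decomposition(
            gem, labels, small_set, cspec, DecompositionConfig(M=4, rng_seed=1)
        )
        path = tmp_path / "log.tsv"
        log.write_tsv(path)
        back = read_log(path)
        assert back.m == log.m
        for k in log.iterations:
            assert [r.genes for r in back.iterations[k]] == [
                r.genes for r in log.iterations[k]
            ]


class TestGeneFrequencies:
    def _exhaustive_log(self, n, kmax):
        genes = [f"G{i:02d}" for i in range(n)]
        log = DecompositionLog(set_name="X", n=n, gene_order=sorted(genes))
        for k in range(1, kmax + 1):
            log.iterations[k] = [
                SubsetRecord(genes=s, accuracy=0.5)
                for s in enumerate_subsets(genes, k)
            ]
        return log

    @pytest.mark.parametrize("n,kmax", [(5, 3), (9, 3), (20, 3)])
    def test_exhaustive_rows_constant(self, n, kmax):
        """At an exhaustive iteration every gene appears in C(n-1, k-1)
        subsets, so heatmap rows for k <= 3 are constant across genes."""
        ft = gene_frequencies(self._exhaustive_log(n, kmax))
        for i, k in enumerate(ft.iterations):
            expected = math.comb(n - 1, k - 1)
            assert set(ft.counts[i]) == {expected}

    def test_n5_k2_counts_by_brute_force(self):
        ft = gene_frequencies(self._exhaustive_log(5, 2))
        tally = {g: 0 for g in ft.genes}
        for s in combinations(sorted(ft.genes), 2):
            for g in s:
                tally[g] += 1
        assert list(ft.counts[1]) == [tally[g] for g in ft.genes]
        assert set(ft.counts[1]) == {4}

    def test_final_iteration_counts_are_one(self, planted_gem):
        gem, labels, truth = planted_gem
        gs = GeneSet("S", tuple(truth))
        cspec = ClassifierSpec(backend="linear_fallback", n_runs=2, rng_seed=0)
        log = run_decomposition(gem, labels, gs, cspec, DecompositionConfig(M=3))
        ft = gene_frequencies(log)
        assert set(ft.counts[-1]) == {1}
        assert list(ft.aggregate) == list(ft.counts.sum(axis=0))


class TestGeneSubsetSelector:
    def test_sklearn_selector_contract(self, planted_gem):
        gem, labels, truth = planted_gem
        others = [g for g in gem.gene_ids if g not in truth][:6]
        genes = list(truth) + list(others)
        idx = gem.rows(genes)
        X = gem.values.T
        y = labels.encode(gem.sample_ids)
        from genesieve import BootstrapPotential

        sel = GeneSubsetSelector(
            genes=idx,
            M=8,
            random_state=0,
            potential=BootstrapPotential(n_runs=3, random_state=2),
        ).fit(X, y, feature_names=gem.gene_ids)
        assert sel.support_.sum() == len(sel.candidate_genes_)
        assert set(sel.candidate_genes_) | set(sel.noncandidate_genes_) == set(
            genes
        )
        reduced = sel.transform(X)
        assert reduced.shape == (X.shape[0], len(sel.candidate_genes_))

    def test_get_params_round_trip(self):
        sel = GeneSubsetSelector(M=12, sd_multiplier=0.25)
        params = sel.get_params()
        assert params["M"] == 12
        assert GeneSubsetSelector(**params).get_params() == params
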