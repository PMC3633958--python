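from itertools import combinations as iter_combinations

import numpy as np
import pytest

from gmdr.data_model import SNPInfo
from gmdr.engine import InteractionResult, make_folds
from gmdr.permutation import PermutationConfig
from gmdr.scores import compute_scores
from gmdr.search import (
    SearchConfig,
    conditioned_search,
    detect_core_snps,
    enumerate_combinations,
    exhaustive_search,
    harvest_top_snps,
    significance_filter,
)
from gmdr.simdata import default_snp_specs, simulate_genotypes, simulate_phenotype, xor_model
from gmdr.data_model import validate_dataset


def _snps(positions, chroms=None):
    return [
        SNPInfo(f"rs{i}", str(chroms[i]) if chroms is not None else "1", int(p))
        for i, p in enumerate(positions)
    ]


class TestEnumerateCombinations:
    def test_four_snps_four_chromosomes_six_pairs(self):
        snps = _snps([1, 1, 1, 1], chroms=[1, 2, 3, 4])
        assert len(list(enumerate_combinations(snps, 2))) == 6

    def test_distance_filter_hand_checked(self):
        # positions 1; 500,000; 2,000,000 on one chromosome, 1 Mb rule:
        # distances 499,999 / 1,999,999 / 1,500,000 -> only (0,2) and (1,2) pass
        snps = _snps([1, 500_000, 2_000_000])
        assert list(enumerate_combinations(snps, 2)) == [(0, 2), (1, 2)]

    def test_exactly_one_megabase_passes(self):
        snps = _snps([1, 1_000_001])
        assert list(enumerate_combinations(snps, 2)) == [(0, 1)]

    def test_inter_chromosomal_pairs_never_filtered(self):
        snps = _snps([1, 2], chroms=[1, 2])
        assert list(enumerate_combinations(snps, 2)) == [(0, 1)]

    def test_k_equals_snp_count(self):
        snps = _snps([1, 1, 1], chroms=[1, 2, 3])
        assert list(enumerate_combinations(snps, 3)) == [(0, 1, 2)]

    def test_count_matches_brute_force_filter(self, rng):
        for trial in range(10):
            m = int(rng.integers(4, 13))
            k = int(rng.integers(2, 6))
            if k > m:
                continue
            chroms = rng.integers(1, 4, size=m)
            pos = rng.integers(1, 3_000_000, size=m)
            snps = _snps(pos, chroms=chroms)
            got = list(enumerate_combinations(snps, k, 1_000_000))
            expected = []
            for combo in iter_combinations(range(m), k):
                ok = all(
                    not (
                        chroms[a] == chroms[b]
                        and abs(int(pos[a]) - int(pos[b])) < 1_000_000
                    )
                    for a, b in iter_combinations(combo, 2)
                )
                if ok:
                    expected.append(combo)
            assert got == expected


def _planted_dataset(seed, n=400, n_snps=8, high=1.0, low=0.0):
    g = simulate_genotypes(n, default_snp_specs(n_snps, maf=0.5), seed=seed)
    ph, _ = simulate_phenotype(g, xor_model((0, 1), high, low), "binary", seed=seed + 1)
    ds = validate_dataset(g, ph, None)
    scores = compute_scores(ds.phenotype)
    folds = make_folds(ds.n_subjects, 10, seed=seed + 2, stratify_labels=ds.phenotype.values)
    return ds, scores, folds


class TestExhaustiveSearch:
    def test_planted_pair_is_top_ranked(self):
        ds, scores, folds = _planted_dataset(seed=100)
        outcome = exhaustive_search(ds, scores, folds)
        assert outcome.n_combinations_evaluated == 28  # C(8,2)
        assert outcome.results
        top = outcome.results[0]
        assert top.combination == (0, 1)
        assert top.cvc == 10
        assert top.testing_accuracy == 1.0

    def test_single_snp_no_pairs(self):
        g = simulate_genotypes(200, default_snp_specs(1, maf=0.3), seed=200)
        ph, _ = simulate_phenotype(g, None, "binary", seed=201)
        ds = validate_dataset(g, ph, None)
        scores = compute_scores(ds.phenotype)
        folds = make_folds(200, 10, seed=202)
        outcome = exhaustive_search(ds, scores, folds)
        assert outcome.n_combinations_evaluated == 0
        assert outcome.results == []

    def test_null_data_yields_no_significant_models(self):
        g = simulate_genotypes(300, default_snp_specs(10, maf=0.3), seed=7)
        ph, _ = simulate_phenotype(g, None, "binary", seed=8)
        ds = validate_dataset(g, ph, None)
        scores = compute_scores(ds.phenotype)
        folds = make_folds(300, 10, seed=9, stratify_labels=ds.phenotype.values)
        outcome = exhaustive_search(
            ds, scores, folds, perm_config=PermutationConfig(n_perm=500, seed=10)
        )
        surviving = significance_filter(outcome.results, 7, 1e-3)
        assert surviving == []

    def test_permutation_p_attached_to_candidates(self):
        ds, scores, folds = _planted_dataset(seed=300)
        outcome = exhaustive_search(
            ds, scores, folds, perm_config=PermutationConfig(n_perm=200, seed=5)
        )
        assert all(r.p_value is not None for r in outcome.results)
        assert outcome.results[0].p_is_bound  # perfect accuracy is unbeatable


class TestHarvestAndConditioned:
    def test_harvest_union_collapses_repeats(self):
        ds, scores, folds = _planted_dataset(seed=400)
        outcome = exhaustive_search(ds, scores, folds)
        # noise-free planted pair wins every fold: harvest is exactly {0, 1}
        assert harvest_top_snps(outcome.selection) == [0, 1]

    def test_harvest_counts_partial_overlap(self):
        from gmdr.engine import SelectionResult

        sel = SelectionResult(
            K=4,
            top_n=1,
            per_fold_selected=[[(0, 1)], [(1, 2)], [(3, 4)], [(0, 1)]],
            cvc={},
            retained=[],
        )
        assert harvest_top_snps(sel) == [0, 1, 2, 3, 4]

    def test_conditioned_on_all_snps_equals_exhaustive(self):
        ds, scores, folds = _planted_dataset(seed=500, n_snps=6)
        full = exhaustive_search(ds, scores, folds)
        cond = conditioned_search(ds, scores, folds, list(range(6)), 2)
        assert [r.combination for r in cond.results] == [
            r.combination for r in full.results
        ]
        for a, b in zip(cond.results, full.results):
            assert a.testing_accuracy == pytest.approx(b.testing_accuracy, abs=1e-15)

    def test_subset_smaller_than_k_empty(self):
        ds, scores, folds = _planted_dataset(seed=600)
        outcome = conditioned_search(ds, scores, folds, [0, 1], 3)
        assert outcome.results == [] and outcome.n_combinations_evaluated == 0

    def test_subset_of_five_k_five_single_tuple(self):
        ds, scores, folds = _planted_dataset(seed=700, n_snps=6)
        outcome = conditioned_search(ds, scores, folds, [0, 1, 2, 3, 4], 5)
        assert outcome.n_combinations_evaluated == 1

    def test_combination_count_matches_binomial(self):
        ds, scores, folds = _planted_dataset(seed=800, n_snps=10)
        outcome = conditioned_search(ds, scores, folds, list(range(10)), 3)
        assert outcome.n_combinations_evaluated == 120  # C(10,3)


def _result(combo, cvc, acc, p, bound=False, K=10):
    return InteractionResult(
        combination=combo,
        cvc=cvc,
        K=K,
        training_accuracy=np.full(K, acc),
        testing_accuracy=acc,
        testing_accuracy_per_fold=np.full(K, acc),
        p_value=p,
        p_is_bound=bound,
        n_perm=int(round(1 / p)) if bound else 10_000,
    )


class TestSignificanceFilter:
    def test_boundary_cvc_and_bound_p(self):
        r = _result((0, 1), 7, 0.56, 1e-4, bound=True)
        assert significance_filter([r], 7, 1e-4) == [r]

    def test_cvc_six_removed(self):
        r = _result((0, 1), 6, 0.9, 1e-6)
        assert significance_filter([r], 7, 1e-4) == []

    def test_mixed_fixture_hand_filtered(self):
        results = [
            _result((0, 1), 10, 0.60, 1e-5),  # keep
            _result((0, 2), 7, 0.58, 1e-4, bound=True),  # keep (bound qualifies)
            _result((1, 2), 6, 0.62, 1e-6),  # CVC too low
            _result((2, 3), 9, 0.55, 5e-3),  # p too large
            _result((3, 4), 8, 0.57, 1e-4),  # keep
        ]
        kept = significance_filter(results, 7, 1e-4)
        # sorted by testing accuracy: 0.60, 0.58, 0.57
        assert [r.combination for r in kept] == [(0, 1), (0, 2), (3, 4)]

    def test_monotone_in_thresholds(self):
        results = [
            _result((0, 1), 8, 0.6, 1e-5),
            _result((0, 2), 7, 0.58, 1e-4),
            _result((1, 2), 10, 0.57, 1e-6),
        ]
        loose = {r.combination for r in significance_filter(results, 7, 1e-4)}
        tight_cvc = {r.combination for r in significance_filter(results, 8, 1e-4)}
        tight_p = {r.combination for r in significance_filter(results, 7, 1e-5)}
        assert tight_cvc <= loose and tight_p <= loose


class TestDetectCoreSnps:
    SNPS = [SNPInfo(f"rs{i}", "1", 1 + i * 2_000_000) for i in range(8)]

    def test_single_model_snp_not_core(self):
        res = [_result((0, 1), 10, 0.6, 1e-5)]
        assert detect_core_snps(res, self.SNPS, core_min_models=2) == []

    def test_two_orders_core(self):
        res = [
            _result((0, 1), 10, 0.6, 1e-5),
            _result((1, 2, 3, 4, 5), 8, 0.58, 1e-5),
        ]
        cores = detect_core_snps(res, self.SNPS, core_min_models=2)
        assert len(cores) == 1
        assert cores[0].snp_index == 1 and cores[0].orders == {2, 5}

    def test_six_model_fixture_hand_counted(self):
        res = [
            _result((0, 1), 10, 0.6, 1e-5),
            _result((0, 2), 9, 0.6, 1e-5),
            _result((0, 3), 8, 0.6, 1e-5),
            _result((1, 4, 5), 8, 0.59, 1e-5),
            _result((2, 4, 6), 8, 0.59, 1e-5),
            _result((4, 5, 6, 7), 7, 0.58, 1e-5),
        ]
        cores = detect_core_snps(res, self.SNPS, core_min_models=2)
        by_id = {c.snp_index: c for c in cores}
        # hand count: 0 in 3 models, 1/2 in 2, 4 in 3, 5/6 in 2, 3/7 in 1
        assert sorted(by_id) == [0, 1, 2, 4, 5, 6]
        assert by_id[0].n_models == 3 and by_id[4].n_models == 3
        assert by_id[4].orders == {3, 4}
        for c in cores:
            assert c.n_models >= 2  # report consistent with its own rule


class TestPowerSimulations:
    def test_attenuated_penetrance_recovers_pair_mostly(self):
        hits = 0
        reps = 25
        for i in range(reps):
            ds, scores, folds = _planted_dataset(
                seed=9000 + 10 * i, n=400, n_snps=6, high=0.9, low=0.1
            )
            outcome = exhaustive_search(ds, scores, folds)
            if outcome.results and outcome.results[0].combination == (0, 1):
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_planted_three_way_recovered_in_conditioned_search(self):
        from gmdr.simdata import PenetranceModel

        hits = 0
        reps = 10
        for i in range(reps):
            g = simulate_genotypes(600, default_snp_specs(8, maf=0.5), seed=50 + i)
            # three-locus checkerboard: affected iff an odd number of het loci
            het = (np.indices((3, 3, 3)) == 1).sum(axis=0) % 2
            model = PenetranceModel(loci=(0, 1, 2), table=het.astype(float))
            ph, _ = simulate_phenotype(g, model, "binary", seed=60 + i)
            ds = validate_dataset(g, ph, None)
            scores = compute_scores(ds.phenotype)
            folds = make_folds(600, 10, seed=70 + i, stratify_labels=ds.phenotype.values)
            outcome = conditioned_search(ds, scores, folds, list(range(8)), 3)
            if outcome.results and outcome.results[0].combination == (0, 1, 2):
                hits += 1
        assert hits >= 9
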