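"""The two-round procedure: entropy, composition, gating, pool, resampling."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import torc
from torc.classifier import ClassifierSpec
from torc.core import (
    TorcConfig,
    apportion,
    construct_reference_oracle,
    entropy,
    estimate_composition,
    expand_pool,
    resample_reference,
    run_torc,
    select_confident,
)
from torc.evaluation import score
from torc.simulate import SimSpec, simulate_pair
from torc.types import (
    CellMatrix,
    Composition,
    EntropyVector,
    LabeledDataset,
    ProbabilityMatrix,
)

from conftest import random_prob_matrix


def _pm(probs, types=None):
    probs = np.asarray(probs, dtype=float)
    types = types or [f"T{k}" for k in range(probs.shape[1])]
    ids = np.array([f"c{i}" for i in range(probs.shape[0])], dtype=object)
    return ProbabilityMatrix(probs, ids, types)


class TestEntropy:
    def test_closed_forms(self):
        p = _pm([[1, 0, 0, 0], [0.25, 0.25, 0.25, 0.25], [0.5, 0.5, 0, 0]])
        np.testing.assert_allclose(entropy(p).values,
                                   [0.0, np.log(4), np.log(2)], atol=1e-12)

    def test_matches_scipy_on_random_rows(self):
        rng = np.random.default_rng(0)
        probs = random_prob_matrix(rng, 200, 6)
        ours = entropy(_pm(probs)).values
        oracle = scipy.stats.entropy(probs, axis=1)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(2, 10), st.integers(0, 2**31 - 1))
    def test_bounded_and_zero_iff_onehot(self, k, seed):
        rng = np.random.default_rng(seed)
        probs = random_prob_matrix(rng, 20, k)
        h = entropy(_pm(probs)).values
        assert np.all(h >= 0.0) and np.all(h <= np.log(k) + 1e-12)
        onehot = np.eye(k)[rng.integers(0, k, 5)]
        assert np.all(entropy(_pm(onehot)).values == 0.0)


class TestEstimateComposition:
    def test_hard_counts_label_frequencies(self):
        p = _pm([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.1, 0.9]])
        comp = estimate_composition(p, "hard")
        assert comp.proportions.tolist() == [0.5, 0.5]
        assert comp.kind == "estimated_target"

    def test_soft_is_column_means(self):
        p = _pm([[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(
            estimate_composition(p, "soft").proportions, [0.5, 0.5]
        )

    def test_hard_equals_soft_on_onehot_rows(self):
        rng = np.random.default_rng(2)
        onehot = np.eye(3)[rng.integers(0, 3, 30)]
        p = _pm(onehot)
        np.testing.assert_allclose(
            estimate_composition(p, "hard").proportions,
            estimate_composition(p, "soft").proportions,
        )

    def test_hard_times_n_is_integer(self):
        rng = np.random.default_rng(3)
        p = _pm(random_prob_matrix(rng, 77, 4))
        props = estimate_composition(p, "hard").proportions
        np.testing.assert_allclose(props * 77, np.round(props * 77), atol=1e-9)


def _ev(values):
    return EntropyVector(np.asarray(values, dtype=float),
                         np.array([f"c{i}" for i in range(len(values))],
                                  dtype=object))


class TestSelectConfident:
    def test_all_equal_entropies_selects_everyone(self):
        cfg = TorcConfig(entropy_quantile=0.1)
        labels = np.array(["A"] * 5, dtype=object)
        assert len(select_confident(_ev([0.3] * 5), labels, cfg)) == 5

    def test_quantile_one_selects_everyone(self):
        cfg = TorcConfig(entropy_quantile=1.0)
        labels = np.array(["A", "A", "B", "B"], dtype=object)
        assert len(select_confident(_ev([0.1, 0.9, 0.2, 0.8]), labels, cfg)) == 4

    def test_tenth_quantile_of_ten_is_lowest_cell(self):
        entropies = [0.1 * i for i in range(1, 11)]
        labels = np.array(["A"] * 10, dtype=object)
        cfg = TorcConfig(entropy_quantile=0.10)
        got = select_confident(_ev(entropies), labels, cfg)
        # brute-force inclusive lower quantile over the ten values
        cut = sorted(entropies)[int(np.ceil(0.10 * 10)) - 1]
        brute = [f"c{i}" for i, e in enumerate(entropies) if e <= cut]
        assert got == brute == ["c0"]

    def test_per_type_gating_protects_rare_types(self):
        # global gating would take only type-A cells; per-type keeps one B
        entropies = [0.01, 0.02, 0.03, 0.04, 0.9, 1.0]
        labels = np.array(["A"] * 4 + ["B"] * 2, dtype=object)
        per_type = select_confident(_ev(entropies), labels,
                                    TorcConfig(entropy_quantile=0.4))
        assert "c4" in per_type
        global_gate = select_confident(
            _ev(entropies), labels,
            TorcConfig(entropy_quantile=0.4, per_type_gating=False),
        )
        assert "c4" not in global_gate


def _tiny_ref():
    rng = np.random.default_rng(0)
    m = CellMatrix(rng.poisson(5, (6, 4)).astype(float),
                   np.array([f"r{i}" for i in range(6)], dtype=object),
                   np.array([f"g{i}" for i in range(4)], dtype=object))
    return LabeledDataset(m, np.array(["A"] * 3 + ["B"] * 3, dtype=object))


def _tiny_target(n=5):
    rng = np.random.default_rng(1)
    return CellMatrix(rng.poisson(5, (n, 4)).astype(float),
                      np.array([f"t{i}" for i in range(n)], dtype=object),
                      np.array([f"g{i}" for i in range(4)], dtype=object))


class TestExpandPool:
    def test_empty_selection_is_identity(self):
        ref = _tiny_ref()
        assert expand_pool(ref, _tiny_target(), [], np.array([])) is ref

    def test_counts_labels_and_provenance(self):
        ref, target = _tiny_ref(), _tiny_target()
        first = np.array(["A", "B", "A", "B", "A"], dtype=object)
        pool = expand_pool(ref, target, ["t0", "t3"], first)
        assert pool.n_cells == 8
        assert pool.type_names == ref.type_names
        added = {str(c): l for c, l in zip(pool.matrix.cell_ids, pool.labels)
                 if str(c).startswith("target:")}
        assert added == {"target:t0": "A", "target:t3": "B"}
        assert pool.origin.tolist() == ["reference"] * 6 + ["target"] * 2

    def test_id_collision_detected(self):
        ref = _tiny_ref()
        ref.matrix.cell_ids[0] = "target:t0"
        with pytest.raises(ValueError, match="collision"):
            expand_pool(ref, _tiny_target(), ["t0"],
                        np.array(["A"] * 5, dtype=object))


class TestApportion:
    def test_stated_examples(self):
        assert apportion(Composition(np.array([1.0, 0.0]), ["A", "B"]),
                         50).tolist() == [50, 0]
        # 0.5/0.5 of 51: largest remainder, tie broken by type order
        assert apportion(Composition(np.array([0.5, 0.5]), ["A", "B"]),
                         51).tolist() == [26, 25]

    def test_within_one_cell_over_random_compositions(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = int(rng.integers(2, 8))
            props = rng.dirichlet(np.ones(k))
            size = int(rng.integers(k, 500))
            counts = apportion(Composition(props, [f"T{i}" for i in range(k)]),
                               size)
            assert counts.sum() == size
            assert np.all(np.abs(counts - props * size) < 1.0)

    def test_min_cells_floor_funded_by_most_abundant(self):
        comp = Composition(np.array([0.9, 0.06, 0.04]), ["A", "B", "C"])
        counts = apportion(comp, 100, min_cells_per_type=10)
        assert counts.tolist() == [80, 10, 10]

    def test_infeasible_size_errors(self):
        comp = Composition(np.array([0.5, 0.5]), ["A", "B"])
        with pytest.raises(ValueError):
            apportion(comp, 10, min_cells_per_type=10)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    def test_exact_sum_property(self, k, seed):
        rng = np.random.default_rng(seed)
        props = rng.dirichlet(np.ones(k))
        size = int(rng.integers(k, 300))
        counts = apportion(Composition(props, [f"T{i}" for i in range(k)]), size)
        assert counts.sum() == size and np.all(counts >= 0)


class TestResampleReference:
    def _pool(self, n_a=60, n_b=40):
        rng = np.random.default_rng(0)
        n = n_a + n_b
        m = CellMatrix(rng.poisson(5, (n, 3)).astype(float),
                       np.array([f"p{i}" for i in range(n)], dtype=object),
                       np.array(["g0", "g1", "g2"], dtype=object))
        labels = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
        return LabeledDataset(m, labels)

    def test_exact_composition_by_apportionment(self):
        pool = self._pool(700, 500)
        comp = Composition(np.array([0.7, 0.3]), ["A", "B"])
        out = resample_reference(pool, comp, 1000, TorcConfig(), rng_seed=1)
        counts = {t: int(np.sum(out.labels == t)) for t in ["A", "B"]}
        assert counts == {"A": 700, "B": 300}

    def test_zero_proportion_type_excluded(self):
        pool = self._pool()
        comp = Composition(np.array([1.0, 0.0]), ["A", "B"])
        out = resample_reference(pool, comp, 50, TorcConfig(), rng_seed=1)
        assert set(out.labels.tolist()) == {"A"}

    def test_replacement_fallback_duplicates_scarce_type(self):
        pool = self._pool(10, 90)
        comp = Composition(np.array([0.5, 0.5]), ["A", "B"])
        out = resample_reference(pool, comp, 80, TorcConfig(), rng_seed=2)
        assert int(np.sum(out.labels == "A")) == 40  # only 10 distinct cells
        assert len(set(out.matrix.cell_ids)) == out.n_cells  # ids deduplicated

    def test_without_fallback_caps_and_warns(self):
        pool = self._pool(10, 90)
        comp = Composition(np.array([0.5, 0.5]), ["A", "B"])
        cfg = TorcConfig(sample_with_replacement_fallback=False)
        out = resample_reference(pool, comp, 80, cfg, rng_seed=2)
        assert int(np.sum(out.labels == "A")) == 10

    def test_positive_mass_for_absent_type_errors(self):
        pool = self._pool()
        comp = Composition(np.array([0.5, 0.3, 0.2]), ["A", "B", "C"])
        with pytest.raises(ValueError, match="'C'|\\['C'\\]"):
            resample_reference(pool, comp, 50, TorcConfig(), rng_seed=0)

    def test_deterministic_given_seed(self):
        pool = self._pool()
        comp = Composition(np.array([0.6, 0.4]), ["A", "B"])
        a = resample_reference(pool, comp, 50, TorcConfig(), rng_seed=7)
        b = resample_reference(pool, comp, 50, TorcConfig(), rng_seed=7)
        assert a.matrix.cell_ids.tolist() == b.matrix.cell_ids.tolist()

    def test_own_composition_full_size_is_permutation(self):
        pool = self._pool(60, 40)
        out = construct_reference_oracle(pool, pool.composition(), 100, 3,
                                         TorcConfig(min_cells_per_type=0))
        assert sorted(out.matrix.cell_ids.tolist()) == \
            sorted(pool.matrix.cell_ids.tolist())

    def test_equal_composition_splits_evenly(self):
        pool = self._pool(200, 100)
        out = construct_reference_oracle(
            pool, Composition.equal(["A", "B"]), 300, 5, TorcConfig()
        )
        assert int(np.sum(out.labels == "A")) == 150


class TestRunTorc:
    def test_full_pipeline_deterministic(self, small_pair, fast_spec, fast_cfg):
        ref, target = small_pair
        r1 = run_torc(ref, target.matrix, fast_spec, fast_cfg)
        r2 = run_torc(ref, target.matrix, fast_spec, fast_cfg)
        assert r1.final_labels.tolist() == r2.final_labels.tolist()
        assert r1.child_seeds == r2.child_seeds
        np.testing.assert_array_equal(r1.entropies.values, r2.entropies.values)

    def test_result_contract(self, small_pair, fast_spec, fast_cfg):
        ref, target = small_pair
        res = run_torc(ref, target.matrix, fast_spec, fast_cfg)
        assert abs(res.estimated_composition.proportions.sum() - 1.0) < 1e-9
        target_ids = set(target.matrix.cell_ids.tolist())
        assert set(res.pool_added_cell_ids) <= target_ids
        assert len(res.final_labels) == target.n_cells

    def test_self_reference_round_trip_keeps_accuracy(self, small_pair,
                                                      fast_spec, fast_cfg):
        # target == reference (labels hidden): round 1 is training accuracy
        # and the second round does not wreck it
        ref, _ = small_pair
        res = run_torc(ref, ref.matrix, fast_spec, fast_cfg)
        acc1 = score(ref.labels, res.first_round_labels).accuracy
        acc2 = score(ref.labels, res.final_labels).accuracy
        assert acc1 >= 0.95
        assert acc2 >= acc1 - 0.05

    def test_stage_errors_are_named(self, small_pair, fast_spec, fast_cfg):
        ref, target = small_pair
        alien = CellMatrix(target.matrix.values,
                           target.matrix.cell_ids,
                           np.array([f"x{i}" for i in
                                     range(target.matrix.n_genes)], dtype=object))
        with pytest.raises(RuntimeError, match="intersect_genes"):
            run_torc(ref, alien, fast_spec, fast_cfg)
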