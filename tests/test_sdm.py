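import numpy as np
import pytest

from landgen import sdm
from landgen.geo import OccurrenceSet, haversine_km
from landgen.raster import GridSpec, SuitabilityMap
from landgen.synthetic import generate_occurrences

from conftest import make_stack


class TestPruneCorrelatedVariables:
    def test_identical_layers_one_removed(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 10))
        stack = make_stack({"a": a, "b": a.copy()})
        pruned, kept = sdm.prune_correlated_variables(stack)
        assert len(kept) == 1

    def test_uncorrelated_stack_unchanged(self):
        rng = np.random.default_rng(1)
        stack = make_stack({"a": rng.random((40, 40)), "b": rng.random((40, 40))})
        _, kept = sdm.prune_correlated_variables(stack)
        assert kept == ["a", "b"]

    def test_near_duplicate_trio_keeps_independent_layer(self):
        rng = np.random.default_rng(2)
        a = rng.random((30, 30))
        b = a + 1e-3 * rng.random((30, 30))
        c = rng.random((30, 30))
        stack = make_stack({"a": a, "b": b, "c": c})
        _, kept = sdm.prune_correlated_variables(stack)
        assert "c" in kept
        assert len(set(kept) & {"a", "b"}) == 1
        # verify against the pairwise r matrix computed directly
        r_ab = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert abs(r_ab) > 0.75

    def test_single_layer_warns(self):
        stack = make_stack({"a": np.random.default_rng(0).random((10, 10))})
        with pytest.warns(UserWarning):
            _, kept = sdm.prune_correlated_variables(stack)
        assert kept == ["a"]


class TestHeterogeneitySurface:
    def test_constant_layers_zero_surface(self):
        stack = make_stack({"a": np.full((12, 12), 3.0), "b": np.full((12, 12), 5.0)})
        with pytest.warns(UserWarning):
            het = sdm.heterogeneity_surface(stack)
        np.testing.assert_array_equal(het, 0.0)

    def test_linear_gradient_constant_interior_sd(self):
        # single layer = column index: PC1 reproduces the gradient up to
        # sign, so the 5x5 window SD of an arithmetic progression is
        # sqrt(2) * step in the interior (population SD of -2..2 times step)
        grad = np.tile(np.arange(20, dtype=float), (20, 1))
        stack = make_stack({"a": grad})
        het = sdm.heterogeneity_surface(stack, window=5)
        interior = het[2:-2, 2:-2]
        step = np.diff(np.unique(het[10, 2:-2]))
        assert np.allclose(interior, interior[0, 0], atol=1e-9)
        # closed form: SD over the 5x5 window of columns j-2..j+2
        z = (grad - grad.mean()) / grad.std()
        expected = np.std([z[0, 8], z[0, 9], z[0, 10], z[0, 11], z[0, 12]])
        assert interior[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_layer_rescaling(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((15, 15)), rng.random((15, 15))
        h1 = sdm.heterogeneity_surface(make_stack({"a": a, "b": b}))
        h2 = sdm.heterogeneity_surface(make_stack({"a": 100 * a + 7, "b": 0.01 * b}))
        np.testing.assert_allclose(h1, h2, atol=1e-9)


class TestRarefyOccurrences:
    def test_already_sparse_unchanged(self):
        occ = OccurrenceSet(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.0, 0.0]))
        out = sdm.rarefy_occurrences(occ, 50.0)  # 1 deg ~ 111 km apart
        assert len(out) == 3

    def test_coincident_points_keep_one(self):
        occ = OccurrenceSet(np.array([5.0, 5.0]), np.array([5.0, 5.0]))
        out = sdm.rarefy_occurrences(occ, 1.0)
        assert len(out) == 1

    def test_collinear_points_match_greedy_oracle(self):
        # 5 points spaced d apart on the equator; threshold 1.5 d
        lons = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        lats = np.zeros(5)
        d = haversine_km(0.0, 0.0, 0.1, 0.0)
        out = sdm.rarefy_occurrences(OccurrenceSet(lons, lats), 1.5 * d)
        # exhaustive greedy oracle in input order
        kept: list[int] = []
        for i in range(5):
            if all(
                haversine_km(lons[i], 0.0, lons[j], 0.0) >= 1.5 * d for j in kept
            ):
                kept.append(i)
        np.testing.assert_allclose(out.lons, lons[kept])

    def test_empty_input_empty_output(self):
        out = sdm.rarefy_occurrences(OccurrenceSet(np.array([]), np.array([])), 5.0)
        assert len(out) == 0


class TestPseudoAbsences:
    def test_exact_free_cells_returned(self):
        arr = np.full((3, 3), 1.0)
        arr[0, :] = np.nan  # mask top row
        stack = make_stack({"a": arr})
        grid = stack.grid
        # presences fill all but two eligible cells
        pres_cells = [(1, 0), (1, 1), (1, 2), (2, 0)]
        lons, lats = zip(*(grid.center_of(r, c) for r, c in pres_cells))
        pas = sdm.sample_pseudo_absences(
            stack, OccurrenceSet(np.array(lons), np.array(lats)), 2, seed=0
        )
        got = {grid.cell_of(lo, la) for lo, la in zip(pas.lons, pas.lats)}
        assert got == {(2, 1), (2, 2)}

    def test_fixed_seed_identical(self, climate):
        current, _ = climate
        occ = OccurrenceSet(np.array([101.0]), np.array([31.0]))
        a = sdm.sample_pseudo_absences(current, occ, 20, seed=5)
        b = sdm.sample_pseudo_absences(current, occ, 20, seed=5)
        np.testing.assert_array_equal(a.points(), b.points())

    def test_never_on_presence_cells(self, climate):
        current, _ = climate
        rng = np.random.default_rng(8)
        rows, cols = np.nonzero(current.mask)
        pick = rng.choice(len(rows), 30, replace=False)
        lons, lats = zip(*(current.grid.center_of(int(rows[i]), int(cols[i]))
                           for i in pick))
        occ = OccurrenceSet(np.array(lons), np.array(lats))
        pas = sdm.sample_pseudo_absences(current, occ, 50, seed=2)
        pres = {current.grid.cell_of(lo, la) for lo, la in zip(occ.lons, occ.lats)}
        pa_cells = {current.grid.cell_of(lo, la) for lo, la in zip(pas.lons, pas.lats)}
        assert not (pres & pa_cells)

    def test_insufficient_cells_raises(self):
        stack = make_stack({"a": np.ones((3, 3))})
        occ = OccurrenceSet(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            sdm.sample_pseudo_absences(stack, occ, 10, seed=0)


class TestTss:
    def test_perfect_classifier(self):
        assert sdm.tss(tp=50, fn=0, tn=50, fp=0) == 1.0

    def test_constant_classifier(self):
        assert sdm.tss(tp=50, fn=0, tn=0, fp=50) == 0.0

    def test_hand_arithmetic(self):
        assert sdm.tss(tp=40, fn=10, tn=30, fp=20) == pytest.approx(0.4)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            sdm.tss(tp=0, fn=0, tn=10, fp=5)


class TestFitEnsemble:
    def test_perfectly_separable_all_retained(self):
        grad = np.tile(np.linspace(-3, 3, 20), (20, 1))
        stack = make_stack({"a": grad})
        grid = stack.grid
        pres, abs_ = [], []
        for r in range(20):
            for c in range(20):
                (pres if grad[r, c] > 0.5 else abs_).append(grid.center_of(r, c))
        # keep a margin between classes so every split separates
        abs_ = [(lo, la) for lo, la in abs_
                if grad[grid.cell_of(lo, la)] < -0.5]
        p = OccurrenceSet(*map(np.array, zip(*pres)))
        a = OccurrenceSet(*map(np.array, zip(*abs_)))
        cfg = sdm.EnsembleConfig(n_repeats=2, seed=0)
        _, evals = sdm.fit_ensemble(p, a, stack, cfg)
        assert all(e.auc == 1.0 and e.tss == 1.0 and e.retained for e in evals)

    def test_permuted_labels_auc_near_half(self, climate):
        current, _ = climate
        rng = np.random.default_rng(9)
        rows, cols = np.nonzero(current.mask)
        pick = rng.choice(len(rows), 400, replace=True)
        lons, lats = zip(*(current.grid.center_of(int(rows[i]), int(cols[i]))
                           for i in pick))
        lons, lats = np.array(lons), np.array(lats)
        # random halves: labels carry no signal
        p = OccurrenceSet(lons[:200], lats[:200])
        a = OccurrenceSet(lons[200:], lats[200:])
        cfg = sdm.EnsembleConfig(algorithms=("glm",), n_repeats=5, seed=1)
        _, evals = sdm.fit_ensemble(p, a, current, cfg)
        mean_auc = np.mean([e.auc for e in evals])
        assert 0.4 <= mean_auc <= 0.6

    def test_retained_flag_matches_gate(self, climate):
        current, _ = climate
        beta = np.zeros(current.n_layers + 1)
        beta[1] = 2.0
        occ, _ = generate_occurrences(current, beta, 100, seed=3)
        pas = sdm.sample_pseudo_absences(current, occ, 100, seed=4)
        cfg = sdm.EnsembleConfig(n_repeats=2, seed=2)
        _, evals = sdm.fit_ensemble(occ, pas, current, cfg)
        for e in evals:
            assert e.retained == (e.auc > 0.6 and e.tss > 0.6)

    def test_too_few_presences_raises(self, climate):
        current, _ = climate
        occ = OccurrenceSet(np.array([101.0]), np.array([31.0]))
        with pytest.raises(ValueError):
            sdm.fit_ensemble(occ, occ, current)


class TestEnsemblePredict:
    def _constant_model(self, value, stack):
        class Const:
            def predict_proba(self, X):
                p = np.full(len(X), value)
                return np.column_stack([1 - p, p])

        mean = np.zeros(stack.n_layers)
        sd = np.ones(stack.n_layers)
        return sdm.FittedModel("const", 0, Const(), mean, sd)

    def test_single_retained_model_passthrough(self, climate):
        current, _ = climate
        m = self._constant_model(0.3, current)
        ev = sdm.ModelEvaluation("const", 0, 0.9, 0.8, True)
        out = sdm.ensemble_predict([m], [ev], current)
        np.testing.assert_allclose(out.values[current.mask], 0.3)

    def test_unweighted_mean_of_two_models(self, climate):
        current, _ = climate
        ms = [self._constant_model(0.2, current), self._constant_model(0.8, current)]
        evs = [sdm.ModelEvaluation("c", i, 0.9, 0.9, True) for i in range(2)]
        out = sdm.ensemble_predict(ms, evs, current)
        np.testing.assert_allclose(out.values[current.mask], 0.5)

    def test_zero_retained_raises(self, climate):
        current, _ = climate
        m = self._constant_model(0.5, current)
        ev = sdm.ModelEvaluation("const", 0, 0.5, 0.1, False)
        with pytest.raises(ValueError):
            sdm.ensemble_predict([m], [ev], current)


class TestLptAndBinarize:
    def _suit(self, values, grid=None):
        values = np.asarray(values, dtype=float)
        grid = grid or GridSpec(0.0, 0.0, 1.0, *values.shape)
        return SuitabilityMap(grid, values)

    def test_lpt_is_minimum_presence_suitability(self):
        suit = self._suit([[0.9, 0.3], [0.7, 0.1]])
        pts = OccurrenceSet(np.array([0.5, 1.5, 0.5]), np.array([1.5, 1.5, 0.5]))
        # cells (0,0)=0.9, (0,1)=0.3, (1,0)=0.7
        assert sdm.lpt_threshold(suit, pts) == pytest.approx(0.3)

    def test_lpt_binarization_keeps_all_presences(self, climate):
        current, _ = climate
        beta = np.zeros(current.n_layers + 1)
        beta[1] = 2.0
        occ, suit = generate_occurrences(current, beta, 80, seed=5)
        lpt = sdm.lpt_threshold(suit, occ)
        b = sdm.binarize(suit, lpt)
        for lon, lat in zip(occ.lons, occ.lats):
            assert b.binary[b.grid.cell_of(lon, lat)]

    def test_binarize_extremes_and_monotonicity(self):
        rng = np.random.default_rng(1)
        suit = self._suit(rng.random((6, 6)))
        assert sdm.binarize(suit, 0.0).binary.all()
        assert not sdm.binarize(suit, 1.0 + 1e-9).binary.any()
        lo = sdm.binarize(suit, 0.3).binary
        hi = sdm.binarize(suit, 0.6).binary
        assert np.all(hi <= lo)

    def test_empty_presences_raise(self):
        suit = self._suit(np.ones((4, 4)))
        with pytest.raises(ValueError):
            sdm.lpt_threshold(suit, OccurrenceSet(np.array([]), np.array([])))


class TestRangeShift:
    def _binary_map(self, grid, cells, scenario):
        vals = np.zeros(grid.shape)
        for r, c in cells:
            vals[r, c] = 1.0
        m = SuitabilityMap(grid, vals, scenario)
        return sdm.binarize(m, 0.5)

    def test_identical_grids_no_change(self, flat_grid):
        cur = self._binary_map(flat_grid, [(0, 0), (1, 1)], "current")
        fut = self._binary_map(flat_grid, [(0, 0), (1, 1)], "future")
        rs = sdm.range_shift(cur, fut)
        assert rs.area_km2["expansion"] == 0
        assert rs.area_km2["contraction"] == 0
        assert rs.percent_change == pytest.approx(0.0)

    def test_disjoint_grids(self, flat_grid):
        cur = self._binary_map(flat_grid, [(0, 0)], "current")
        fut = self._binary_map(flat_grid, [(2, 2)], "future")
        rs = sdm.range_shift(cur, fut)
        assert rs.area_km2["stable"] == 0
        assert rs.area_km2["contraction"] == pytest.approx(rs.current_area_km2)

    def test_hand_counted_percent_change(self, flat_grid):
        # 4 stable + 2 lost = 6 current; 4 stable + 1 gained = 5 future
        cur_cells = [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]
        fut_cells = [(0, 0), (0, 1), (1, 0), (1, 1), (2, 2)]
        rs = sdm.range_shift(
            self._binary_map(flat_grid, cur_cells, "current"),
            self._binary_map(flat_grid, fut_cells, "future"),
        )
        # near-equator cells are equal-area to ~1e-8
        assert rs.percent_change == pytest.approx((5 - 6) / 6 * 100, rel=1e-6)

    def test_area_conservation(self, flat_grid):
        rng = np.random.default_rng(2)
        cur = self._binary_map(flat_grid, [(r, c) for r in range(3) for c in range(3)
                                           if rng.random() < 0.5], "current")
        fut = self._binary_map(flat_grid, [(r, c) for r in range(3) for c in range(3)
                                           if rng.random() < 0.5], "future")
        rs = sdm.range_shift(cur, fut)
        assert rs.area_km2["expansion"] + rs.area_km2["stable"] == pytest.approx(
            rs.future_area_km2
        )
        assert rs.area_km2["contraction"] + rs.area_km2["stable"] == pytest.approx(
            rs.current_area_km2
        )


class TestVariableImportance:
    def _linear_model(self, coef, stack):
        class Lin:
            def predict_proba(self, X):
                p = 1 / (1 + np.exp(-(X @ coef)))
                return np.column_stack([1 - p, p])

        return sdm.FittedModel("lin", 0, Lin(),
                               np.zeros(stack.n_layers), np.ones(stack.n_layers))

    def test_ignored_variable_near_zero_importance(self):
        rng = np.random.default_rng(4)
        stack = make_stack({"a": rng.random((40, 40)), "b": rng.random((40, 40))})
        m = self._linear_model(np.array([3.0, 0.0]), stack)
        imp = sdm.variable_importance(m, stack, seed=0)
        assert imp["b"] < 0.02
        assert imp["a"] > imp["b"]

    def test_importance_bounded(self, climate):
        current, _ = climate
        coef = np.zeros(current.n_layers)
        coef[0] = 2.0
        m = self._linear_model(coef, current)
        imp = sdm.variable_importance(m, current, seed=1)
        assert all(0 <= v <= 2 for v in imp.values())
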