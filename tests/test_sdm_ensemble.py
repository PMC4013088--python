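"""Pseudo-absence selection, AUC/TSS, thresholding, replicates, ensembling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import invasimap as iv
from invasimap.sdm_ensemble import LEARNERS, ModelReplicate, TrainingSet, replicate_metrics


def occ_from_cells(grid, cells_by_species):
    rows = []
    for code, cells in cells_by_species.items():
        for r, c in cells:
            x, y = grid.cell_center(r, c)
            rows.append({"species": code, "x": x, "y": y})
    return iv.OccurrenceTable(pd.DataFrame(rows), thinned=True)


class TestPseudoAbsences:
    def test_disjoint_two_species(self):
        grid = iv.Grid(4, 4, 250.0)
        occ = occ_from_cells(grid, {"SpAaaa": [(0, 0), (0, 1)], "SpBbbb": [(2, 2), (3, 3)]})
        pa = iv.select_pseudo_absences(occ, "SpAaaa", grid)
        assert set(map(tuple, pa)) == {(2, 2), (3, 3)}

    def test_shared_cell_excluded(self):
        grid = iv.Grid(4, 4, 250.0)
        occ = occ_from_cells(grid, {"SpAaaa": [(1, 1)], "SpBbbb": [(1, 1), (2, 2)]})
        pa = iv.select_pseudo_absences(occ, "SpAaaa", grid)
        assert set(map(tuple, pa)) == {(2, 2)}

    def test_three_species_union_minus_focal(self):
        grid = iv.Grid(5, 5, 250.0)
        occ = occ_from_cells(
            grid,
            {
                "SpAaaa": [(0, 0), (1, 1)],
                "SpBbbb": [(1, 1), (2, 2), (3, 3)],
                "SpCccc": [(3, 3), (4, 4)],
            },
        )
        pa = iv.select_pseudo_absences(occ, "SpAaaa", grid)
        assert set(map(tuple, pa)) == {(2, 2), (3, 3), (4, 4)}

    def test_single_species_errors(self):
        grid = iv.Grid(4, 4, 250.0)
        occ = occ_from_cells(grid, {"SpAaaa": [(0, 0)]})
        with pytest.raises(ValueError, match="pseudo-absence"):
            iv.select_pseudo_absences(occ, "SpAaaa", grid)

    def test_unthinned_rejected(self):
        grid = iv.Grid(4, 4, 250.0)
        occ = occ_from_cells(grid, {"SpAaaa": [(0, 0)], "SpBbbb": [(1, 1)]})
        occ.thinned = False
        with pytest.raises(ValueError, match="thinned"):
            iv.select_pseudo_absences(occ, "SpAaaa", grid)


class TestAUC:
    def test_perfect_separation(self):
        assert iv.auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_worked_example(self):
        assert iv.auc([0.8, 0.4], [0.6, 0.2]) == pytest.approx(0.75)

    def test_all_ties(self):
        assert iv.auc([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iv.auc([], [0.5])

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=1, max_size=20),
        st.lists(st.floats(0, 1, width=32), min_size=1, max_size=20),
    )
    def test_complement_symmetry(self, a, b):
        assert iv.auc(a, b) + iv.auc(b, a) == pytest.approx(1.0)


class TestTSS:
    def test_perfect(self):
        assert iv.tss(10, 0, 10, 0) == pytest.approx(1.0)

    def test_worked_example(self):
        assert iv.tss(40, 10, 30, 20) == pytest.approx(0.4)

    def test_inverted(self):
        assert iv.tss(0, 10, 0, 10) == pytest.approx(-1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            iv.tss(0, 0, 5, 5)


class TestSensSpecThreshold:
    def test_separated_returns_lowest_presence(self):
        assert iv.sens_spec_threshold([0.9, 0.8], [0.2, 0.1]) == 0.8

    def test_single_pair(self):
        assert iv.sens_spec_threshold([0.7], [0.3]) == 0.7

    @staticmethod
    def brute_force(p, a):
        """Independent oracle: exhaustive scan with explicit tie-breaks."""
        p, a = np.asarray(p), np.asarray(a)
        best = None
        for t in sorted(set(p) | set(a)):
            se = float((p >= t).mean())
            sp = float((a < t).mean())
            key = (abs(se - sp), -(se + sp - 1.0), t)
            if best is None or key < best[0]:
                best = (key, t)
        return best[1]

    @given(
        st.lists(st.floats(0, 1, width=16), min_size=1, max_size=15),
        st.lists(st.floats(0, 1, width=16), min_size=1, max_size=15),
    )
    def test_matches_exhaustive_oracle(self, p, a):
        assert iv.sens_spec_threshold(p, a) == self.brute_force(p, a)

    def test_tss_identity_at_threshold(self):
        rng = np.random.default_rng(8)
        p = rng.normal(0.7, 0.2, 200)
        a = rng.normal(0.3, 0.2, 200)
        t = iv.sens_spec_threshold(p, a)
        se = (p >= t).mean()
        sp = (a < t).mean()
        # at the equal-error threshold TSS collapses to 2*Se - 1
        assert se + sp - 1 == pytest.approx(2 * se - 1, abs=0.02)


def toy_training_set(n=60, informative=True, seed=0, n_cov=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_cov))
    y = np.concatenate([np.ones(n // 2), np.zeros(n - n // 2)])
    if informative:
        X[:, 0] += np.where(y == 1, 2.0, -2.0)
    # non-overlapping synthetic cells; fits inside the 8x8 test grid at n <= 64
    n_pres_rows = -(-(n // 2) // 8)
    pres = np.array([(i // 8, i % 8) for i in range(n // 2)])
    absn = np.array([(n_pres_rows + i // 8, i % 8) for i in range(n - n // 2)])
    return TrainingSet("ToySpec", pres, absn, X, y, [f"cov{i+1:02d}" for i in range(n_cov)])


@pytest.fixture
def tiny_stack():
    grid = iv.Grid(8, 8, 250.0)
    return iv.generate_covariates(grid, n_layers=3, spatial_range=2, seed=0)


class TestFitReplicates:
    def test_replicate_count(self, tiny_stack):
        reps = iv.fit_replicates(toy_training_set(), tiny_stack, n_reps=3, seed=0)
        assert len(reps) == 3 * len(LEARNERS)
        assert {r.learner_id for r in reps} == set(LEARNERS)

    def test_separable_species_high_auc(self, tiny_stack):
        reps = iv.fit_replicates(
            toy_training_set(informative=True), tiny_stack, n_reps=5, seed=1
        )
        assert replicate_metrics(reps)["auc"].median() > 0.95

    def test_permuted_labels_null_auc(self, tiny_stack):
        reps = iv.fit_replicates(
            toy_training_set(informative=False, n=100, seed=3),
            tiny_stack, n_reps=50, seed=2, learners=("maxent",),
        )
        assert replicate_metrics(reps)["auc"].median() == pytest.approx(0.5, abs=0.05)

    def test_determinism(self, tiny_stack):
        r1 = iv.fit_replicates(toy_training_set(), tiny_stack, n_reps=2, seed=5)
        r2 = iv.fit_replicates(toy_training_set(), tiny_stack, n_reps=2, seed=5)
        assert [r.auc for r in r1] == [r.auc for r in r2]

    def test_auc_tss_within_ranges(self, tiny_stack):
        reps = iv.fit_replicates(toy_training_set(), tiny_stack, n_reps=3, seed=6)
        m = replicate_metrics(reps)
        assert m["auc"].between(0, 1).all()
        assert m["tss"].between(-1, 1).all()


def constant_replicate(grid, value, auc_score):
    return ModelReplicate(
        learner_id="maxent", split_seed=0, auc=auc_score, tss=0.5, threshold=0.5,
        prediction=iv.RasterLayer(grid, np.full(grid.shape, value)),
    )


class TestEnsemble:
    def make_ts(self, grid):
        pres = np.array([(0, c) for c in range(5)])
        absn = np.array([(1, c) for c in range(5)])
        X = np.zeros((10, 1))
        y = np.concatenate([np.ones(5), np.zeros(5)])
        return TrainingSet("ToySpec", pres, absn, X, y, ["cov01"])

    def test_auc_weighted_mean(self):
        grid = iv.Grid(3, 5, 250.0)
        reps = [constant_replicate(grid, 1.0, 0.9), constant_replicate(grid, 0.0, 0.6)]
        em = iv.ensemble(reps, self.make_ts(grid))
        assert em.weighted_mean.values[0, 0] == pytest.approx(0.9 / 1.5)
        assert em.n_included == 2

    def test_unanimous_committee(self):
        grid = iv.Grid(3, 5, 250.0)
        reps = [constant_replicate(grid, 0.9, 0.8), constant_replicate(grid, 0.8, 0.7)]
        em = iv.ensemble(reps, self.make_ts(grid))
        assert np.all(em.committee_avg.values == 1.0)

    def test_single_member_identity(self):
        grid = iv.Grid(3, 5, 250.0)
        rep = constant_replicate(grid, 0.7, 0.9)
        em = iv.ensemble([rep], self.make_ts(grid))
        assert np.array_equal(em.weighted_mean.values, rep.prediction.values)

    def test_inclusion_bound_one_errors(self):
        grid = iv.Grid(3, 5, 250.0)
        reps = [constant_replicate(grid, 0.9, 0.95)]
        with pytest.raises(ValueError, match="inclusion"):
            iv.ensemble(reps, self.make_ts(grid), inclusion_auc=1.0)

    def test_weighted_mean_in_member_hull(self, tiny_stack):
        reps = iv.fit_replicates(toy_training_set(), tiny_stack, n_reps=3, seed=9)
        ts = toy_training_set()
        em = iv.ensemble(reps, ts)
        included = [r for r in reps if r.auc > 0.5]
        stackmin = np.min([r.prediction.values for r in included], axis=0)
        stackmax = np.max([r.prediction.values for r in included], axis=0)
        ok = np.isfinite(em.weighted_mean.values)
        assert np.all(em.weighted_mean.values[ok] >= stackmin[ok] - 1e-12)
        assert np.all(em.weighted_mean.values[ok] <= stackmax[ok] + 1e-12)
        assert np.nanmin(em.committee_avg.values) >= 0
        assert np.nanmax(em.committee_avg.values) <= 1
        # binary layer is the thresholded weighted mean
        assert np.array_equal(
            em.binary.values[ok], (em.weighted_mean.values[ok] >= em.threshold).astype(float)
        )


class LinearToy:
    """Bare logistic scorer with known coefficients, for interpretation tests."""

    def __init__(self, coefs):
        self.coefs = np.asarray(coefs, dtype=float)

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-(X @ self.coefs)))
        return np.column_stack([1 - p, p])


class TestInterpretation:
    def test_zero_coefficient_unimportant(self, tiny_stack):
        model = LinearToy([3.0, 0.0, 0.0])
        imp = iv.variable_importance(model, tiny_stack, n_shuffles=3, seed=0)
        assert imp["cov01"] > 0.5
        assert imp["cov02"] == pytest.approx(0.0, abs=0.05)
        assert imp["cov03"] == pytest.approx(0.0, abs=0.05)

    def test_constant_prediction_undefined(self, tiny_stack):
        model = LinearToy([0.0, 0.0, 0.0])
        imp = iv.variable_importance(model, tiny_stack, n_shuffles=2, seed=0)
        assert all(np.isnan(v) for v in imp.values())

    def test_response_curve_flat_for_ignored_covariate(self, tiny_stack):
        model = LinearToy([2.0, 0.0, 0.0])
        curve = iv.response_curve(model, tiny_stack, "cov02", n_points=10)
        assert curve["prediction"].std() == pytest.approx(0.0, abs=1e-12)

    def test_response_curve_monotone_for_driver(self, tiny_stack):
        model = LinearToy([2.0, 0.0, 0.0])
        curve = iv.response_curve(model, tiny_stack, "cov01", n_points=25)
        assert np.all(np.diff(curve["prediction"]) >= 0)

    def test_response_curve_two_points_span_range(self, tiny_stack):
        model = LinearToy([1.0, 0.0, 0.0])
        curve = iv.response_curve(model, tiny_stack, "cov01", n_points=2)
        X, _ = tiny_stack.full_matrix()
        assert len(curve) == 2
        assert curve["value"].tolist() == [X[:, 0].min(), X[:, 0].max()]

    def test_unknown_covariate_rejected(self, tiny_stack):
        with pytest.raises(KeyError):
            iv.response_curve(LinearToy([1, 0, 0]), tiny_stack, "nope")
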