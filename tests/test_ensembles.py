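import numpy as np
import pytest

import pbme.ensembles as ens
from pbme.dynamics import Trajectory
from pbme.ensembles import (
    EnsembleError,
    adaboost_update,
    bootstrap_replicate,
    combine,
    confidence,
    learn_bagging_ensemble,
    learn_boosting_ensemble,
    learn_ls_ensemble,
    learn_ls_ensemble_fast,
)
from pbme.fitting import DEConfig, estimate_parameters

from conftest import make_decay_dataset

TINY_DE = DEConfig(population=8, evals_per_param=25, seed=0)


def _traj(values, t=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) if t is None else np.asarray(t, float)
    return Trajectory(t, {"y": values})


@pytest.fixture(scope="module")
def decay_fit(pp_library, decay_structure):
    data = make_decay_dataset(rate=0.5)
    return data, estimate_parameters(pp_library, decay_structure, data, cfg=TINY_DE)


class TestConfidence:
    def test_perfect_fit_has_zero_beta(self, decay_fit):
        data, model = decay_fit
        exact = model.simulate(data)
        frame = data.frame.copy()
        frame["x.d"] = exact["x.d"]
        from pbme.dynamics import TimeSeriesDataset

        report = confidence(model, TimeSeriesDataset(frame, endogenous=("x.d",)))
        assert report.max_disc == 0.0
        assert report.beta == 0.0

    def test_two_point_hand_example(self, decay_fit, monkeypatch):
        # residuals (1, 2): maxDisc = 4, avg loss = (1/4 + 4/4)/2 = 0.625,
        # beta = 0.625 / 0.375 ~= 1.667
        data, model = decay_fit
        monkeypatch.setattr(
            ens, "_squared_discrepancies", lambda m, d: np.array([1.0, 4.0])
        )
        report = confidence(model, data)
        assert report.max_disc == 4.0
        assert report.avg_loss == pytest.approx(0.625)
        assert report.beta == pytest.approx(1.0 / 0.6, rel=1e-6)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
    def test_beta_invariant_under_residual_scaling(self, decay_fit, monkeypatch, scale):
        data, model = decay_fit
        base = np.array([0.5, 2.0, 1.25, 4.0])
        monkeypatch.setattr(ens, "_squared_discrepancies", lambda m, d: base.copy())
        beta_1 = confidence(model, data).beta
        monkeypatch.setattr(ens, "_squared_discrepancies", lambda m, d: base * scale**2)
        assert confidence(model, data).beta == pytest.approx(beta_1, rel=1e-12)

    def test_failed_simulation_gets_worst_confidence(self, decay_fit, monkeypatch):
        data, model = decay_fit
        monkeypatch.setattr(ens, "_squared_discrepancies", lambda m, d: None)
        assert confidence(model, data).beta == ens.BETA_MAX


class TestCombine:
    def test_identical_constituents_reproduce_the_trajectory(self):
        base = _traj([1.0, 5.0, 2.0])
        for scheme in ens.SCHEMES:
            out = combine([base, base, base], [0.2, 0.4, 0.9], scheme)
            assert np.allclose(out["y"], base["y"])

    def test_average_of_constant_trajectories(self):
        out = combine([_traj([1.0] * 4), _traj([3.0] * 4)], [0.5, 0.5], "average")
        assert np.allclose(out["y"], 2.0)

    def test_median_of_two_equals_average(self):
        a, b = _traj([1.0, 10.0]), _traj([3.0, 0.0])
        med = combine([a, b], [1.0, 1.0], "median")
        avg = combine([a, b], [1.0, 1.0], "average")
        assert np.allclose(med["y"], avg["y"])

    def test_weighted_median_hand_example(self):
        # values (1, 2, 10) with weights (0.2, 0.5, 0.3) -> 2
        trajs = [_traj([1.0]), _traj([2.0]), _traj([10.0])]
        betas = np.exp(-np.array([0.2, 0.5, 0.3]))  # ln(1/beta) gives the weights
        out = combine(trajs, betas, "weighted-median")
        assert out["y"][0] == 2.0

    @pytest.mark.parametrize("scheme", ens.SCHEMES)
    def test_prediction_stays_inside_constituent_envelope(self, scheme):
        rng = np.random.default_rng(5)
        trajs = [_traj(rng.normal(size=20)) for _ in range(7)]
        betas = rng.uniform(0.05, 0.95, size=7)
        out = combine(trajs, betas, scheme)
        stack = np.vstack([tr["y"] for tr in trajs])
        assert np.all(out["y"] >= stack.min(axis=0) - 1e-12)
        assert np.all(out["y"] <= stack.max(axis=0) + 1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(EnsembleError, match="time grids"):
            combine([_traj([1.0, 2.0]), _traj([1.0, 2.0], t=[0.0, 2.0])], [1, 1], "average")

    def test_all_zero_weights_rejected(self):
        trajs = [_traj([1.0]), _traj([2.0])]
        with pytest.raises(EnsembleError, match="weights"):
            combine(trajs, [5.0, 7.0], "weighted-average")  # beta > 1: zero weight


class TestLibrarySampling:
    def test_k1_returns_best_of_one_sample(self, pp_library, decay_incomplete):
        data = make_decay_dataset(rate=0.5)
        result = learn_ls_ensemble(
            pp_library, data, data, decay_incomplete, k=1, cfg=TINY_DE, seed=4
        )
        assert len(result) == 1

    def test_duplicates_mode_returns_exactly_k(self, pp_library, decay_incomplete):
        data = make_decay_dataset(rate=0.5)
        result = learn_ls_ensemble_fast(
            pp_library, data, data, decay_incomplete, allow_duplicates=True, k=10, cfg=TINY_DE, seed=4
        )
        assert len(result) == 10

    def test_without_duplicates_collects_distinct_constituents(self, pp_library, pp_incomplete):
        data = make_decay_dataset(rate=0.5, t_stop=6.0)
        frame = data.frame.rename(columns={"x.d": "prey.d"})
        frame["predator.d"] = np.linspace(2.0, 1.0, len(frame))
        from pbme.dynamics import TimeSeriesDataset

        two_var = TimeSeriesDataset(frame, endogenous=("prey.d", "predator.d"))
        result = learn_ls_ensemble_fast(
            pp_library, two_var, two_var, pp_incomplete,
            allow_duplicates=False, k=4, cfg=TINY_DE, seed=8,
        )
        assert len(result) == 4
        keys = [m.structure.key for m, _ in result.constituents]
        assert len(set(keys)) == 4  # pigeonhole over the 4-structure space

    def test_without_duplicates_fails_on_too_small_space(self, pp_library, decay_incomplete):
        data = make_decay_dataset(rate=0.5)
        with pytest.raises(EnsembleError, match="distinct"):
            learn_ls_ensemble_fast(
                pp_library, data, data, decay_incomplete,
                allow_duplicates=False, k=3, cfg=TINY_DE, seed=1,
            )

    def test_k_zero_rejected(self, pp_library, decay_incomplete):
        data = make_decay_dataset()
        with pytest.raises(EnsembleError, match="k"):
            learn_ls_ensemble_fast(pp_library, data, data, decay_incomplete, k=0, cfg=TINY_DE)

    def test_fast_and_naive_variants_agree_exactly(self, pp_library, pp_incomplete):
        data = make_decay_dataset(rate=0.5, t_stop=6.0)
        frame = data.frame.rename(columns={"x.d": "prey.d"})
        frame["predator.d"] = np.linspace(2.0, 1.0, len(frame))
        from pbme.dynamics import TimeSeriesDataset

        two_var = TimeSeriesDataset(frame, endogenous=("prey.d", "predator.d"))
        kw = dict(allow_duplicates=True, k=6, cfg=TINY_DE, seed=21)
        fast = learn_ls_ensemble_fast(pp_library, two_var, two_var, pp_incomplete, **kw)
        naive = learn_ls_ensemble(pp_library, two_var, two_var, pp_incomplete, **kw)
        assert len(fast) == len(naive)
        for (fm, fb), (nm, nb) in zip(fast.constituents, naive.constituents):
            assert fm.structure.key == nm.structure.key
            assert np.array_equal(fm.params, nm.params)
            assert fb == nb


class TestBagging:
    def test_bootstrap_replicate_preserves_order_and_coverage(self):
        rng = np.random.default_rng(77)
        n = 1000
        counts = bootstrap_replicate(rng, n)
        assert counts.sum() == n
        # retained points are a subset of the ordered grid; expected coverage 1 - 1/e
        assert abs(np.count_nonzero(counts) / n - (1 - 1 / np.e)) < 0.02

    def test_degenerate_replicates_are_redrawn(self):
        rng = np.random.default_rng(0)
        counts = bootstrap_replicate(rng, 2)
        assert np.count_nonzero(counts) >= 2

    def test_bagging_learns_k_constituents(self, pp_library, decay_incomplete):
        data = make_decay_dataset(rate=0.5)
        result = learn_bagging_ensemble(
            pp_library, data, data, decay_incomplete, k=3, cfg=TINY_DE, seed=2
        )
        assert len(result) == 3
        assert result.method == "bagging"


class TestBoosting:
    def test_update_rule_shifts_weight_to_worst_points(self):
        dist = np.full(4, 0.25)
        losses = np.array([0.0, 0.2, 0.6, 1.0])
        new = adaboost_update(dist, losses, beta=0.25)
        assert new.sum() == pytest.approx(1.0, abs=1e-12)
        assert new[3] > new[0]  # worst-fit point gains over best-fit
        assert np.all(np.diff(new) > 0)  # monotone in the loss for beta < 1

    def test_distribution_stays_normalized_over_iterations(self):
        rng = np.random.default_rng(3)
        dist = np.full(50, 0.02)
        for _ in range(20):
            dist = adaboost_update(dist, rng.uniform(0, 1, 50), rng.uniform(0.05, 0.9))
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_boosting_learns_and_stops_cleanly(self, pp_library, decay_incomplete):
        data = make_decay_dataset(rate=0.5)
        result = learn_boosting_ensemble(
            pp_library, data, data, decay_incomplete, k=3, cfg=TINY_DE, seed=6
        )
        assert 1 <= len(result) <= 3
        assert all(b >= 0 for b in result.betas)

    def test_immediate_high_loss_yields_single_constituent(self, pp_library, decay_incomplete, monkeypatch):
        data = make_decay_dataset(rate=0.5)
        # a discrepancy profile whose uniform average loss is >= 0.5
        monkeypatch.setattr(
            ens, "_squared_discrepancies", lambda m, d: np.linspace(0.5, 1.0, len(d))
        )
        with pytest.warns(UserWarning, match="first iteration"):
            result = learn_boosting_ensemble(
                pp_library, data, data, decay_incomplete, k=5, cfg=TINY_DE, seed=6
            )
        assert len(result) == 1


class TestEnsembleContainer:
    def test_serialization_mentions_structures_and_betas(self, pp_library, decay_incomplete):
        data = make_decay_dataset(rate=0.5)
        result = learn_ls_ensemble_fast(
            pp_library, data, data, decay_incomplete, k=2, cfg=TINY_DE, seed=4
        )
        text = result.to_text()
        assert "decay=Decay" in text
        assert "beta:" in text
        assert "scheme: average" in text
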