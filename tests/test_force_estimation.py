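"""Estimator tests: slope, anchored prediction, RMSE/NRMSE, cross-validation."""

import numpy as np
import pytest

from earforce import (
    DegenerateInputError,
    RangeError,
    Session,
    SubjectParams,
    TrainingSet,
    cross_validate,
    estimated_width,
    fold_mean_slope,
    generate_session,
    nrmse,
    predict,
    rmse,
    slope,
)
from earforce.signal_model import RUN_LENGTH
from helpers import affine_session, make_run


def grid_search_slope(e, f, coarse=(-40.0, 40.0, 0.1), fine_step=0.002):
    """Independent oracle: dense grid search over (a, b) minimizing
    the sum of squared residuals, coarse pass then local refinement."""
    e = np.asarray(e, float)
    f = np.asarray(f, float)
    n = e.size
    se, sf, see, sef, sff = e.sum(), f.sum(), (e * e).sum(), (e * f).sum(), (f * f).sum()

    def sse(a, b):
        # closed-form expansion of sum((f - a e - b)^2) on the grid
        return (
            sff
            - 2 * a * sef
            - 2 * b * sf
            + a**2 * see
            + 2 * a * b * se
            + n * b**2
        )

    def argmin_on(a_grid, b_grid):
        A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
        vals = sse(A, B)
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        return a_grid[i], b_grid[j]

    a_lo, a_hi, a_step = coarse
    a_best, b_best = argmin_on(
        np.arange(a_lo, a_hi + a_step, a_step),
        np.arange(-15.0, 15.0, 0.01),
    )
    # fine pass: the SSE surface couples a and b strongly (e is not
    # centered), so b must be gridded much finer than a
    a_best, b_best = argmin_on(
        np.arange(a_best - 0.3, a_best + 0.3, fine_step),
        np.arange(b_best - 0.1, b_best + 0.1, 0.0001),
    )
    return a_best


class TestSlope:
    def test_exact_affine(self):
        e = np.linspace(0.1, 0.9, 50)
        assert slope(e, 2 * e + 1) == pytest.approx(2.0, abs=1e-12)

    def test_flat_force_is_zero(self):
        e = np.linspace(0.1, 0.9, 50)
        assert slope(e, np.full(50, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_constant_ear_raises(self):
        with pytest.raises(DegenerateInputError):
            slope(np.full(50, 0.5), np.linspace(0, 1, 50))

    def test_matches_polyfit(self, rng):
        for _ in range(20):
            e = rng.uniform(0.2, 0.8, RUN_LENGTH)
            f = -3.0 * e + 1.5 + rng.normal(0, 0.05, RUN_LENGTH)
            assert slope(e, f) == pytest.approx(
                np.polyfit(e, f, 1)[0], rel=1e-9
            )

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            e = rng.uniform(0.4, 0.6, RUN_LENGTH)
            a_true = rng.uniform(-20, 20)
            b_true = rng.uniform(-1, 1)
            f = a_true * e + b_true + rng.normal(0, 0.02, RUN_LENGTH)
            got = slope(e, f)
            assert abs(got - grid_search_slope(e, f)) <= 0.002 + 1e-9


class TestFoldMeanSlope:
    def test_identical_slopes(self):
        session = affine_session(a_s=-16.0)
        training = TrainingSet.from_session(session, 1)
        assert fold_mean_slope(training) == pytest.approx(-16.0, abs=1e-9)

    def test_mean_of_distinct_slopes(self):
        members = []
        e = np.linspace(0.1, 0.9, 50)
        for a in (1.0, 2.0, 3.0, 4.0, 5.0):
            members.append((e, a * e))
        training = TrainingSet(fold_index=1, members=tuple(members))
        assert fold_mean_slope(training) == pytest.approx(3.0, abs=1e-12)

    def test_recompute_and_average_oracle(self, session_a):
        training = TrainingSet.from_session(session_a, 3)
        expected = np.mean([slope(e, f) for e, f in training.members])
        assert fold_mean_slope(training) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_member_names_run(self):
        e = np.linspace(0.1, 0.9, 50)
        training = TrainingSet(
            fold_index=2,
            members=((e, 2 * e), (np.full(50, 0.5), e)),
            member_indices=(1, 3),
        )
        with pytest.raises(DegenerateInputError, match=r"fold 2.*run 3"):
            fold_mean_slope(training)

    def test_excludes_held_out_run(self, session_a):
        training = TrainingSet.from_session(session_a, 2)
        assert len(training.members) == session_a.K - 1
        assert 2 not in training.member_indices


class TestPredict:
    def test_constant_ear_gives_anchor(self):
        out = predict(np.full(10, 0.3), a_bar=-16.0, e0=0.3, f0=0.5)
        np.testing.assert_allclose(out, 0.5)

    def test_zero_slope_gives_anchor(self):
        out = predict(np.linspace(0, 1, 10), a_bar=0.0, e0=0.2, f0=0.4)
        np.testing.assert_allclose(out, 0.4)

    def test_direct_evaluation(self):
        out = predict(np.array([0.1, 0.2, 0.3]), a_bar=-10.0, e0=0.1, f0=0.5)
        np.testing.assert_allclose(out, [0.5, -0.5, -1.5])

    def test_empty_series_raises(self):
        with pytest.raises(DegenerateInputError):
            predict(np.array([]), 1.0, 0.0, 0.0)


class TestErrorMetrics:
    def test_rmse_identical_series(self, rng):
        f = rng.uniform(size=100)
        assert rmse(f, f) == 0.0

    def test_rmse_constant_offset(self, rng):
        f = rng.uniform(size=100)
        assert rmse(f, f + 0.125) == pytest.approx(0.125)

    def test_rmse_direct_formula(self, rng):
        f = rng.uniform(size=200)
        g = rng.uniform(size=200)
        assert rmse(f, g) == pytest.approx(
            np.sqrt(np.sum((f - g) ** 2) / 200), abs=1e-12
        )

    def test_rmse_length_mismatch(self):
        with pytest.raises(RangeError):
            rmse(np.zeros(5), np.zeros(6))

    def test_nrmse_zero_error(self):
        assert nrmse(0.0, 0.7, 0.1) == 0.0

    def test_nrmse_mean_of_ratios_differs_from_ratio_of_means(self):
        # per-fold ratio: deliberately not equal to the ratio of the
        # column averages used elsewhere in the report
        assert nrmse(0.0338, 0.6004, 0.0614) == pytest.approx(
            0.0338 / 0.5390, abs=1e-12
        )
        assert nrmse(0.0338, 0.6004, 0.0614) != pytest.approx(0.0659, abs=1e-4)

    def test_nrmse_scale_invariance(self):
        assert nrmse(0.04, 0.8, 0.2) == pytest.approx(
            nrmse(0.08, 1.4, 0.2), abs=1e-12
        )

    def test_nrmse_zero_width_raises(self):
        with pytest.raises(DegenerateInputError):
            nrmse(0.1, 0.5, 0.5)

    @pytest.mark.parametrize(
        "fmax, fmin, width",
        [(0.6004, 0.0614, 0.5390), (0.2584, 0.0544, 0.2040), (0.3, 0.3, 0.0)],
    )
    def test_estimated_width(self, fmax, fmin, width):
        assert estimated_width(fmax, fmin) == pytest.approx(width, abs=1e-12)

    def test_estimated_width_inverted_raises(self):
        with pytest.raises(RangeError):
            estimated_width(0.1, 0.2)


class TestCrossValidate:
    def test_noise_free_exact_recovery(self, ideal_session, ideal_params):
        ev = cross_validate(ideal_session)
        assert ev.a_bar_mean == pytest.approx(ideal_params.slope, abs=1e-9)
        for fr in ev.folds:
            assert fr.rmse_k == pytest.approx(0.0, abs=1e-9)
            assert fr.nrmse_k == pytest.approx(0.0, abs=1e-9)

    def test_anchor_identity(self, session_a):
        """f̃_k1 equals the held-out run's initial force value exactly."""
        ev = cross_validate(session_a)
        for fr, run in zip(ev.folds, session_a.runs):
            assert fr.f_tilde[0] == fr.f0 == run.force[0]

    def test_k2_boundary(self, ideal_params):
        session = generate_session(ideal_params, K=2)
        ev = cross_validate(session)
        assert len(ev.folds) == 2
        assert ev.a_bar_mean == pytest.approx(ideal_params.slope, abs=1e-9)

    def test_column_averages_independent(self, session_a):
        ev = cross_validate(session_a)
        assert ev.rmse_mean == pytest.approx(
            np.mean([fr.rmse_k for fr in ev.folds]), abs=1e-12
        )
        assert ev.nrmse_mean == pytest.approx(
            np.mean([fr.nrmse_k for fr in ev.folds]), abs=1e-12
        )
        # mean of per-fold ratios, not ratio of means
        assert ev.nrmse_mean != pytest.approx(
            ev.rmse_mean / ev.width_mean, abs=1e-9
        )
        assert ev.a_bar_sd == pytest.approx(
            np.std([fr.a_bar_k for fr in ev.folds], ddof=1), abs=1e-12
        )

    def test_affine_equivariance(self, session_a):
        """Scaling force by c scales slopes, RMSE and width by c and
        leaves NRMSE unchanged."""
        c = 0.5
        scaled = Session(
            subject_id="scaled",
            runs=[
                make_run(r.ear, c * r.force, r.emg, run_index=r.run_index)
                for r in session_a.runs
            ],
        )
        ev = cross_validate(session_a)
        ev_c = cross_validate(scaled)
        assert ev_c.a_bar_mean == pytest.approx(c * ev.a_bar_mean, rel=1e-9)
        assert ev_c.rmse_mean == pytest.approx(c * ev.rmse_mean, rel=1e-9)
        assert ev_c.width_mean == pytest.approx(c * ev.width_mean, rel=1e-9)
        assert ev_c.nrmse_mean == pytest.approx(ev.nrmse_mean, rel=1e-9)

    def test_ear_flip_antisymmetry(self, session_a):
        """ear' = 1 − ear negates every slope, leaves RMSE/NRMSE."""
        flipped = Session(
            subject_id="flip",
            runs=[
                make_run(1.0 - r.ear, r.force, r.emg, run_index=r.run_index)
                for r in session_a.runs
            ],
        )
        ev = cross_validate(session_a)
        ev_f = cross_validate(flipped)
        assert ev_f.a_bar_mean == pytest.approx(-ev.a_bar_mean, rel=1e-9)
        assert ev_f.rmse_mean == pytest.approx(ev.rmse_mean, rel=1e-9)
        assert ev_f.nrmse_mean == pytest.approx(ev.nrmse_mean, rel=1e-9)

    def test_degenerate_fold_aborts_with_identity(self):
        session = affine_session(a_s=-16.0, K=3)
        flat = make_run(
            np.full(RUN_LENGTH, 0.5), session.runs[0].force,
            session.runs[0].emg, run_index=2,
        )
        bad = Session(
            subject_id="S", runs=[session.runs[0], flat, session.runs[2]]
        )
        with pytest.raises(DegenerateInputError, match=r"subject S.*run 2"):
            cross_validate(bad)

    def test_force_noise_recovery_unbiased(self):
        """Force-channel noise leaves the recovered slope unbiased
        within Monte-Carlo error."""
        vals = []
        for seed in range(40):
            p = SubjectParams(
                slope=-16.1, noise_ear_sd=0.0, noise_emg_sd=0.0, seed=seed
            )
            vals.append(cross_validate(generate_session(p)).a_bar_mean)
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - (-16.1)) < max(4 * se, 0.02)

    def test_ear_noise_attenuates_slope(self):
        """Errors-in-variables: |recovered slope| shrinks monotonically
        as ear-channel noise grows (fixed seeds, 3 levels)."""
        means = []
        for sd in (0.0, 0.003, 0.01):
            vals = []
            for seed in range(15):
                p = SubjectParams(
                    slope=-16.1, noise_ear_sd=sd, noise_force_sd=0.0,
                    noise_emg_sd=0.0, seed=seed,
                )
                vals.append(
                    abs(cross_validate(generate_session(p)).a_bar_mean)
                )
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
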