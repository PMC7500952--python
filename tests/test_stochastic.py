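"""Stochastic single-cell simulation and cohort statistics."""

import numpy as np
import pytest

from ifngate import GatingModel, GatingPolicy, InputProgram, ModelParameters
from ifngate.stochastic import (
    CohortConfig,
    NoiseConfig,
    cohort_statistics,
    run_pretreatment_cohort,
    simulate_cell_sde,
)
from ifngate.model import integrate

P = ModelParameters(k1=2000, k2=5000, k3=1000, k4=100, k5=200, tau=8.0)


class TestSimulateCellSde:
    def test_zero_noise_reduces_to_deterministic(self):
        prog = InputProgram(((0, 24),))
        pol = GatingPolicy.fixed_delay(8.0)
        rng = np.random.default_rng(0)
        sde = simulate_cell_sde(
            P, prog, pol, NoiseConfig(0.0, 0.0), dt=0.01, t_end=30, rng=rng
        )
        det = integrate(P, prog, pol, t_end=30, dt=0.01)
        np.testing.assert_array_equal(sde.irf9, det.irf9)
        np.testing.assert_array_equal(sde.usp18, det.usp18)

    def test_same_seed_reproduces(self):
        prog = InputProgram(((0, 24),))
        pol = GatingPolicy.fixed_delay(8.0)
        a = simulate_cell_sde(
            P, prog, pol, NoiseConfig(), dt=0.01, t_end=30,
            rng=np.random.default_rng(42),
        )
        b = simulate_cell_sde(
            P, prog, pol, NoiseConfig(), dt=0.01, t_end=30,
            rng=np.random.default_rng(42),
        )
        np.testing.assert_array_equal(a.irf9, b.irf9)
        np.testing.assert_array_equal(a.usp18, b.usp18)

    def test_nonnegative_under_noise(self):
        prog = InputProgram()
        pol = GatingPolicy.always_on()
        traj = simulate_cell_sde(
            P, prog, pol, NoiseConfig(convention="euler_maruyama"),
            dt=0.01, t_end=24, rng=np.random.default_rng(1),
        )
        assert np.all(traj.irf9 >= 0)
        assert np.all(traj.usp18 >= 0)

    def test_noise_only_null_stays_near_zero(self):
        # without input the drift is zero; clamped noise keeps the state
        # within a few accumulated-noise scales of zero, far below any
        # induced signal
        noise = NoiseConfig()  # paper_euler: sigma * dt per step
        dt, t_end = 0.01, 24.0
        rng = np.random.default_rng(5)
        finals = [
            simulate_cell_sde(P, InputProgram(), GatingPolicy.always_on(),
                              noise, dt, t_end, rng).irf9[-1]
            for _ in range(100)
        ]
        walk_scale = noise.sigma_irf9 * np.sqrt(dt * t_end)
        assert 0 <= np.mean(finals) < 3 * walk_scale

    def test_convention_scales(self):
        n = NoiseConfig(sigma_irf9=100, sigma_usp18=10, convention="paper_euler")
        assert n.step_scales(0.01) == (1.0, 0.1)
        m = NoiseConfig(sigma_irf9=100, sigma_usp18=10, convention="euler_maruyama")
        assert m.step_scales(0.01) == (10.0, 1.0)


class TestPretreatmentCohort:
    def test_zero_noise_fully_open_window_gives_identical_cells(self):
        # with the window spanning the whole cycle every cell has zero
        # delay, so a zero-noise cohort is one deterministic trajectory
        cfg = CohortConfig(n_cells=20, seed=0, dt=0.01,
                           gating=GatingModel(21.82, 21.82))
        res = run_pretreatment_cohort(P, (2.0,), cfg, NoiseConfig(0.0, 0.0))
        assert len(res.records) == 20
        assert res.records["usp18_end_break"].nunique() == 1
        assert res.records["irf9_induction"].nunique() == 1

    def test_mean_usp18_monotone_in_pretreatment_duration(self):
        cfg = CohortConfig(n_cells=100, seed=3, dt=0.01)
        res = run_pretreatment_cohort(P, (2.0, 10.0, 24.0), cfg, NoiseConfig(0.0, 0.0))
        means = res.records.groupby("pre_duration_h")["usp18_end_break"].mean()
        assert means.loc[2.0] <= means.loc[10.0] <= means.loc[24.0]

    def test_desensitization_produces_negative_pooled_correlation(self):
        cfg = CohortConfig(n_cells=150, seed=9, dt=0.01)
        res = run_pretreatment_cohort(P, (2.0, 10.0, 24.0), cfg, NoiseConfig())
        stats = cohort_statistics(res)
        assert stats["pooled_correlation"] < 0

    def test_usp18_cv_decreases_with_pretreatment_duration(self):
        # short pretreatments induce USP18 only in the fraction of cells
        # caught inside the window (bimodal cohort, high CV); 24 h
        # saturates the gate for everyone
        cfg = CohortConfig(n_cells=150, seed=1, dt=0.01)
        res = run_pretreatment_cohort(P, (2.0, 10.0, 24.0), cfg, NoiseConfig())
        stats = cohort_statistics(res)
        cvs = [
            stats["conditions"][f"pre_{d:g}h"]["usp18"]["cv"] for d in (2, 10, 24)
        ]
        assert cvs[0] > cvs[1] > cvs[2]


class TestCohortStatistics:
    def test_cv_zero_for_identical_values(self):
        import pandas as pd

        from ifngate.stochastic import CohortResult

        df = pd.DataFrame(
            {
                "condition": ["a"] * 4,
                "pre_duration_h": [2.0] * 4,
                "usp18_end_break": [5.0] * 4,
                "irf9_induction": [1.0, 2.0, 3.0, 4.0],
            }
        )
        res = CohortResult(df, P, CohortConfig(n_cells=4), NoiseConfig())
        stats = cohort_statistics(res)
        assert stats["conditions"]["a"]["usp18"]["cv"] == 0.0

    def test_perfect_anticorrelation(self):
        import pandas as pd

        from ifngate.stochastic import CohortResult

        x = np.linspace(1, 10, 20)
        df = pd.DataFrame(
            {
                "condition": ["a"] * 20,
                "pre_duration_h": [2.0] * 20,
                "usp18_end_break": x,
                "irf9_induction": -2 * x + 30,
            }
        )
        res = CohortResult(df, P, CohortConfig(n_cells=20), NoiseConfig())
        assert cohort_statistics(res)["pooled_correlation"] == pytest.approx(-1.0)

    def test_zero_mean_cv_flagged(self):
        import pandas as pd

        from ifngate.stochastic import CohortResult

        df = pd.DataFrame(
            {
                "condition": ["a"] * 3,
                "pre_duration_h": [2.0] * 3,
                "usp18_end_break": [0.0, 0.0, 0.0],
                "irf9_induction": [1.0, 2.0, 3.0],
            }
        )
        res = CohortResult(df, P, CohortConfig(n_cells=3), NoiseConfig())
        entry = cohort_statistics(res)["conditions"]["a"]["usp18"]
        assert entry["cv"] is None
        assert entry["cv_defined"] is False
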