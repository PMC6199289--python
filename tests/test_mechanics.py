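"""Steady-state extraction, Hill fitting and viscoelastic decomposition."""

import numpy as np
import pytest

from sarcomech.datatypes import ForceTrace, StepAnnotation
from sarcomech.mechanics import (
    PCaStep,
    analyze_stretch_step,
    compute_specific_force,
    extract_steady_state,
    fit_hill,
    force_per_diameter,
    summarize_rupture,
)
from sarcomech.phantom import TraceSpec, generate_force_trace, hill_force


def flat_trace(value: float, duration: float = 30.0, rate: float = 100.0, spikes=()):
    t = np.arange(int(duration * rate)) / rate
    f = np.full_like(t, value)
    for t0 in spikes:
        half = 0.1
        f += 500.0 * np.clip(1 - np.abs(t - t0 - half) / half, 0, None)
    ann = [StepAnnotation("pca", 6.0, 0.0, duration)]
    return ForceTrace(t, f, annotations=ann)


class TestSteadyState:
    def test_plateau_recovered_despite_spikes(self):
        tr = flat_trace(100.0, spikes=(3.0, 8.0, 12.0))
        s = extract_steady_state(tr, tr.annotations[0])
        assert s.steady_force_un == pytest.approx(100.0)
        assert s.steady

    def test_noiseless_constant_is_exact(self):
        tr = flat_trace(42.0)
        s = extract_steady_state(tr, tr.annotations[0])
        assert s.steady_force_un == 42.0

    def test_monotone_ramp_flagged_non_steady(self):
        t = np.arange(3000) / 100.0
        f = 10.0 + 5.0 * t  # never settles
        tr = ForceTrace(t, f, annotations=[StepAnnotation("pca", 6.0, 0.0, 30.0)])
        s = extract_steady_state(tr, tr.annotations[0])
        assert not s.steady

    def test_short_window_rejected(self):
        t = np.arange(500) / 100.0
        tr = ForceTrace(t, np.ones_like(t), annotations=[StepAnnotation("pca", 6.0, 0.0, 5.0)])
        with pytest.raises(ValueError, match="10 s"):
            extract_steady_state(tr, tr.annotations[0])

    def test_full_staircase_extraction(self, pca_trace):
        steps = [extract_steady_state(pca_trace, a) for a in pca_trace.annotations]
        for a, s in zip(pca_trace.annotations, steps):
            expected = float(hill_force(a.value, 300.0, 6.0, 4.0))
            assert s.steady_force_un == pytest.approx(expected, abs=0.05)


class TestHillFit:
    def test_exact_data_recovery(self):
        pcas = np.array([9.0, 7.0, 6.5, 6.0, 5.5, 4.92])
        steps = [
            PCaStep(p, float(hill_force(p, 300.0, 6.0, 4.0)), 100) for p in pcas
        ]
        h = fit_hill(steps)
        assert h.pca50 == pytest.approx(6.0, rel=1e-6)
        assert h.hill_slope == pytest.approx(4.0, rel=1e-6)
        assert h.fmax_fit_un == pytest.approx(300.0, rel=1e-6)

    def test_noisy_recovery_statistics(self):
        """2% multiplicative noise: |bias| < 0.01 and RMSE < 0.05 over 100 seeds."""
        pcas = np.array([9.0, 7.0, 6.5, 6.0, 5.5, 4.92])
        clean = hill_force(pcas, 300.0, 6.0, 4.0)
        est = []
        for seed in range(100):
            rng = np.random.default_rng(3000 + seed)
            noisy = clean * (1.0 + 0.02 * rng.standard_normal(len(pcas)))
            steps = [PCaStep(p, float(v), 100) for p, v in zip(pcas, noisy)]
            est.append(fit_hill(steps).pca50)
        est = np.asarray(est)
        assert abs(est.mean() - 6.0) < 0.01
        assert np.sqrt(np.mean((est - 6.0) ** 2)) < 0.05

    def test_saturating_level_supplies_maximum(self):
        """The pCa 4.92 plateau carries the maximal (normalising) force."""
        pcas = np.array([9.0, 7.0, 6.5, 6.0, 5.5, 4.92])
        steps = [PCaStep(p, float(hill_force(p, 300.0, 6.0, 4.0)), 100) for p in pcas]
        h = fit_hill(steps)
        assert float(h.normalized(4.92)) > 0.99
        assert max(s.steady_force_un for s in steps) == steps[-1].steady_force_un

    def test_fitted_curve_monotone_decreasing_in_pca(self):
        pcas = np.array([9.0, 7.0, 6.5, 6.0, 5.5, 4.92])
        steps = [PCaStep(p, float(hill_force(p, 200.0, 5.8, 2.5)), 100) for p in pcas]
        h = fit_hill(steps)
        grid = h.predict(np.linspace(4.5, 9.5, 200))
        assert np.all(np.diff(grid) <= 0)

    def test_insufficient_levels_rejected(self):
        steps = [PCaStep(p, 10.0 * i + 1, 10) for i, p in enumerate([9.0, 6.0, 5.0])]
        with pytest.raises(ValueError, match="4 distinct"):
            fit_hill(steps)


class TestForceNormalisation:
    def test_specific_force_worked_example(self):
        """126 uN over a 40 um circular CSA is about 10 N/cm^2."""
        csa = np.pi * 20.0**2
        assert compute_specific_force(126.0, csa) == pytest.approx(10.03, abs=0.01)

    def test_zero_force(self):
        assert compute_specific_force(0.0, 100.0) == 0.0

    def test_halving_with_doubled_csa(self):
        assert compute_specific_force(50.0, 200.0) == compute_specific_force(50.0, 100.0) / 2

    def test_zero_csa_rejected(self):
        with pytest.raises(ValueError):
            compute_specific_force(10.0, 0.0)

    def test_force_per_diameter(self):
        assert force_per_diameter(120.0, 40.0) == pytest.approx(3.0)


class TestStretchStep:
    def test_exact_double_exponential_recovery(self, stretch_trace):
        r = analyze_stretch_step(
            stretch_trace, stretch_trace.annotations[0],
            csa_um2=1256.64, initial_length_um=2000.0,
        )
        assert r.fmax_un == pytest.approx(350.0, rel=1e-6)
        assert r.feq_un == pytest.approx(200.0, rel=0.01)
        assert r.a1_un == pytest.approx(100.0, rel=0.01)
        assert r.a2_un == pytest.approx(50.0, rel=0.01)
        assert r.tau1_s == pytest.approx(0.5, rel=0.01)
        assert r.tau2_s == pytest.approx(5.0, rel=0.01)
        assert r.delta_f_over_fmax == pytest.approx(3 / 7, rel=0.01)
        assert r.double_exponential
        assert r.tau1_s < r.tau2_s
        assert r.strain == pytest.approx(50.0 / 2000.0)
        assert r.stress_max_kpa == pytest.approx(350.0 / 1256.64 * 1000.0, rel=1e-6)

    def test_constant_window_falls_back_to_single(self):
        t = np.arange(2000) / 20.0
        tr = ForceTrace(t, np.full_like(t, 80.0),
                        annotations=[StepAnnotation("stretch", 50.0, 0.0, 100.0)])
        r = analyze_stretch_step(tr, tr.annotations[0])
        assert not r.double_exponential
        assert r.delta_f_over_fmax == pytest.approx(0.0, abs=1e-9)
        assert abs(r.a1_un) < 1.0

    def test_dff_invariant_to_rescaling(self, stretch_trace):
        r1 = analyze_stretch_step(stretch_trace, stretch_trace.annotations[0])
        scaled = ForceTrace(
            stretch_trace.time_s, stretch_trace.force_un * 13.0,
            position_um=stretch_trace.position_um,
            annotations=stretch_trace.annotations,
        )
        r2 = analyze_stretch_step(scaled, scaled.annotations[0], csa_um2=999.0)
        assert r2.delta_f_over_fmax == pytest.approx(r1.delta_f_over_fmax, rel=1e-6)

    def test_noisy_feq_bias_and_dff_rmse(self):
        """sigma = 2 uN over 50 seeds: F_eq bias < 1%, dF/F_max RMSE < 0.02."""
        feqs, dffs = [], []
        for seed in range(50):
            spec = TraceSpec(
                kind="stretch_series", step_sizes_um=[50.0], feq_per_step_un=[200.0],
                a1_un=100.0, a2_un=50.0, tau1_s=0.5, tau2_s=5.0,
                noise_sigma_un=2.0, step_duration_s=60.0, seed=seed,
            )
            tr = generate_force_trace(spec)
            r = analyze_stretch_step(tr, tr.annotations[0])
            feqs.append(r.feq_un)
            dffs.append(r.delta_f_over_fmax)
        assert abs(np.mean(feqs) - 200.0) / 200.0 < 0.01
        assert np.sqrt(np.mean((np.array(dffs) - 3 / 7) ** 2)) < 0.02


class TestRupture:
    @staticmethod
    def staircase_with_collapse(n_steps: int, collapse_after: int | None):
        rate, dur = 50.0, 20.0
        t = np.arange(int(n_steps * dur * rate)) / rate
        f = np.zeros_like(t)
        pos = np.zeros_like(t)
        for i in range(n_steps):
            sel = (t >= i * dur) & (t < (i + 1) * dur)
            f[sel] = 50.0 * (i + 1)
            pos[sel] = 50.0 * (i + 1)
        if collapse_after is not None:
            f[t >= collapse_after * dur - 0.02] = 1.0
        ann = [StepAnnotation("stretch", 50.0, i * dur, (i + 1) * dur) for i in range(n_steps)]
        return ForceTrace(t, f, position_um=pos, annotations=ann)

    def test_collapse_after_sixth_step(self):
        tr = self.staircase_with_collapse(8, collapse_after=6)
        s = summarize_rupture(tr, csa_um2=1000.0, initial_length_um=2000.0)
        assert s.ruptured
        assert s.rupture_strain == pytest.approx(6 * 50.0 / 2000.0)
        assert s.rupture_stress_kpa == pytest.approx(300.0 / 1000.0 * 1000.0, rel=0.01)

    def test_unruptured_trace_is_censored(self):
        tr = self.staircase_with_collapse(4, collapse_after=None)
        assert not summarize_rupture(tr).ruptured

    def test_collapse_at_first_step(self):
        tr = self.staircase_with_collapse(4, collapse_after=1)
        s = summarize_rupture(tr, csa_um2=1000.0, initial_length_um=2000.0)
        assert s.ruptured
        assert s.rupture_strain == pytest.approx(50.0 / 2000.0)
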