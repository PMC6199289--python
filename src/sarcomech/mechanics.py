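"""Single-fiber mechanics from annotated force traces.

Active mechanics: each pCa step of a staircase recording is reduced to a
steady-state force (solution-exchange spikes removed with a robust rolling-
median gate, plateau taken from the quiet tail of the window), and the
per-step forces are fitted with the sigmoidal Hill relation

    F(pCa) = F_max / (1 + 10^(h * (pCa - pCa50)))

whose midpoint pCa50 is the Ca2+ sensitivity of the contractile apparatus
and whose slope h describes the cooperativity of activation.  Forces are
normalised to cross-sectional area (specific force, N/cm^2) or to fiber
diameter (uN/um).

Passive mechanics: each step stretch shows an instantaneous rise to the
peak restoration force F_max followed by a viscoelastic decay

    F(t) = F_eq + A1*exp(-t/tau1) + A2*exp(-t/tau2)

to the steady-state elastic level F_eq.  The viscous stress-relief ratio
dF/F_max = (F_max - F_eq)/F_max, the two relaxation times, stresses
(force/CSA) and strains (actuator position / initial length) are reported
per step, and a rupture event, when present, is summarised by the last
pre-collapse stress and strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import ForceTrace, StepAnnotation

__all__ = [
    "PCaStep",
    "HillFitResult",
    "StretchStepResult",
    "RuptureSummary",
    "extract_steady_state",
    "fit_hill",
    "compute_specific_force",
    "force_per_diameter",
    "analyze_stretch_step",
    "summarize_rupture",
]

# 1 uN/um^2 = 1 MPa, i.e. 100 N/cm^2 or 1000 kPa
_UN_PER_UM2_TO_N_PER_CM2 = 100.0
_UN_PER_UM2_TO_KPA = 1000.0


@dataclass
class PCaStep:
    """Steady-state force at one Ca2+ activation level."""

    pca: float
    steady_force_un: float
    n_samples_used: int
    steady: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.steady_force_un):
            raise ValueError("steady-state force must be finite")
        if not 4.0 <= self.pca <= 10.0:
            raise ValueError("pCa outside the physiological range [4, 10]")


@dataclass
class HillFitResult:
    """Parameters of the sigmoidal pCa-force fit."""

    pca50: float
    hill_slope: float
    fmax_fit_un: float
    residual_rms: float
    covariance: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        if self.hill_slope <= 0:
            raise ValueError("Hill slope must be positive")

    def predict(self, pca: np.ndarray | float) -> np.ndarray:
        from .phantom import hill_force

        return hill_force(pca, self.fmax_fit_un, self.pca50, self.hill_slope)

    def normalized(self, pca: np.ndarray | float) -> np.ndarray:
        """Force normalised to the fitted maximum, F/F_max."""
        return self.predict(pca) / self.fmax_fit_un

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.covariance))
        lines = [
            "Hill pCa-force fit",
            "------------------",
            f"pCa50          {self.pca50:8.3f} +/- {se[1]:.3f}",
            f"Hill slope h   {self.hill_slope:8.3f} +/- {se[2]:.3f}",
            f"F_max (uN)     {self.fmax_fit_un:8.2f} +/- {se[0]:.2f}",
            f"residual RMS   {self.residual_rms:8.3g}",
            f"n levels       {self.n_points:8d}",
        ]
        return "\n".join(lines)


@dataclass
class StretchStepResult:
    """Viscoelastic decomposition of one step stretch."""

    step_um: float
    fmax_un: float
    feq_un: float
    a1_un: float
    a2_un: float
    tau1_s: float
    tau2_s: float
    delta_f_over_fmax: float
    stress_max_kpa: Optional[float] = None
    stress_eq_kpa: Optional[float] = None
    strain: Optional[float] = None
    double_exponential: bool = True
    decaying: bool = True

    def summary(self) -> str:
        model = "double" if self.double_exponential else "single"
        lines = [
            f"Stretch step ({self.step_um:g} um, {model}-exponential fit)",
            "---------------------------------------------",
            f"F_max (uN)       {self.fmax_un:10.2f}",
            f"F_eq (uN)        {self.feq_un:10.2f}",
            f"dF/F_max         {self.delta_f_over_fmax:10.4f}",
            f"A1, A2 (uN)      {self.a1_un:10.2f} {self.a2_un:10.2f}",
            f"tau1, tau2 (s)   {self.tau1_s:10.3f} {self.tau2_s:10.3f}",
        ]
        if self.stress_max_kpa is not None:
            lines.append(f"stress max/eq (kPa) {self.stress_max_kpa:7.2f} {self.stress_eq_kpa:7.2f}")
        if self.strain is not None:
            lines.append(f"strain            {self.strain:10.4f}")
        return "\n".join(lines)


@dataclass
class RuptureSummary:
    """Stress and strain at fiber rupture; ``ruptured=False`` marks censoring."""

    ruptured: bool
    rupture_stress_kpa: Optional[float] = None
    rupture_strain: Optional[float] = None


# --------------------------------------------------------------------------
# active mechanics
# --------------------------------------------------------------------------

def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    import pandas as pd

    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def extract_steady_state(
    trace: ForceTrace,
    step: StepAnnotation,
    spike_gate_sigmas: float = 5.0,
    quiet_fraction: float = 0.20,
    drift_tolerance: float = 0.01,
    min_quiet_samples: int = 50,
) -> PCaStep:
    """Steady-state force of one pCa step, with exchange spikes removed.

    Samples more than ``spike_gate_sigmas`` robust sigmas above the rolling
    median are treated as solution-exchange artifacts and discarded; the
    steady-state force is the median of the last ``quiet_fraction`` of the
    remaining window.  A linear drift check over that tail (threshold
    ``drift_tolerance`` of the steady force per 10 s) flags steps that
    never settled.
    """
    t, f = trace.window(step.start_s, step.end_s)
    if len(t) < 2 or (t[-1] - t[0]) < 10.0:
        raise ValueError("step window must span at least 10 s")
    dt = np.median(np.diff(t))
    win = max(3, int(round(1.0 / dt)))
    base = _rolling_median(f, win)
    resid = f - base
    sigma = np.median(np.abs(resid - np.median(resid))) / 0.6745
    if sigma > 0:
        quiet = resid <= spike_gate_sigmas * sigma
    else:
        quiet = np.ones_like(f, dtype=bool)
    tq, fq = t[quiet], f[quiet]
    if len(fq) < min_quiet_samples:
        raise ValueError("fewer than 50 quiet samples in step window")
    n_tail = max(min_quiet_samples, int(round(quiet_fraction * len(fq))))
    tt, ft = tq[-n_tail:], fq[-n_tail:]
    steady = float(np.median(ft))
    slope = float(np.polyfit(tt, ft, 1)[0]) if len(tt) > 2 else 0.0
    steady_ok = abs(slope) * 10.0 <= drift_tolerance * max(abs(steady), 1e-12)
    return PCaStep(
        pca=step.value,
        steady_force_un=steady,
        n_samples_used=int(n_tail),
        steady=steady_ok,
    )


def fit_hill(steps: list[PCaStep]) -> HillFitResult:
    """Least-squares Hill fit of steady-state force versus pCa.

    Requires >= 4 distinct pCa levels spanning >= 1.5 units.  The fit is
    multi-started over Hill slopes {1, 2, 4, 8} and the best residual is
    kept.
    """
    from .phantom import hill_force

    pca = np.array([s.pca for s in steps], dtype=float)
    force = np.array([s.steady_force_un for s in steps], dtype=float)
    if len(np.unique(pca)) < 4:
        raise ValueError("need at least 4 distinct pCa levels")
    if np.ptp(pca) < 1.5:
        raise ValueError("pCa levels must span at least 1.5 units")

    def model(p, fmax, pca50, h):
        return hill_force(p, fmax, pca50, h)

    import warnings

    from scipy.optimize import OptimizeWarning

    best = None
    mid0 = float(np.median(pca))
    for h0 in (1.0, 2.0, 4.0, 8.0):
        try:
            with warnings.catch_warnings():
                # singular covariance from a bad start is expected; the
                # multistart keeps the best-residual fit anyway
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(
                    model,
                    pca,
                    force,
                    p0=(force.max(), mid0, h0),
                    maxfev=20000,
                )
        except RuntimeError:
            continue
        if popt[2] <= 0:
            continue
        rss = float(np.sum((model(pca, *popt) - force) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise RuntimeError(
            "Hill fit failed from all starts; check steady-state forces"
        )
    rss, popt, pcov = best
    return HillFitResult(
        pca50=float(popt[1]),
        hill_slope=float(popt[2]),
        fmax_fit_un=float(popt[0]),
        residual_rms=float(np.sqrt(rss / len(pca))),
        covariance=pcov,
        n_points=len(pca),
    )


def compute_specific_force(force_un: float, csa_um2: float) -> float:
    """Specific force in N/cm^2 from force (uN) and CSA (um^2).

    1 uN/um^2 = 1e-6 N / 1e-8 cm^2 = 100 N/cm^2.
    """
    if csa_um2 <= 0:
        raise ValueError("CSA must be positive")
    return force_un / csa_um2 * _UN_PER_UM2_TO_N_PER_CM2


def force_per_diameter(force_un: float, diameter_um: float) -> float:
    """Maximum force normalised to fiber diameter (uN/um)."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return force_un / diameter_um


# --------------------------------------------------------------------------
# passive mechanics
# --------------------------------------------------------------------------

def _double_exp(t, feq, a1, a2, tau1, tau2):
    return feq + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _single_exp(t, feq, a, tau):
    return feq + a * np.exp(-t / tau)


def analyze_stretch_step(
    trace: ForceTrace,
    step: StepAnnotation,
    csa_um2: Optional[float] = None,
    initial_length_um: Optional[float] = None,
    min_hold_s: float = 10.0,
    selection_margin: float = 0.05,
) -> StretchStepResult:
    """Decompose one step stretch into F_max, F_eq and the relaxation terms.

    F_max is the maximum force in the window (min-max analysis); the decay
    from the peak onwards is fitted with the double-exponential model, or
    with a single exponential when the second term does not improve the
    residual by at least ``selection_margin`` (relative).  A window whose
    fitted F_eq is not below F_max is flagged non-decaying but still
    reported.
    """
    t, f = trace.window(step.start_s, step.end_s)
    if len(t) < 10 or (t[-1] - t[0]) < min_hold_s:
        raise ValueError(f"step window must span at least {min_hold_s} s of hold")
    i_max = int(np.argmax(f))
    fmax = float(f[i_max])
    td = t[i_max:] - t[i_max]
    fd = f[i_max:]
    if len(td) < 6:
        raise ValueError("too few samples after the force peak")
    feq0 = float(np.median(fd[-max(5, len(fd) // 10):]))
    amp0 = max(fmax - feq0, 1e-12)
    span = max(td[-1], 1e-6)

    def try_fit(func, p0, bounds):
        try:
            popt, _ = curve_fit(func, td, fd, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            return None
        rss = float(np.sum((func(td, *popt) - fd) ** 2))
        return rss, popt

    single = try_fit(
        _single_exp,
        (feq0, amp0, span / 5),
        ([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
    )
    double = try_fit(
        _double_exp,
        (feq0, 0.6 * amp0, 0.4 * amp0, span / 20, span / 3),
        ([-np.inf, 0.0, 0.0, 1e-9, 1e-9], [np.inf, np.inf, np.inf, np.inf, np.inf]),
    )

    use_double = False
    if double is not None and single is not None:
        use_double = double[0] < (1.0 - selection_margin) * single[0]
    elif double is not None:
        use_double = True
    if use_double:
        feq, a1, a2, tau1, tau2 = (float(v) for v in double[1])
        if tau1 > tau2:  # identifiability convention
            tau1, tau2, a1, a2 = tau2, tau1, a2, a1
    elif single is not None:
        feq, a, tau = (float(v) for v in single[1])
        a1, a2, tau1, tau2 = a, 0.0, tau, tau
    else:
        raise RuntimeError("exponential relaxation fit failed")

    decaying = feq < fmax
    dff = (fmax - feq) / fmax if fmax > 0 else 0.0
    dff = float(np.clip(dff, 0.0, None))

    stress_max = stress_eq = strain = None
    if csa_um2 is not None:
        stress_max = fmax / csa_um2 * _UN_PER_UM2_TO_KPA
        stress_eq = feq / csa_um2 * _UN_PER_UM2_TO_KPA
    if initial_length_um is not None and trace.position_um is not None:
        sel = (trace.time_s >= step.start_s) & (trace.time_s < step.end_s)
        strain = float(trace.position_um[sel][-1] / initial_length_um)
    return StretchStepResult(
        step_um=step.value,
        fmax_un=fmax,
        feq_un=feq,
        a1_un=a1,
        a2_un=a2,
        tau1_s=tau1,
        tau2_s=tau2,
        delta_f_over_fmax=dff,
        stress_max_kpa=stress_max,
        stress_eq_kpa=stress_eq,
        strain=strain,
        double_exponential=use_double,
        decaying=decaying,
    )


def summarize_rupture(
    trace: ForceTrace,
    csa_um2: Optional[float] = None,
    initial_length_um: Optional[float] = None,
    drop_fraction: float = 0.80,
    drop_window_s: float = 1.0,
) -> RuptureSummary:
    """Detect a terminal force collapse and report the pre-rupture state.

    A rupture is a drop of more than ``drop_fraction`` of the local force
    level within ``drop_window_s``.  Traces without a collapse return a
    censored summary.
    """
    t, f = trace.time_s, trace.force_un
    dt = np.median(np.diff(t))
    k = max(1, int(round(drop_window_s / dt)))
    peak = float(np.max(np.abs(f)))
    if peak <= 0:
        return RuptureSummary(ruptured=False)
    idx = None
    for i in range(len(f) - k):
        if f[i] > 0.05 * peak and (f[i] - f[i + k]) > drop_fraction * f[i]:
            idx = i
            break
    if idx is None:
        return RuptureSummary(ruptured=False)
    stress = f[idx] / csa_um2 * _UN_PER_UM2_TO_KPA if csa_um2 else None
    strain = None
    if initial_length_um and trace.position_um is not None:
        strain = float(trace.position_um[idx] / initial_length_um)
    return RuptureSummary(
        ruptured=True, rupture_stress_kpa=stress, rupture_strain=strain
    )
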