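"""Synthetic SHG fiber phantoms and force traces with exact ground truth.

The phantom model renders a single striated fiber as a modulated cosine
grating inside the chord envelope of a circular cross-section:

    I(x, y, z) = envelope(v, z) * [1 + m * cos(psi(x, y))] + noise

where ``v`` is the in-plane coordinate perpendicular to the fiber axis and
``psi`` is a phase field whose gradient follows a smooth, Gaussian-correlated
field of local striation-normal directions.  Myofibrillar disorder is
controlled by the angular dispersion of that field; verniers (out-of-register
Y-defects) are inserted as edge dislocations of the grating, i.e. phase
singularities with +-2*pi winding, each of which terminates one fringe.

Because the phase field is obtained by a least-squares integration of the
target normal directions, the *rendered* local orientation can differ
slightly from the nominal random field.  Ground truth therefore reports the
empirical statistics of the rendered field (mean cosine of the deviation
angles over the fiber region), so that recovery tests compare like with
like.

Force traces follow the two experimental designs: staircases of pCa steps
whose plateaus obey the Hill relation (with brief positive solution-exchange
spikes superimposed), and step-stretch series with an instantaneous rise
followed by a double-exponential viscoelastic decay to a plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .datatypes import ForceTrace, ImageStack, StepAnnotation

__all__ = [
    "FiberPhantomSpec",
    "GroundTruth",
    "TraceSpec",
    "generate_fiber_stack",
    "generate_force_trace",
    "compute_pixel_energy",
]


# --------------------------------------------------------------------------
# specs and ground truth
# --------------------------------------------------------------------------

@dataclass
class FiberPhantomSpec:
    """Parameters of a striated-fiber phantom.

    Defaults emulate a relaxed fast-twitch fiber imaged at high NA:
    2.5 um sarcomeres, ~45 um diameter, 0.25 um pixels.
    """

    sarcomere_length_um: float = 2.5
    fiber_diameter_um: float = 45.0
    modulation_depth: float = 0.5
    orientation_dispersion_deg: float = 5.0
    n_dislocations: int = 0
    field_size_um: tuple[float, float] = (100.0, 100.0)
    pixel_size_um: float = 0.25
    z_step_um: float = 2.0
    n_slices: int = 1
    main_axis_deg: float = 0.0
    photon_scale: float = 0.0
    read_sigma: float = 0.0
    angle_correlation_um: float = 10.0
    base_intensity: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if not 1.5 <= self.sarcomere_length_um <= 4.5:
            raise ValueError("sarcomere length must lie in [1.5, 4.5] um")
        if self.pixel_size_um >= self.sarcomere_length_um / 4:
            raise ValueError(
                "pixel size violates the striation Nyquist margin "
                f"({self.pixel_size_um} um >= SL/4 = {self.sarcomere_length_um / 4} um)"
            )
        if self.pixel_size_um <= 0 or min(self.field_size_um) <= 0:
            raise ValueError("field and pixel sizes must be positive")
        if not 0 < self.modulation_depth <= 1:
            raise ValueError("modulation depth must be in (0, 1]")
        if self.n_dislocations < 0:
            raise ValueError("dislocation count must be >= 0")
        if self.orientation_dispersion_deg < 0:
            raise ValueError("dispersion must be >= 0")
        if self.fiber_diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.photon_scale < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_slices < 1 or self.z_step_um <= 0:
            raise ValueError("need >= 1 slice with positive z step")


@dataclass
class GroundTruth:
    """Exact generator bookkeeping attached to each phantom."""

    true_sl_um: float
    true_diameter_um: float
    true_cas: float
    true_vd_per_100um2: float
    dislocation_coords: list[tuple[float, float, float]]
    true_main_axis_deg: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.true_cas <= 1.0:
            raise ValueError("true_cas must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "true_sl_um": self.true_sl_um,
            "true_diameter_um": self.true_diameter_um,
            "true_cas": self.true_cas,
            "true_vd_per_100um2": self.true_vd_per_100um2,
            "dislocation_coords": [list(c) for c in self.dislocation_coords],
            "true_main_axis_deg": self.true_main_axis_deg,
        }


@dataclass
class TraceSpec:
    """Parameters of a synthetic force recording.

    ``kind`` selects the experimental design: ``"pca_series"`` renders a
    staircase of Ca2+ activation steps, ``"stretch_series"`` a sequence of
    step stretches with viscoelastic relaxation.
    """

    kind: str = "pca_series"
    # pCa staircase
    pca_levels: Sequence[float] = (9.0, 7.0, 6.5, 6.0, 5.5, 4.92)
    hill_pca50: float = 6.0
    hill_slope: float = 4.0
    fmax_force_un: float = 300.0
    spike_amplitude_un: float = 400.0
    spikes_per_step: int = 2
    # stretch staircase
    step_sizes_um: Sequence[float] = (50.0, 50.0, 50.0, 50.0)
    feq_per_step_un: Sequence[float] = (100.0, 200.0, 320.0, 460.0)
    a1_un: float = 100.0
    a2_un: float = 50.0
    tau1_s: float = 0.5
    tau2_s: float = 5.0
    # common
    step_duration_s: float = 60.0
    sampling_rate_hz: float = 100.0
    noise_sigma_un: float = 0.0
    initial_length_um: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("pca_series", "stretch_series"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.kind == "pca_series":
            lv = np.asarray(self.pca_levels, dtype=float)
            if lv.size < 2 or np.any(np.diff(lv) >= 0):
                raise ValueError("pCa levels must be strictly decreasing")
        else:
            if len(self.step_sizes_um) != len(self.feq_per_step_un):
                raise ValueError("need one F_eq per stretch step")
            if self.tau1_s <= 0 or self.tau2_s <= 0:
                raise ValueError("time constants must be positive")
            if self.tau1_s == self.tau2_s:
                raise ValueError("tau1 and tau2 must differ")
        if self.sampling_rate_hz <= 0 or self.step_duration_s <= 0:
            raise ValueError("sampling rate and step duration must be positive")
        if self.noise_sigma_un < 0:
            raise ValueError("noise sigma must be >= 0")


# --------------------------------------------------------------------------
# phase-field machinery
# --------------------------------------------------------------------------

def _correlated_angle_field(
    shape: tuple[int, int],
    dispersion_deg: float,
    correlation_um: float,
    pixel_size_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth Gaussian random field of angle deviations (radians).

    White noise is low-pass filtered with a Gaussian kernel whose sigma is
    the requested correlation length, then rescaled so the empirical
    standard deviation equals the requested marginal dispersion.
    """
    if dispersion_deg == 0:
        return np.zeros(shape)
    sigma_px = correlation_um / pixel_size_um
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma_px, mode="wrap")
    smooth -= smooth.mean()  # deviations are defined about the nominal axis
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth * (np.deg2rad(dispersion_deg) / sd)


def _integrate_phase(
    px: np.ndarray, py: np.ndarray, h: float
) -> np.ndarray:
    """Least-squares integration of a target gradient field (DCT Poisson solve).

    Finds psi minimising ||grad(psi) - (px, py)||^2.  The mean (planar)
    gradient component lies in the null space of the Neumann Laplacian, so
    it is split off and re-added analytically; the fluctuating part is
    solved with the discrete cosine transform.
    """
    ny_, nx_ = px.shape
    mx, my = px.mean(), py.mean()
    px = px - mx
    py = py - my
    gy, gx = np.gradient(py, h, axis=0), np.gradient(px, h, axis=1)
    div = gx + gy
    ny, nx = div.shape
    d = sp_fft.dctn(div, type=2, norm="ortho")
    iy = np.arange(ny)[:, None]
    ix = np.arange(nx)[None, :]
    denom = (2 * np.cos(np.pi * iy / ny) - 2 + 2 * np.cos(np.pi * ix / nx) - 2) / h**2
    denom[0, 0] = 1.0
    d /= denom
    d[0, 0] = 0.0
    fluct = sp_fft.idctn(d, type=2, norm="ortho")
    xs = (np.arange(nx_) + 0.5) * h
    ys = (np.arange(ny_) + 0.5) * h
    return fluct + mx * xs[None, :] + my * ys[:, None]


def _place_dislocations(
    spec: FiberPhantomSpec, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Draw in-plane dislocation sites inside the fiber core.

    Sites are kept a few sarcomere lengths apart and away from the fiber
    edge so each renders as a clean, isolated Y-defect.  Raises if the
    requested count exceeds what the core region can hold.
    """
    n = spec.n_dislocations
    if n == 0:
        return []
    wx, wy = spec.field_size_um
    radius = spec.fiber_diameter_um / 2
    # usable band perpendicular to the axis: central 70% of the chord
    half_band = 0.35 * spec.fiber_diameter_um
    margin_x = 3 * spec.sarcomere_length_um
    min_sep = 4 * spec.sarcomere_length_um
    usable_area = (wx - 2 * margin_x) * 2 * half_band
    if usable_area <= 0 or n * min_sep**2 > usable_area:
        raise ValueError(
            f"{n} dislocations exceed the geometric capacity of the fiber core"
        )
    cy = wy / 2
    pts: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(pts) == n:
            break
        x = rng.uniform(margin_x, wx - margin_x)
        y = rng.uniform(cy - half_band, cy + half_band)
        if all((x - qx) ** 2 + (y - qy) ** 2 >= min_sep**2 for qx, qy in pts):
            pts.append((x, y))
    if len(pts) < n:
        raise ValueError(
            f"could not place {n} dislocations with {min_sep:.1f} um separation"
        )
    return pts


def generate_fiber_stack(spec: FiberPhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a striated-fiber phantom and its exact ground truth.

    Returns the image stack and a :class:`GroundTruth` whose ``true_cas``
    is the empirical mean cosine of the rendered striation-normal
    deviations over the fiber region, and whose vernier density refers to
    the full frame area (dislocation lines run through all slices).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    wx, wy = spec.field_size_um
    nx = int(round(wx / spec.pixel_size_um))
    ny = int(round(wy / spec.pixel_size_um))
    h = spec.pixel_size_um
    k = 2 * np.pi / spec.sarcomere_length_um
    theta0 = np.deg2rad(spec.main_axis_deg)

    # smooth local deviation of the striation normal from the main axis
    alpha = _correlated_angle_field(
        (ny, nx),
        spec.orientation_dispersion_deg,
        spec.angle_correlation_um,
        h,
        rng,
    )
    if spec.orientation_dispersion_deg == 0:
        xs = (np.arange(nx) + 0.5) * h
        psi = np.broadcast_to(k * (np.cos(theta0) * xs)[None, :], (ny, nx)).copy()
        ys = (np.arange(ny) + 0.5) * h
        psi = psi + k * np.sin(theta0) * ys[:, None]
    else:
        px = k * np.cos(theta0 + alpha)
        py = k * np.sin(theta0 + alpha)
        psi = _integrate_phase(px, py, h)

    # edge dislocations: +-2*pi phase winding, one terminating fringe each
    sites = _place_dislocations(spec, rng)
    if sites:
        yy = ((np.arange(ny) + 0.5) * h)[:, None]
        xx = ((np.arange(nx) + 0.5) * h)[None, :]
        for i, (sx, sy) in enumerate(sites):
            sign = 1.0 if i % 2 == 0 else -1.0
            psi = psi + sign * np.arctan2(yy - sy, xx - sx)

    # rendered normal directions (from the actual phase gradient)
    gpy, gpx = np.gradient(psi, h)
    rendered_dev = np.arctan2(gpy, gpx) - theta0
    # fold to the axial range (-pi/2, pi/2]
    rendered_dev = (rendered_dev + np.pi / 2) % np.pi - np.pi / 2

    grating = 1.0 + spec.modulation_depth * np.cos(psi)

    # chord envelope of a circular cross-section, fiber axis through field center
    ys = (np.arange(ny) + 0.5) * h
    xs = (np.arange(nx) + 0.5) * h
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    v = -(xx - wx / 2) * np.sin(theta0) + (yy - wy / 2) * np.cos(theta0)
    radius = spec.fiber_diameter_um / 2
    z_center = (spec.n_slices - 1) / 2 * spec.z_step_um

    slices = np.empty((spec.n_slices, ny, nx))
    cas_num = 0.0
    cas_den = 0
    for iz in range(spec.n_slices):
        dz = iz * spec.z_step_um - z_center
        chord_sq = radius**2 - dz**2
        if chord_sq <= 0:
            env = np.zeros((ny, nx))
        else:
            half_chord = np.sqrt(chord_sq)
            env = (np.abs(v) <= half_chord).astype(float)
            env = ndimage.gaussian_filter(env, 0.8)
        img = spec.base_intensity * env * grating
        inside = env > 0.5
        cas_num += float(np.cos(rendered_dev[inside]).sum())
        cas_den += int(inside.sum())
        slices[iz] = img

    if spec.photon_scale > 0:
        slices = rng.poisson(np.clip(slices, 0, None) * spec.photon_scale) / spec.photon_scale
    if spec.read_sigma > 0:
        slices = slices + rng.normal(0.0, spec.read_sigma, slices.shape)
    slices = np.clip(slices, 0.0, None)

    stack = ImageStack(slices, pixel_size_um=h, z_step_um=spec.z_step_um)
    coords = [
        (sx, sy, iz * spec.z_step_um)
        for iz in range(spec.n_slices)
        for (sx, sy) in sites
    ]
    vd = spec.n_dislocations / (wx * wy / 100.0)
    truth = GroundTruth(
        true_sl_um=spec.sarcomere_length_um,
        true_diameter_um=spec.fiber_diameter_um,
        true_cas=cas_num / cas_den if cas_den else 1.0,
        true_vd_per_100um2=vd,
        dislocation_coords=coords,
        true_main_axis_deg=spec.main_axis_deg,
    )
    return stack, truth


# --------------------------------------------------------------------------
# force traces
# --------------------------------------------------------------------------

def hill_force(pca: np.ndarray | float, fmax: float, pca50: float, slope: float):
    """Steady-state active force of the Hill pCa-force relation.

    F(pCa) = F_max / (1 + 10^(h * (pCa - pCa50)))
    """
    return fmax / (1.0 + 10.0 ** (slope * (np.asarray(pca, dtype=float) - pca50)))


def _triangular_spike(t: np.ndarray, t0: float, width: float, amplitude: float):
    """Brief positive transient emulating a manual solution exchange."""
    half = width / 2
    return amplitude * np.clip(1.0 - np.abs(t - t0 - half) / half, 0.0, None)


def generate_force_trace(spec: TraceSpec) -> ForceTrace:
    """Synthesize an annotated force recording for one experimental design."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sampling_rate_hz
    dur = spec.step_duration_s
    spike_width = 0.2

    if spec.kind == "pca_series":
        levels = list(spec.pca_levels)
        n_steps = len(levels)
        t = np.arange(int(round(n_steps * dur / dt))) * dt
        force = np.zeros_like(t)
        annotations = []
        for i, pca in enumerate(levels):
            t0, t1 = i * dur, (i + 1) * dur
            sel = (t >= t0) & (t < t1)
            force[sel] = hill_force(pca, spec.fmax_force_un, spec.hill_pca50, spec.hill_slope)
            if spec.spikes_per_step > 0 and spec.spike_amplitude_un > 0:
                # exchanges early in the step, well clear of the analysed tail
                spike_times = t0 + (np.arange(spec.spikes_per_step) + 1) * (
                    0.3 * dur / (spec.spikes_per_step + 1)
                )
                if np.any(np.diff(spike_times) < spike_width):
                    raise ValueError("overlapping spike windows")
                for ts in spike_times:
                    force += _triangular_spike(t, ts, spike_width, spec.spike_amplitude_un)
            annotations.append(StepAnnotation("pca", pca, t0, t1))
        position = None
    else:
        steps = list(spec.step_sizes_um)
        n_steps = len(steps)
        t = np.arange(int(round(n_steps * dur / dt))) * dt
        force = np.zeros_like(t)
        position = np.zeros_like(t)
        annotations = []
        cum = 0.0
        for i, (step_um, feq) in enumerate(zip(steps, spec.feq_per_step_un)):
            t0, t1 = i * dur, (i + 1) * dur
            sel = (t >= t0) & (t < t1)
            tau = t[sel] - t0
            force[sel] = (
                feq
                + spec.a1_un * np.exp(-tau / spec.tau1_s)
                + spec.a2_un * np.exp(-tau / spec.tau2_s)
            )
            cum += step_um
            position[sel] = cum
            annotations.append(StepAnnotation("stretch", step_um, t0, t1))

    if spec.noise_sigma_un > 0:
        force = force + rng.normal(0.0, spec.noise_sigma_un, force.shape)
    return ForceTrace(t, force, position_um=position, annotations=annotations)


# --------------------------------------------------------------------------
# acquisition utilities
# --------------------------------------------------------------------------

def compute_pixel_energy(average_power_mw: float, sweep_time_us: float) -> float:
    """Energy deposited per pixel, in nanojoules.

    With average power P (mW) and per-pixel sweep time T (us), the deposited
    energy is P * T; 1 mW * 1 us = 1 nJ, so the product is already in nJ.
    Useful for validating acquisition settings against photodamage budgets.
    """
    if average_power_mw <= 0 or sweep_time_us <= 0:
        raise ValueError("power and sweep time must be positive")
    return average_power_mw * sweep_time_us
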