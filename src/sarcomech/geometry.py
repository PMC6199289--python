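"""Fiber geometry from SHG stacks: diameter, cross-sectional area, sarcomere length.

The diameter follows the width-profile procedure: the in-plane width of the
optical section is measured in every usable z-slice, the width-versus-depth
curve is fitted with a Gaussian, and the fitted peak is taken as the fiber
diameter (for a circular cross-section the widest chord is the diameter).
CSA is then the circle area pi*(D/2)^2.

Sarcomere length comes from a one-dimensional power spectrum taken along
the fiber direction: after rotating the slice so the main axis is
horizontal, rows inside the fiber are averaged into a single profile whose
spectrum shows an envelope peak near DC and the striation peak at 1/SL.
Peaks are ranked by amplitude; the highest is the envelope, the
second-highest is the striation frequency (refined by parabolic
interpolation), and the stack SL is the mean over valid slices.

Slice validity reproduces the intensity-coverage rule: a slice is evaluated
only if at least 10% of its pixels reach 10% of the stack maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage import measure

from .datatypes import ImageStack

__all__ = [
    "GeometryResult",
    "select_valid_slices",
    "measure_width_profile",
    "fit_diameter",
    "estimate_sl_slice",
    "estimate_sl_stack",
    "analyze_geometry",
]

# slice-validity rule: >= this fraction of pixels at >= this fraction of max
COVERAGE_FRAC = 0.10
INTENSITY_FRAC = 0.10
# spectrum bins below this frequency belong to the DC/envelope peak
ENVELOPE_FREQ_UM = 0.08


class NoStriationSignal(ValueError):
    """Raised when a slice spectrum shows no usable striation peak."""


@dataclass
class GeometryResult:
    """Fiber geometry extracted from one stack."""

    diameter_um: float
    csa_um2: float
    sl_um: float
    width_per_slice: pd.DataFrame = field(repr=False)
    sl_per_slice: pd.DataFrame = field(repr=False)
    valid_slices: list[int] = field(default_factory=list)
    diameter_fit_ok: bool = True

    def summary(self) -> str:
        lines = [
            "Fiber geometry",
            "--------------",
            f"diameter (um)     {self.diameter_um:8.2f}" + ("" if self.diameter_fit_ok else "  [fallback: max width]"),
            f"CSA (um^2)        {self.csa_um2:8.1f}",
            f"SL (um)           {self.sl_um:8.3f}",
            f"valid slices      {len(self.valid_slices):8d}",
        ]
        return "\n".join(lines)


def select_valid_slices(stack: ImageStack) -> list[int]:
    """Indices of slices passing the intensity-coverage rule.

    Slice z is kept iff at least 10% of its pixels have intensity of at
    least 10% of the stack maximum (both bounds inclusive).
    """
    ref = float(stack.voxels.max())
    if ref <= 0:
        return []
    frac = (stack.voxels >= INTENSITY_FRAC * ref).mean(axis=(1, 2))
    return [int(i) for i in np.nonzero(frac >= COVERAGE_FRAC)[0]]


def measure_width_profile(
    stack: ImageStack,
    threshold_frac: float = 0.10,
    main_axis_deg: float = 0.0,
    slice_indices: list[int] | None = None,
) -> pd.DataFrame:
    """Per-slice fiber width perpendicular to the main axis.

    The width is the extent, perpendicular to the fiber axis, of the
    largest connected region above ``threshold_frac`` times the stack
    maximum.  Slices with no suprathreshold pixels get width 0 and a flag.
    The threshold is relative, so the result is invariant to intensity
    rescaling.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    ref = float(stack.voxels.max())
    indices = (
        list(range(stack.n_slices)) if slice_indices is None else list(slice_indices)
    )
    ux, uy = np.cos(np.deg2rad(main_axis_deg)), np.sin(np.deg2rad(main_axis_deg))
    rows = []
    for iz in indices:
        img = stack.voxels[iz]
        above = img >= threshold_frac * ref
        if not above.any():
            rows.append({"slice": iz, "width_um": 0.0, "empty": True})
            continue
        labels = measure.label(above)
        largest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
        ys, xs = np.nonzero(largest)
        # signed distance perpendicular to the axis direction
        perp = -xs * uy + ys * ux
        width = (perp.max() - perp.min() + 1) * stack.pixel_size_um
        rows.append({"slice": iz, "width_um": float(width), "empty": False})
    return pd.DataFrame(rows)


def _gaussian(z: np.ndarray, amp: float, z0: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((z - z0) / sigma) ** 2)


def fit_diameter(
    width_per_slice: pd.DataFrame, z_step_um: float
) -> tuple[float, float, bool]:
    """Gaussian fit of the width-vs-depth curve.

    Returns (diameter_um, csa_um2, fit_ok).  The diameter is the fitted
    peak amplitude; CSA assumes a circular cross-section.  When the fit
    fails to converge the maximum measured width is used and flagged.
    """
    data = width_per_slice[~width_per_slice.get("empty", False)]
    widths = data["width_um"].to_numpy(dtype=float)
    z = data["slice"].to_numpy(dtype=float) * z_step_um
    if len(widths) < 5:
        raise ValueError("need at least 5 valid slice widths for the diameter fit")
    amp0 = widths.max()
    z00 = z[np.argmax(widths)]
    sigma0 = max(np.ptp(z) / 4, z_step_um)
    fit_ok = True
    try:
        popt, _ = curve_fit(
            _gaussian, z, widths, p0=(amp0, z00, sigma0), maxfev=10000
        )
        diameter = float(abs(popt[0]))
        if not np.isfinite(diameter) or diameter <= 0:
            raise RuntimeError
    except RuntimeError:
        diameter = float(amp0)
        fit_ok = False
    csa = np.pi * (diameter / 2.0) ** 2
    return diameter, float(csa), fit_ok


def _spectrum_profile(
    image: np.ndarray, main_axis_deg: float, intensity_ref: float
) -> np.ndarray:
    """Rotate the slice so the fiber is horizontal and average fiber rows."""
    if abs(main_axis_deg) > 1e-6:
        image = ndimage.rotate(image, main_axis_deg, reshape=True, order=1)
    row_has_fiber = (image >= INTENSITY_FRAC * intensity_ref).any(axis=1)
    if not row_has_fiber.any():
        raise NoStriationSignal("no fiber rows in slice")
    return image[row_has_fiber].mean(axis=0)


def estimate_sl_slice(
    image: np.ndarray,
    main_axis_deg: float,
    pixel_size_um: float,
    intensity_ref: float | None = None,
    snr_min: float = 3.0,
) -> float:
    """Sarcomere length of one slice from the axial power spectrum.

    The profile along the fiber is transformed; the DC/envelope region
    (below 0.08 1/um) forms the highest peak, and the second-highest peak
    is read as the striation frequency.  Its bin is refined by parabolic
    interpolation of the log-magnitude.  Raises :class:`NoStriationSignal`
    if the candidate peak is weaker than ``snr_min`` times the spectral
    noise floor (median magnitude outside the envelope).
    """
    image = np.asarray(image, dtype=float)
    ref = float(image.max()) if intensity_ref is None else float(intensity_ref)
    profile = _spectrum_profile(image, main_axis_deg, ref)
    n = len(profile)
    mag = np.abs(np.fft.rfft(profile - profile.mean()))
    freqs = np.fft.rfftfreq(n, d=pixel_size_um)
    beyond = freqs >= ENVELOPE_FREQ_UM
    if beyond.sum() < 5:
        raise NoStriationSignal("profile too short for spectral analysis")
    # local maxima of the out-of-envelope spectrum, ranked by amplitude
    m = mag.copy()
    m[~beyond] = 0.0
    is_peak = np.r_[False, (m[1:-1] > m[:-2]) & (m[1:-1] >= m[2:]), False]
    if not is_peak.any():
        raise NoStriationSignal("no spectral peak beyond the envelope")
    peak_idx = int(np.flatnonzero(is_peak)[np.argmax(m[is_peak])])
    floor = float(np.median(mag[beyond]))
    if floor > 0 and mag[peak_idx] < snr_min * floor:
        raise NoStriationSignal(
            f"striation peak {mag[peak_idx]:.3g} below {snr_min}x noise floor {floor:.3g}"
        )
    # parabolic interpolation on log magnitude for sub-bin frequency
    f = freqs[peak_idx]
    if 0 < peak_idx < len(mag) - 1 and mag[peak_idx - 1] > 0 and mag[peak_idx + 1] > 0:
        la, lb, lc = np.log(mag[peak_idx - 1 : peak_idx + 2])
        denom = la - 2 * lb + lc
        if denom < 0:
            delta = 0.5 * (la - lc) / denom
            f = f + delta * (freqs[1] - freqs[0])
    if f <= 0:
        raise NoStriationSignal("non-positive striation frequency")
    return float(1.0 / f)


def estimate_sl_stack(
    stack: ImageStack,
    main_axis_deg: float = 0.0,
    slice_indices: list[int] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Stack sarcomere length: mean of per-valid-slice estimates.

    Slices raising :class:`NoStriationSignal` are skipped (recorded with a
    NaN); an error is raised only when no slice is usable.
    """
    indices = select_valid_slices(stack) if slice_indices is None else list(slice_indices)
    if not indices:
        raise ValueError("no valid slice for SL estimation")
    ref = float(stack.voxels.max())
    rows = []
    for iz in indices:
        try:
            sl = estimate_sl_slice(
                stack.voxels[iz], main_axis_deg, stack.pixel_size_um, intensity_ref=ref
            )
        except NoStriationSignal:
            sl = np.nan
        rows.append({"slice": iz, "sl_um": sl})
    table = pd.DataFrame(rows)
    good = table["sl_um"].dropna()
    if good.empty:
        raise ValueError("no slice with a striation signal")
    return float(good.mean()), table


def analyze_geometry(
    stack: ImageStack,
    main_axis_deg: float = 0.0,
    threshold_frac: float = 0.10,
) -> GeometryResult:
    """Diameter, CSA and SL of one stack using the standard procedures."""
    valid = select_valid_slices(stack)
    if not valid:
        raise ValueError("no valid slices in stack")
    widths = measure_width_profile(
        stack, threshold_frac=threshold_frac, main_axis_deg=main_axis_deg,
        slice_indices=valid,
    )
    if len(widths[~widths["empty"]]) >= 5:
        diameter, csa, fit_ok = fit_diameter(widths, stack.z_step_um)
    else:
        w = widths.loc[~widths["empty"], "width_um"]
        diameter = float(w.max()) if len(w) else 0.0
        csa = np.pi * (diameter / 2.0) ** 2
        fit_ok = False
    sl, sl_table = estimate_sl_stack(stack, main_axis_deg, slice_indices=valid)
    return GeometryResult(
        diameter_um=diameter,
        csa_um2=float(csa),
        sl_um=sl,
        width_per_slice=widths,
        sl_per_slice=sl_table,
        valid_slices=valid,
        diameter_fit_ok=fit_ok,
    )
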