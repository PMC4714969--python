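"""Ratiometric ciliary Ca²⁺ quantification (GCaMP6s / mCherry).

The sensor is a cilia-targeted fusion of a green Ca²⁺ indicator
(GCaMP6s) and a red Ca²⁺-insensitive reference (mCherry); the green/red
ratio reports free [Ca²⁺] independent of expression level.  The pipeline:

1. mask cilia by thresholding the red channel (which reports only sensor
   presence) and excluding saturated pixels,
2. background-subtract both channels and form the per-pixel ratio,
3. under non-sequential scanning, correct the mean ratio for green→red
   spectral bleed-through: A_c = R − α, with α the slope of a linear fit
   of leak intensity vs green intensity in a red-free specimen,
4. calibrate corrected ratios against buffers of known free [Ca²⁺] with a
   Hill fit, and invert the fit to convert measured ratios into nM.

The subtractive bleed-through correction is the conventional first-order
one; see the methods note for its accuracy limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class MaskWarning(UserWarning):
    pass


class DynamicRangeError(ValueError):
    """Ratio outside the invertible (R_min, R_max) range of the Hill fit."""


@dataclass
class TwoChannelStack:
    """Congruent green (GCaMP6s) and red (mCherry) frame stacks.

    ``scan_mode`` records how the two channels were acquired:
    ``non_sequential`` (simultaneous; beating cilia stay registered but
    green emission bleeds into the red detector) or ``sequential``
    (no bleed-through; only valid for immobilized cilia).
    """

    green: np.ndarray            # (n_frames, h, w)
    red: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    bit_depth: int = 16
    scan_mode: str = "non_sequential"

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.ndim == 2:
            self.green = self.green[None]
        if self.red.ndim == 2:
            self.red = self.red[None]
        if self.green.shape != self.red.shape:
            raise ValueError("green and red stacks must be congruent")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        if self.scan_mode not in ("sequential", "non_sequential"):
            raise ValueError("scan_mode must be sequential or non_sequential")

    @property
    def saturation_level(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class BleedthroughFit:
    alpha: float            # leak per unit green intensity (dimensionless)
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class HillFit:
    """Hill-equation parameters of the ratio–[Ca²⁺] relation.

    A_c([Ca]) = R_min + (R_max − R_min)·[Ca]ⁿ / (EC50ⁿ + [Ca]ⁿ)
    with [Ca] and EC50 in nM.
    """

    R_min: float
    R_max: float
    EC50_nM: float
    n_H: float
    covariance: np.ndarray | None = None

    def forward(self, ca_nm):
        ca = np.asarray(ca_nm, dtype=float)
        cn = ca ** self.n_H
        return self.R_min + (self.R_max - self.R_min) * cn / (self.EC50_nM ** self.n_H + cn)


@dataclass
class CalibrationCurve:
    free_ca_nM: np.ndarray
    mean_Ac: np.ndarray
    sem_Ac: np.ndarray
    n_per_level: np.ndarray
    hill: HillFit | None = None


@dataclass
class RatioTimeSeries:
    time_s: np.ndarray
    ratio: np.ndarray
    normalized: np.ndarray | None = None
    roi_label: str = ""
    bleedthrough_corrected: bool = False


# ---------------------------------------------------------------------------
# masking and ratio images
# ---------------------------------------------------------------------------

def make_cilium_mask(red_frame: np.ndarray, threshold: float,
                     saturation_level: float) -> np.ndarray:
    """Binary cilium mask: threshold ≤ red < saturation.

    The red (mCherry) channel reports sensor presence independent of Ca²⁺,
    so pixels below ``threshold`` carry no sensor and saturated pixels are
    unquantifiable; both are excluded.
    """
    if not threshold < saturation_level:
        raise ValueError("threshold must lie below the saturation level")
    red_frame = np.asarray(red_frame, dtype=float)
    mask = (red_frame >= threshold) & (red_frame < saturation_level)
    if not mask.any():
        warnings.warn("cilium mask is empty", MaskWarning, stacklevel=2)
    return mask


def ratio_image(stack: TwoChannelStack, mask: np.ndarray,
                background_g: float, background_r: float,
                denominator_floor: float | None = None
                ) -> tuple[np.ndarray, int]:
    """Per-pixel background-subtracted green/red ratio on masked pixels.

    Unmasked pixels are NaN.  Masked pixels whose red signal, after
    background subtraction, falls at or below ``denominator_floor``
    (default 1 % of the red channel's dynamic range, i.e. its
    background-subtracted maximum) are dropped (NaN); the count of
    dropped pixels is returned alongside the ratio stack.
    """
    if denominator_floor is None:
        denominator_floor = max(0.01 * (float(stack.red.max()) - background_r),
                                1e-9)
    g = stack.green - background_g
    r = stack.red - background_r
    valid = mask[None, :, :] & (r > denominator_floor)
    n_dropped = int((mask[None, :, :] & ~valid).sum())
    out = np.full(g.shape, np.nan)
    np.divide(g, r, out=out, where=valid)
    if n_dropped and n_dropped == int(mask.sum()) * g.shape[0]:
        warnings.warn("all masked pixels dropped (background ≥ signal?)",
                      MaskWarning, stacklevel=2)
    return out, n_dropped


def mean_masked_ratio(ratio_frames: np.ndarray) -> float:
    """Mean ratio over all masked (finite) pixels of all frames.

    Matches the convention of averaging the fluorescence of *all* motile
    cilia of a cell rather than per-cilium averaging.
    """
    finite = np.isfinite(ratio_frames)
    if not finite.any():
        return float("nan")
    return float(ratio_frames[finite].mean())


# ---------------------------------------------------------------------------
# bleed-through
# ---------------------------------------------------------------------------

def estimate_bleedthrough(green_means, leak_means) -> BleedthroughFit:
    """Slope α of the leak (red-channel) signal vs green signal, by OLS.

    Measured on a specimen expressing only the green indicator, where any
    red-channel signal is pure bleed-through.
    """
    x = np.asarray(green_means, dtype=float)
    y = np.asarray(leak_means, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("green intensities are constant; slope is undefined")
    res = stats.linregress(x, y)
    return BleedthroughFit(alpha=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue ** 2), n_points=int(x.size))


def correct_ratio(raw_ratio, alpha: float):
    """Bleed-through-corrected ratio A_c = R − α.

    α ≥ 0 is the bleed-through slope.  The result may be negative and is
    reported as-is.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return np.asarray(raw_ratio, dtype=float) - alpha


# ---------------------------------------------------------------------------
# Hill calibration
# ---------------------------------------------------------------------------

def _hill(ca, r_min, r_max, ec50, n_h):
    cn = ca ** n_h
    return r_min + (r_max - r_min) * cn / (ec50 ** n_h + cn)


def fit_hill(free_ca_nm, ratios, weights=None) -> HillFit:
    """Weighted least-squares Hill fit of corrected ratios vs free [Ca²⁺].

    At least five concentration levels spanning the transition are
    required.  Bounds: R_min ≥ 0, n_H ∈ (0.3, 6).  Non-monotone data emit
    a warning (the fit proceeds); an all-flat curve raises.
    """
    ca = np.asarray(free_ca_nm, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if ca.size < 5:
        raise ValueError("need at least 5 concentration levels")
    order = np.argsort(ca)
    ca, y = ca[order], y[order]
    if weights is not None:
        w = np.asarray(weights, dtype=float)[order]
        sigma = 1.0 / np.sqrt(w / w.mean())
    else:
        sigma = None
    if np.ptp(y) < 1e-12:
        raise ValueError("all ratios equal; calibration curve is degenerate")
    dy = np.diff(y)
    if np.any(dy < -0.05 * np.ptp(y)):
        warnings.warn("calibration ratios are not monotone in [Ca²⁺]",
                      stacklevel=2)

    p0 = (max(y.min(), 1e-6), y.max(), float(np.median(ca)), 1.5)
    bounds = ([0.0, 0.0, 1e-3, 0.3], [np.inf, np.inf, 1e9, 6.0])
    try:
        popt, pcov = optimize.curve_fit(_hill, ca, y, p0=p0, sigma=sigma,
                                        absolute_sigma=False, bounds=bounds,
                                        maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"Hill fit did not converge: {err}") from err
    return HillFit(R_min=float(popt[0]), R_max=float(popt[1]),
                   EC50_nM=float(popt[2]), n_H=float(popt[3]), covariance=pcov)


def ratio_to_calcium(a_c: float, hill: HillFit) -> float:
    """Invert the Hill fit: [Ca²⁺] = EC50·((A_c−R_min)/(R_max−A_c))^(1/n_H), nM."""
    if a_c <= hill.R_min:
        raise DynamicRangeError(
            f"ratio {a_c:.4g} at or below the fit floor R_min={hill.R_min:.4g}")
    if a_c >= hill.R_max:
        raise DynamicRangeError(
            f"ratio {a_c:.4g} at or above the fit ceiling R_max={hill.R_max:.4g}")
    return float(hill.EC50_nM * ((a_c - hill.R_min) / (hill.R_max - a_c)) ** (1.0 / hill.n_H))


# ---------------------------------------------------------------------------
# high-level pipelines
# ---------------------------------------------------------------------------

def calibrate(stacks_per_level: dict[float, list[TwoChannelStack]],
              mask_threshold: float, background_g: float, background_r: float,
              alpha: float | None = None) -> CalibrationCurve:
    """Build a calibration curve from stacks acquired at known free [Ca²⁺].

    For each level the mean masked ratio of every stack is computed; when
    the stacks were scanned non-sequentially the bleed-through correction
    A_c = R − α is applied (``alpha`` then must be given).  The per-level
    means are fitted with the Hill equation.
    """
    levels = sorted(stacks_per_level)
    means, sems, ns = [], [], []
    for ca in levels:
        vals = []
        for stack in stacks_per_level[ca]:
            mask = make_cilium_mask(stack.red[0], mask_threshold,
                                    stack.saturation_level)
            frames, _ = ratio_image(stack, mask, background_g, background_r)
            r = mean_masked_ratio(frames)
            if stack.scan_mode == "non_sequential":
                if alpha is None:
                    raise ValueError("non-sequential stacks require alpha")
                r = float(correct_ratio(r, alpha))
            vals.append(r)
        vals = np.asarray(vals)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
        ns.append(len(vals))
    curve = CalibrationCurve(np.asarray(levels, dtype=float), np.asarray(means),
                             np.asarray(sems), np.asarray(ns))
    curve.hill = fit_hill(curve.free_ca_nM, curve.mean_Ac)
    return curve


def quantify_basal_calcium(stack: TwoChannelStack, curve: CalibrationCurve,
                           mask_threshold: float, background_g: float,
                           background_r: float,
                           alpha: float | None = None) -> tuple[float, float]:
    """Measure the resting ciliary ratio and convert it to free [Ca²⁺] (nM).

    Returns ``(A_c, ca_nM)``.  The same scan-mode rules as in
    :func:`calibrate` apply.
    """
    if curve.hill is None:
        raise ValueError("calibration curve carries no Hill fit")
    mask = make_cilium_mask(stack.red[0], mask_threshold, stack.saturation_level)
    frames, _ = ratio_image(stack, mask, background_g, background_r)
    r = mean_masked_ratio(frames)
    if stack.scan_mode == "non_sequential":
        if alpha is None:
            raise ValueError("non-sequential stack requires alpha")
        r = float(correct_ratio(r, alpha))
    return r, ratio_to_calcium(r, curve.hill)


def normalize_timeseries(series: RatioTimeSeries,
                         baseline_frames: int = 1) -> RatioTimeSeries:
    """Normalize a ratio time course to its initial value, R/R₀.

    R₀ is the mean ratio over the first ``baseline_frames`` frames; the
    normalized trace averages exactly 1 over that window.
    """
    if baseline_frames < 1 or baseline_frames > series.ratio.size:
        raise ValueError("baseline window outside the series")
    r0 = float(np.mean(series.ratio[:baseline_frames]))
    if r0 <= 0:
        raise ValueError("baseline ratio must be positive")
    return RatioTimeSeries(time_s=series.time_s, ratio=series.ratio,
                           normalized=series.ratio / r0,
                           roi_label=series.roi_label,
                           bleedthrough_corrected=series.bleedthrough_corrected)
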