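"""The Alignment Index (AI) and its supporting histogram operations.

AI is a 2D nematic order parameter for axial orientation data:

    AI = | (1/N) * sum_i w_i * (2 cos^2(theta_i - theta_th) - 1) |
       = | sum_i w_i cos(2 (theta_i - theta_th)) / sum_i w_i |

where theta_th is the doubled-angle circular mean orientation. AI = 1
means zero angular dispersion (perfect alignment); AI = 0 means a fully
random (uniform) set of orientations.

Because mature sub-epidermal collagen forms two orthogonal fibril
families — which would cancel each other in a single global AI — the
angular histogram is split at 90 degrees and each half-range is assessed
independently, after subtracting the orientation-independent noise floor
from the histogram. A mass-weighted mean of the two per-range values
serves as the single per-image summary.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Union

import numpy as np

from .directionality import (
    DirectionalityParams,
    OrientationHistogram,
    angular_histogram,
    power_spectrum,
)

__all__ = [
    "OrientationSample",
    "AIResult",
    "subtract_background",
    "split_ranges",
    "circular_mean_orientation",
    "alignment_index",
    "analyze_sample",
    "analyze_image",
]


@dataclass
class OrientationSample:
    """Discrete axial measurements theta_i in [0, 180) with optional weights."""

    angles: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() >= 180.0):
            raise ValueError("angles must lie in [0, 180)")
        if self.weights is not None:
            self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
            if self.weights.shape != self.angles.shape:
                raise ValueError("weights must match angles in shape")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")


Angular = Union[OrientationSample, OrientationHistogram, np.ndarray, list]


def _angles_weights(data: Angular) -> tuple[np.ndarray, np.ndarray]:
    """Common access path: histograms contribute bin centers weighted by
    bin values; samples contribute their angles and weights."""
    if isinstance(data, OrientationHistogram):
        return data.bin_centers, data.values
    if isinstance(data, OrientationSample):
        w = data.weights if data.weights is not None else np.ones_like(data.angles)
        return data.angles, w
    angles = np.atleast_1d(np.asarray(data, dtype=float))
    return angles, np.ones_like(angles)


@dataclass
class AIResult:
    """Per-range and combined Alignment Index for one image or sample.

    The low range is [0, 90), the high range [90, 180). ``mass_*`` is the
    total histogram weight in each range after background subtraction;
    ``ai_combined`` is the mass-weighted mean of the two range AIs. A
    degenerate range (zero mass) reports AI 0 and theta NaN.
    """

    ai_low: float
    ai_high: float
    theta_th_low: float
    theta_th_high: float
    mass_low: float
    mass_high: float
    ai_combined: float
    degenerate_low: bool = False
    degenerate_high: bool = False

    @property
    def ai_dominant(self) -> float:
        """AI of the range carrying more mass (single-family readout)."""
        return self.ai_low if self.mass_low >= self.mass_high else self.ai_high

    def to_dict(self) -> dict:
        return asdict(self)


def subtract_background(
    hist: OrientationHistogram, *, percentile: float = 0.0
) -> OrientationHistogram:
    """Remove the orientation-independent noise floor from a histogram.

    Default rule subtracts the minimum bin value (percentile = 0); a
    higher ``percentile`` subtracts that percentile of the bin values
    instead, clamping at zero. A flat histogram becomes all-zero and is
    flagged degenerate.
    """
    if hist.n_bins == 0:
        return hist
    floor = float(np.percentile(hist.values, percentile)) if percentile > 0 \
        else float(hist.values.min())
    values = np.clip(hist.values - floor, 0.0, None)
    degenerate = bool(values.sum() == 0.0)
    return OrientationHistogram(
        hist.bin_centers.copy(), values, normalized=False,
        provenance=hist.provenance, degenerate=degenerate,
    )


def split_ranges(
    hist: OrientationHistogram,
) -> tuple[OrientationHistogram, OrientationHistogram]:
    """Partition a histogram at the 90-degree boundary.

    Bin edges must align with 90 degrees (true for any even bin count over
    [0, 180)); a straddling bin is an error rather than a silent split.
    """
    width = hist.bin_width
    edges = hist.bin_centers - width / 2.0
    # tolerate float rounding: an edge within ~1e-9 bins of 90 is aligned
    eps = 1e-9 * width
    straddle = (edges < 90.0 - eps) & (edges + width > 90.0 + eps)
    if np.any(straddle):
        raise ValueError(
            "a histogram bin straddles 90 degrees; use an even bin count"
        )
    low_mask = hist.bin_centers < 90.0
    low = OrientationHistogram(
        hist.bin_centers[low_mask], hist.values[low_mask],
        provenance=hist.provenance,
    )
    high = OrientationHistogram(
        hist.bin_centers[~low_mask], hist.values[~low_mask],
        provenance=hist.provenance,
    )
    return low, high


def circular_mean_orientation(data: Angular) -> tuple[float, dict]:
    """Doubled-angle circular mean orientation theta_th in [0, 180).

    theta_th = 0.5 * atan2(sum w sin 2theta, sum w cos 2theta), which is
    the standard axial mean and coincides with the arithmetic mean for
    tight unimodal samples away from the wrap.

    Returns (theta_th, flags). Zero total weight -> theta NaN and
    ``degenerate``; an (numerically) vanishing resultant — e.g. exactly
    balanced orthogonal masses — returns the smaller-angle solution with
    ``ambiguous`` set.
    """
    angles, weights = _angles_weights(data)
    flags = {"degenerate": False, "ambiguous": False}
    total = float(weights.sum())
    if total == 0.0 or angles.size == 0:
        flags["degenerate"] = True
        return float("nan"), flags
    two = np.deg2rad(2.0 * angles)
    C = float(np.sum(weights * np.cos(two))) / total
    S = float(np.sum(weights * np.sin(two))) / total
    R = float(np.hypot(C, S))
    if R < 1e-12:
        # resultant vanishes: any theta_th is as good; take the smaller root
        flags["ambiguous"] = True
        return 0.0, flags
    theta = np.rad2deg(np.arctan2(S, C)) / 2.0 % 180.0
    return float(theta), flags


def alignment_index(data: Angular, theta_th: float | None = None) -> float:
    """AI = |sum w cos(2(theta - theta_th))| / sum w, in [0, 1].

    If ``theta_th`` is omitted it is the doubled-angle circular mean of
    the data, in which case AI equals the mean resultant length of the
    doubled angles. Zero total weight gives AI 0 (degenerate convention).
    """
    angles, weights = _angles_weights(data)
    total = float(weights.sum())
    if total == 0.0 or angles.size == 0:
        return 0.0
    if theta_th is None:
        theta_th, flags = circular_mean_orientation(data)
        if flags["degenerate"]:
            return 0.0
    delta = np.deg2rad(2.0 * (angles - theta_th))
    ai = abs(float(np.sum(weights * np.cos(delta)))) / total
    return float(min(ai, 1.0))


def analyze_sample(data: Angular, *, background: bool = False,
                   percentile: float = 0.0) -> AIResult:
    """Range-split AI analysis of a histogram or angle sample.

    For histograms, optionally background-subtract first. Each half-range
    gets its own theta_th and AI; ``ai_combined`` is their mass-weighted
    mean, which reduces to the single-family AI when one range is empty.
    """
    if isinstance(data, OrientationHistogram):
        hist = subtract_background(data, percentile=percentile) if background else data
        low, high = split_ranges(hist)
        parts = (low, high)
    else:
        angles, weights = _angles_weights(data)
        lo = angles < 90.0
        parts = (
            OrientationSample(angles[lo], weights[lo]),
            OrientationSample(angles[~lo], weights[~lo]),
        )

    stats = []
    for part in parts:
        _, w = _angles_weights(part)
        mass = float(np.sum(w))
        theta, flags = circular_mean_orientation(part)
        ai = alignment_index(part, theta) if not flags["degenerate"] else 0.0
        stats.append((ai, theta, mass, flags["degenerate"]))

    (ai_l, th_l, m_l, d_l), (ai_h, th_h, m_h, d_h) = stats
    total = m_l + m_h
    combined = (m_l * ai_l + m_h * ai_h) / total if total > 0 else 0.0
    return AIResult(
        ai_low=ai_l, ai_high=ai_h,
        theta_th_low=th_l, theta_th_high=th_h,
        mass_low=m_l, mass_high=m_h,
        ai_combined=float(combined),
        degenerate_low=d_l, degenerate_high=d_h,
    )


def analyze_image(
    image: np.ndarray,
    params: DirectionalityParams | None = None,
    *,
    background: bool = True,
    percentile: float = 0.0,
) -> AIResult:
    """Full per-image pipeline: power spectrum -> angular histogram ->
    background subtraction -> range split -> per-range theta_th and AI."""
    params = params or DirectionalityParams()
    spec = power_spectrum(image, params)
    hist = angular_histogram(spec, params)
    return analyze_sample(hist, background=background, percentile=percentile)
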