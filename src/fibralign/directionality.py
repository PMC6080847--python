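"""Orientation histograms from the 2D Fourier power spectrum.

A field of fibrils oriented at angle theta concentrates spectral energy
along the direction perpendicular to theta in the frequency plane. The
directionality method therefore (1) windows and transforms the image,
(2) bins the power spectrum's energy by the orientation of each frequency
pixel within an annular band, and (3) rotates by 90 degrees back into
real-space fibril coordinates, folding opposite half-planes together
because orientations are axial (period 180 degrees).

Conventions (shared package-wide): angles in degrees, counter-clockwise
from the +x (column) axis with y up; half-open range [0, 180). Images are
row-major, so on a y-down display the rotation appears clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DirectionalityParams",
    "OrientationHistogram",
    "power_spectrum",
    "angular_histogram",
    "histogram_from_angles",
    "read_image",
]


@dataclass(frozen=True)
class DirectionalityParams:
    """Tunable knobs of the Fourier directionality stage.

    n_bins : angular bins over [0, 180); 90 bins give 2-degree resolution.
    window : apodization applied before the FFT ("hann" or "none"); Hann
        suppresses the cross-shaped edge artifact of a periodised image.
    f_min, f_max : radial band as a fraction of the Nyquist frequency;
        the lower cut removes the DC/low-frequency background blob, the
        upper cut removes corner anisotropy (frequencies above Nyquist on
        the diagonals).
    pad_pow2 : pad the (square) image up to the next power of two.
    """

    n_bins: int = 90
    window: str = "hann"
    f_min: float = 0.02
    f_max: float = 0.9
    pad_pow2: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError(f"n_bins must be >= 8, got {self.n_bins}")
        if not (0.0 <= self.f_min < self.f_max <= 1.0):
            raise ValueError(
                f"need 0 <= f_min < f_max <= 1, got ({self.f_min}, {self.f_max})"
            )
        if self.window not in ("hann", "none"):
            raise ValueError(f"unknown window {self.window!r}")


@dataclass
class OrientationHistogram:
    """Binned axial orientation distribution over [0, 180) degrees."""

    bin_centers: np.ndarray
    values: np.ndarray
    normalized: bool = False
    provenance: str = "fourier"  # "fourier" | "ground_truth"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin_centers and values must have equal shape")
        if np.any(self.values < 0):
            raise ValueError("histogram values must be non-negative")
        if len(self.bin_centers) > 1 and np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    @property
    def bin_width(self) -> float:
        if len(self.bin_centers) > 1:
            return float(self.bin_centers[1] - self.bin_centers[0])
        return 180.0

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def normalize(self) -> "OrientationHistogram":
        tot = self.total
        if tot == 0:
            return OrientationHistogram(
                self.bin_centers, self.values, True, self.provenance, True
            )
        return OrientationHistogram(
            self.bin_centers, self.values / tot, True, self.provenance, self.degenerate
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_deg": self.bin_centers, "value": self.values}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "fourier"):
        df = pd.read_csv(path)
        return cls(df["bin_center_deg"].to_numpy(), df["value"].to_numpy(),
                   provenance=provenance)


def _bin_centers(n_bins: int) -> np.ndarray:
    width = 180.0 / n_bins
    return (np.arange(n_bins) + 0.5) * width


def power_spectrum(
    image: np.ndarray, params: DirectionalityParams | None = None
) -> np.ndarray:
    """Centered power spectrum |F|^2 / Npix of the windowed, mean-subtracted image.

    Mean subtraction kills the DC spike; the 1/Npix scaling makes the sum
    of the spectrum equal the sum of the squared windowed image (Parseval).
    The image is padded to a square (optionally to the next power of two)
    before transforming; padding happens after windowing, so pad pixels
    contribute no energy.
    """
    params = params or DirectionalityParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got ndim={image.ndim}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    work = image - image.mean()
    if params.window == "hann":
        wr = np.hanning(work.shape[0])
        wc = np.hanning(work.shape[1])
        work = work * np.outer(wr, wc)
    n = max(work.shape)
    if params.pad_pow2:
        n = 1 << (n - 1).bit_length()
    padded = np.zeros((n, n), dtype=float)
    padded[: work.shape[0], : work.shape[1]] = work
    F = np.fft.fftshift(np.fft.fft2(padded))
    return (np.abs(F) ** 2) / padded.size


def angular_histogram(
    spectrum: np.ndarray, params: DirectionalityParams | None = None
) -> OrientationHistogram:
    """Accumulate annular spectral energy into axial orientation bins.

    Each frequency pixel inside the radial band [f_min, f_max] (fractions
    of Nyquist) contributes its full energy to the single bin containing
    its orientation. The 90-degree frequency-to-real-space rotation is
    applied here, so the returned histogram is already in fibril
    coordinates; opposite half-planes fold together by the axial mod-180.
    """
    params = params or DirectionalityParams()
    spec = np.asarray(spectrum, dtype=float)
    if spec.ndim != 2 or spec.shape[0] != spec.shape[1]:
        raise ValueError("expected a square centered spectrum")
    n = spec.shape[0]
    c = n // 2  # fftshift center
    idx = np.arange(n, dtype=float) - c
    nyq = n / 2.0
    fx = idx[np.newaxis, :] / nyq  # column frequency, fraction of Nyquist
    fy = -idx[:, np.newaxis] / nyq  # row frequency, sign-flipped for y-up
    r = np.hypot(fx, fy)
    band = (r >= params.f_min) & (r <= params.f_max)
    if not band.any():
        raise ValueError("radial band selects no frequency pixels")
    phi = np.degrees(np.arctan2(fy, fx))  # orientation of the frequency pixel
    theta = (phi + 90.0) % 180.0  # real-space fibril orientation
    width = 180.0 / params.n_bins
    bins = np.minimum((theta[band] / width).astype(int), params.n_bins - 1)
    values = np.bincount(bins, weights=spec[band], minlength=params.n_bins)
    return OrientationHistogram(_bin_centers(params.n_bins), values, provenance="fourier")


def histogram_from_angles(
    angles: np.ndarray, n_bins: int = 90, weights: np.ndarray | None = None
) -> OrientationHistogram:
    """Bin ground-truth axial angles directly (the oracle path).

    Angles must already lie in [0, 180); callers wrap first, so an
    out-of-range value is a hard error rather than silently folded.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size and (angles.min() < 0.0 or angles.max() >= 180.0):
        raise ValueError("angles must lie in [0, 180); wrap before binning")
    values, _ = np.histogram(
        angles, bins=n_bins, range=(0.0, 180.0), weights=weights
    )
    return OrientationHistogram(
        _bin_centers(n_bins), values.astype(float), provenance="ground_truth"
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF as float64; reject multi-channel input."""
    arr = tifffile.imread(path)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2D image, got shape {arr.shape}; "
            "extract one channel before analysis"
        )
    return arr.astype(float)
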