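"""Synthetic fibril-image generation with known orientation ground truth.

This module draws fields of straight, fluorescently-rendered fibril
segments whose orientations come from an axial von Mises mixture, so that
every downstream stage (power spectrum, angular histogram, alignment
index, group statistics) can be validated against exact ground truth.

Two families of presets emulate the biology this pipeline targets:

* a developmental series — sparse, randomly oriented wisps that mature
  into a dense two-family orthogonal cross-hatch lattice;
* a wound-repair series — an orthogonal lattice with a circular region
  denuded of fibrils that refills over a simulated timecourse, first with
  sparse randomly aligned material and finally with lattice-like order.

All angles are axial: a fibril at theta and theta + 180 deg are the same
object, so orientations live in the half-open interval [0, 180) and all
circular arithmetic is done on doubled angles (period 360 deg).

Coordinate convention: x is the column index, y is the row index, and the
orientation angle is measured counter-clockwise from +x with the y axis
pointing *up* mathematically. On a screen that displays row 0 at the top
the rotation therefore appears clockwise; all modules in this package
share the convention, so rendered and recovered angles agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MixtureComponent",
    "OrientationMixture",
    "FibrilSegment",
    "FibrilScene",
    "WoundScenario",
    "sample_orientations",
    "render_scene",
    "random_scene",
    "make_developmental_series",
    "make_wound_series",
    "developmental_presets",
    "write_scene",
]


class ParameterError(ValueError):
    """Raised when a simulation parameter is out of its valid domain."""


# ---------------------------------------------------------------------------
# orientation mixtures


@dataclass(frozen=True)
class MixtureComponent:
    """One axial von Mises component.

    mu : mean orientation in degrees, reduced modulo 180.
    kappa : concentration on the doubled-angle circle; 0 means uniform.
    weight : non-negative mixing weight (normalised across the mixture).
    """

    mu: float
    kappa: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ParameterError(f"kappa must be >= 0, got {self.kappa}")
        if self.weight < 0:
            raise ParameterError(f"weight must be >= 0, got {self.weight}")
        object.__setattr__(self, "mu", float(self.mu) % 180.0)


@dataclass(frozen=True)
class OrientationMixture:
    """Mixture of axial von Mises components over [0, 180) degrees.

    Sampling doubles the angles (so mu and mu + 180 are identical), draws
    from a von Mises on the circle, and halves back. kappa = 0 components
    reduce exactly to the uniform distribution on [0, 180).
    """

    components: tuple[MixtureComponent, ...]

    def __init__(self, components: Sequence[MixtureComponent | tuple]) -> None:
        comps = tuple(
            c if isinstance(c, MixtureComponent) else MixtureComponent(*c)
            for c in components
        )
        if not comps:
            raise ParameterError("mixture needs at least one component")
        total = sum(c.weight for c in comps)
        if total <= 0:
            raise ParameterError("mixture weights sum to zero")
        object.__setattr__(self, "components", comps)

    @property
    def weights(self) -> np.ndarray:
        w = np.array([c.weight for c in self.components], dtype=float)
        return w / w.sum()

    @classmethod
    def uniform(cls) -> "OrientationMixture":
        return cls([MixtureComponent(0.0, 0.0)])

    @classmethod
    def orthogonal(cls, kappa: float, mu: float = 45.0) -> "OrientationMixture":
        """Two equally weighted families 90 degrees apart (cross-hatch).

        The default places the families at 45 and 135 degrees — the
        centers of the two half-ranges of the 0-90/90-180 split — so each
        family is assessed whole by its own range. Families at 0/90 would
        sit exactly on the split boundaries and self-cancel.
        """
        return cls(
            [MixtureComponent(mu, kappa, 0.5), MixtureComponent(mu + 90.0, kappa, 0.5)]
        )


def sample_orientations(
    mixture: OrientationMixture, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` axial orientations (degrees in [0, 180)) from ``mixture``.

    The draw is a von Mises on doubled angles: phi ~ VM(2 mu, kappa), and
    the returned angle is (phi / 2) mod 180. kappa = 0 yields the uniform
    distribution on [0, 180).
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    which = rng.choice(len(mixture.components), size=n, p=mixture.weights)
    out = np.empty(n, dtype=float)
    for idx, comp in enumerate(mixture.components):
        m = which == idx
        k = int(m.sum())
        if k == 0:
            continue
        if comp.kappa == 0.0:
            out[m] = rng.uniform(0.0, 180.0, size=k)
        else:
            phi = rng.vonmises(np.deg2rad(2.0 * comp.mu), comp.kappa, size=k)
            out[m] = np.rad2deg(phi) / 2.0 % 180.0
    return out


# ---------------------------------------------------------------------------
# scenes and rendering


@dataclass(frozen=True)
class FibrilSegment:
    """A straight fibril: center (x, y) px, axial angle deg, length px,
    thickness px, peak amplitude in arbitrary intensity units."""

    x: float
    y: float
    angle_deg: float
    length: float
    thickness: float
    amplitude: float


@dataclass
class FibrilScene:
    """Full description of one synthetic image.

    The rendered image is: anti-aliased additive segments, blurred by a
    Gaussian PSF of ``psf_sigma`` px, plus a flat ``background``, plus
    optional Poisson shot noise and Gaussian read noise of ``noise_sigma``.
    Identical parameters and seed reproduce the image bit-for-bit.
    """

    size: int
    segments: list[FibrilSegment] = field(default_factory=list)
    psf_sigma: float = 1.0
    background: float = 5.0
    noise_sigma: float = 0.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ParameterError(f"image size must be positive, got {self.size}")

    @property
    def angles(self) -> np.ndarray:
        return np.array([s.angle_deg for s in self.segments], dtype=float)


def _draw_segment(canvas: np.ndarray, seg: FibrilSegment) -> None:
    """Accumulate one anti-aliased capsule-profile segment onto ``canvas``."""
    n = canvas.shape[0]
    th = np.deg2rad(seg.angle_deg)
    dx, dy = np.cos(th), -np.sin(th)  # y axis up; row index grows downward
    half = seg.length / 2.0
    x0, y0 = seg.x - half * dx, seg.y - half * dy
    x1, y1 = seg.x + half * dx, seg.y + half * dy
    pad = seg.thickness / 2.0 + 1.5
    c_lo = max(int(np.floor(min(x0, x1) - pad)), 0)
    c_hi = min(int(np.ceil(max(x0, x1) + pad)) + 1, n)
    r_lo = max(int(np.floor(min(y0, y1) - pad)), 0)
    r_hi = min(int(np.ceil(max(y0, y1) + pad)) + 1, n)
    if c_lo >= c_hi or r_lo >= r_hi:
        return
    cols = np.arange(c_lo, c_hi, dtype=float)
    rows = np.arange(r_lo, r_hi, dtype=float)
    px, py = np.meshgrid(cols, rows)
    # distance from each pixel to the segment (projection clamped to [0, L])
    vx, vy = x1 - x0, y1 - y0
    L2 = vx * vx + vy * vy
    if L2 == 0:
        d = np.hypot(px - x0, py - y0)
    else:
        t = np.clip(((px - x0) * vx + (py - y0) * vy) / L2, 0.0, 1.0)
        d = np.hypot(px - (x0 + t * vx), py - (y0 + t * vy))
    profile = np.clip(seg.thickness / 2.0 + 0.5 - d, 0.0, 1.0)
    canvas[r_lo:r_hi, c_lo:c_hi] += seg.amplitude * profile


def render_scene(scene: FibrilScene) -> np.ndarray:
    """Render a scene to a non-negative float64 image.

    Deterministic: the noise stream is derived from ``scene.seed`` alone
    (not from segment content), so two scenes differing only inside a
    sub-region have identical noise fields.
    """
    from scipy.ndimage import gaussian_filter

    img = np.zeros((scene.size, scene.size), dtype=float)
    for seg in scene.segments:
        _draw_segment(img, seg)
    if scene.psf_sigma > 0:
        img = gaussian_filter(img, scene.psf_sigma)
    img += scene.background
    if scene.poisson:
        rng_p = np.random.default_rng([scene.seed, 101])
        img = rng_p.poisson(np.clip(img, 0, None)).astype(float)
    if scene.noise_sigma > 0:
        rng_g = np.random.default_rng([scene.seed, 202])
        img += rng_g.normal(0.0, scene.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, None)


def random_scene(
    size: int,
    n_fibrils: int,
    mixture: OrientationMixture,
    seed: int,
    *,
    length: tuple[float, float] = (60.0, 140.0),
    thickness: float = 2.0,
    amplitude: tuple[float, float] = (40.0, 80.0),
    psf_sigma: float = 1.2,
    background: float = 8.0,
    noise_sigma: float = 3.0,
    poisson: bool = False,
) -> FibrilScene:
    """Build a scene of ``n_fibrils`` segments with uniform random centers
    and mixture-drawn orientations. Returns the scene; ground-truth angles
    are ``scene.angles``."""
    rng = np.random.default_rng([seed, 1])
    angles = sample_orientations(mixture, n_fibrils, np.random.default_rng([seed, 2]))
    xs = rng.uniform(0, size, n_fibrils)
    ys = rng.uniform(0, size, n_fibrils)
    lens = rng.uniform(*length, n_fibrils)
    amps = rng.uniform(*amplitude, n_fibrils)
    segs = [
        FibrilSegment(xs[i], ys[i], angles[i], lens[i], thickness, amps[i])
        for i in range(n_fibrils)
    ]
    return FibrilScene(
        size=size,
        segments=segs,
        psf_sigma=psf_sigma,
        background=background,
        noise_sigma=noise_sigma,
        poisson=poisson,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# developmental series


def developmental_presets(
    *, lattice_mu: float = 45.0
) -> list[tuple[str, OrientationMixture, int]]:
    """Default three-stage series: (label, mixture, fibril count).

    Stage 1 is sparse and isotropic (early wispy deposition), stage 2 a
    loose orthogonal cross-hatch, stage 3 a tight one. The absolute lattice
    orientation is arbitrary; ``lattice_mu`` rotates both families.
    """
    return [
        ("2dpf-like", OrientationMixture.uniform(), 60),
        ("3dpf-like", OrientationMixture.orthogonal(3.0, lattice_mu), 150),
        ("4dpf-like", OrientationMixture.orthogonal(20.0, lattice_mu), 260),
    ]


def make_developmental_series(
    stages: Sequence[tuple[str, OrientationMixture, int]] | None = None,
    *,
    size: int = 512,
    seed: int = 0,
    **scene_kwargs,
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Render one image per stage; returns (label, image, ground-truth angles).

    Stages are independent draws, not a time-evolution model: each stage
    gets its own sub-seeded scene.
    """
    if stages is None:
        stages = developmental_presets()
    if not stages:
        raise ParameterError("need at least one stage")
    out = []
    for i, (label, mixture, count) in enumerate(stages):
        scene = random_scene(size, count, mixture, seed=seed * 1009 + i, **scene_kwargs)
        out.append((label, render_scene(scene), scene.angles))
    return out


# ---------------------------------------------------------------------------
# wound series


@dataclass
class WoundScenario:
    """Orthogonal lattice with a circular wound domain.

    ``outside_mixture``/``outside_count`` describe the unwounded lattice;
    the wound is a disk (center defaults to the image center). Inside-wound
    fibril density is expressed per timepoint as a fraction of the outside
    areal density.
    """

    size: int = 512
    wound_radius: float = 140.0
    wound_center: tuple[float, float] | None = None
    outside_mixture: OrientationMixture = field(
        default_factory=lambda: OrientationMixture.orthogonal(20.0)
    )
    outside_count: int = 260
    scene_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wound_radius <= 0:
            raise ParameterError("wound radius must be positive")
        if self.wound_center is None:
            self.wound_center = (self.size / 2.0, self.size / 2.0)
        cx, cy = self.wound_center
        if not (0 <= cx <= self.size and 0 <= cy <= self.size):
            raise ParameterError("wound center outside image bounds")

    def wound_mask(self) -> np.ndarray:
        yy, xx = np.mgrid[0 : self.size, 0 : self.size]
        cx, cy = self.wound_center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.wound_radius**2


@dataclass
class WoundTimepointResult:
    label: str
    image: np.ndarray
    inside_angles: np.ndarray
    outside_angles: np.ndarray
    wound_mask: np.ndarray


def make_wound_series(
    scenario: WoundScenario,
    timepoints: Sequence[tuple[str, float, OrientationMixture | None]],
    seed: int = 0,
) -> list[WoundTimepointResult]:
    """Render the wound timecourse.

    ``timepoints`` rows are (label, density fraction in [0, 1], inside
    mixture or None for isotropic). The outside-wound fibrils — and the
    noise field — are drawn once from ``seed``, so everything beyond the
    wound margin is pixel-identical across timepoints; only the interior
    refill changes.
    """
    kw = dict(
        length=(60.0, 140.0),
        thickness=2.0,
        amplitude=(40.0, 80.0),
        psf_sigma=1.2,
        background=8.0,
        noise_sigma=3.0,
    )
    kw.update(scenario.scene_kwargs)
    size = scenario.size
    cx, cy = scenario.wound_center
    r = scenario.wound_radius

    for _label, frac, _mix in timepoints:
        if not 0.0 <= frac <= 1.0:
            raise ParameterError(f"density fraction must be in [0,1], got {frac}")

    # outside lattice: reject any segment that could touch the wound disk
    rng = np.random.default_rng([seed, 11])
    ang_rng = np.random.default_rng([seed, 12])
    max_len = kw["length"][1]
    margin = max_len / 2.0 + 3.0 * kw["psf_sigma"]
    max_attempts = 1000 * max(scenario.outside_count, 1)
    attempts = 0
    outside: list[FibrilSegment] = []
    outside_angles: list[float] = []
    while len(outside) < scenario.outside_count:
        attempts += 1
        if attempts > max_attempts:
            raise ParameterError(
                "cannot place outside-wound fibrils: wound radius plus "
                "fibril length leaves (almost) no room in the image; "
                "reduce wound_radius or the fibril length range"
            )
        x, y = rng.uniform(0, size, 2)
        if np.hypot(x - cx, y - cy) <= r + margin:
            continue
        a = float(sample_orientations(scenario.outside_mixture, 1, ang_rng)[0])
        outside.append(
            FibrilSegment(
                x, y, a, rng.uniform(*kw["length"]), kw["thickness"],
                rng.uniform(*kw["amplitude"]),
            )
        )
        outside_angles.append(a)

    # areal density of the outside lattice, fibrils per px^2
    disk_area = np.pi * r * r
    outside_density = scenario.outside_count / (size * size - disk_area)

    results = []
    for t_idx, (label, frac, inside_mixture) in enumerate(timepoints):
        n_inside = int(round(frac * outside_density * disk_area))
        inside_radius = r - max_len / 2.0
        if n_inside > 0 and inside_radius <= 0:
            raise ParameterError(
                "wound radius is smaller than half the maximum fibril "
                "length; no fibril fits inside the wound"
            )
        irng = np.random.default_rng([seed, 20 + t_idx, 1])
        iang = np.random.default_rng([seed, 20 + t_idx, 2])
        mix = inside_mixture or OrientationMixture.uniform()
        inside: list[FibrilSegment] = []
        inside_angles: list[float] = []
        while len(inside) < n_inside:
            x, y = irng.uniform(0, size, 2)
            if np.hypot(x - cx, y - cy) > inside_radius:
                continue
            a = float(sample_orientations(mix, 1, iang)[0])
            inside.append(
                FibrilSegment(
                    x, y, a, irng.uniform(*kw["length"]), kw["thickness"],
                    irng.uniform(*kw["amplitude"]),
                )
            )
            inside_angles.append(a)
        scene = FibrilScene(
            size=size,
            segments=outside + inside,
            psf_sigma=kw["psf_sigma"],
            background=kw["background"],
            noise_sigma=kw["noise_sigma"],
            seed=seed,  # same noise stream at every timepoint
        )
        results.append(
            WoundTimepointResult(
                label=label,
                image=render_scene(scene),
                inside_angles=np.array(inside_angles),
                outside_angles=np.array(outside_angles),
                wound_mask=scenario.wound_mask(),
            )
        )
    return results


def wound_crop(image: np.ndarray, scenario: WoundScenario) -> np.ndarray:
    """Axis-aligned square inscribed in the wound disk.

    Cropping (rather than zero-masking) avoids introducing mask-edge
    energy into the power spectrum.
    """
    cx, cy = scenario.wound_center
    h = scenario.wound_radius / np.sqrt(2.0)
    r0, r1 = int(np.ceil(cy - h)), int(np.floor(cy + h))
    c0, c1 = int(np.ceil(cx - h)), int(np.floor(cx + h))
    return image[r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# on-disk form


def write_scene(
    outdir: str | Path,
    stem: str,
    image: np.ndarray,
    segments: Sequence[FibrilSegment] | np.ndarray,
    params: dict | None = None,
) -> dict[str, Path]:
    """Write image (TIFF), ground truth (CSV) and parameters (JSON).

    ``segments`` may be a list of FibrilSegment (full table written) or a
    bare angle array (angle column only).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": outdir / f"{stem}.tif",
        "csv": outdir / f"{stem}_truth.csv",
        "json": outdir / f"{stem}_params.json",
    }
    tifffile.imwrite(paths["tiff"], image.astype(np.float32))
    if len(segments) and isinstance(segments[0], FibrilSegment):
        table = pd.DataFrame(
            [(s.x, s.y, s.angle_deg, s.length, s.thickness) for s in segments],
            columns=["x", "y", "angle_deg", "length", "thickness"],
        )
    else:
        table = pd.DataFrame({"angle_deg": np.asarray(segments, dtype=float)})
    table.to_csv(paths["csv"], index=False)
    with open(paths["json"], "w") as fh:
        json.dump(params or {}, fh, indent=2, default=str)
    return paths
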