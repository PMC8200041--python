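"""Synthetic two-channel SHG collagen fiber images with known ground truth.

Fibrillar collagen in SHG microscopy appears as bright elongated fibers over a
dark, photon-starved background, recorded simultaneously in a forward and a
weaker backward detection channel.  This module draws fiber centerlines as
correlated random walks whose initial orientation follows an axial von Mises
law, rasterizes them with a Gaussian cross-section, and applies Poisson
photon-counting noise per channel.  The backward channel shares the fiber
geometry but carries an extra fine-scale multiplicative speckle texture and a
smaller photon budget, mimicking the smaller, more disordered features that
direction reveals.

Every generated field comes with a :class:`GroundTruth` record (true fiber
polylines, straightness, coverage, orientation parameters) so that downstream
extraction stages can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .io import Channel, SHGField

#: saturating-response rate of the rendered intensity (counts plateau as
#: fiber density accumulates); chosen so single fibers are flat-topped with a
#: crisp edge while overlap and brightness variation still modulate intensity
_SATURATION = 3.0

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "FiberPath",
    "CLASS_PRESETS",
    "sample_fiber",
    "render_field",
    "generate_dataset",
    "polyline_straightness",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic fiber-field generator.

    Lengths and widths are lognormal: ``length_mu`` / ``width_mu`` are the
    medians in micrometres and ``length_sigma`` / ``width_sigma`` the standard
    deviations of the underlying log.  ``wiggle_sigma`` is the per-step
    tangent-angle jitter (radians per one-pixel arc step) and so controls
    fiber straightness; ``kappa`` is the von Mises concentration of the axial
    fiber orientation about ``theta_mean``.
    """

    n_fibers: int = 40
    theta_mean: float = 0.0
    kappa: float = 1.0
    length_mu: float = 25.0
    length_sigma: float = 0.35
    width_mu: float = 3.0
    width_sigma: float = 0.25
    wiggle_sigma: float = 0.2
    amp_sigma: float = 0.0
    mottle_sigma: float = 0.0
    photon_budget_fwd: float = 150.0
    photon_budget_bwd: float = 40.0
    background: float = 3.0
    fov_um: float = 180.0
    n_px: int = 512
    seed: int = 0

    def validate(self) -> None:
        vals = {
            "kappa": self.kappa,
            "length_mu": self.length_mu,
            "length_sigma": self.length_sigma,
            "width_mu": self.width_mu,
            "width_sigma": self.width_sigma,
            "wiggle_sigma": self.wiggle_sigma,
            "photon_budget_fwd": self.photon_budget_fwd,
            "photon_budget_bwd": self.photon_budget_bwd,
            "background": self.background,
            "amp_sigma": self.amp_sigma,
            "mottle_sigma": self.mottle_sigma,
            "fov_um": self.fov_um,
            "theta_mean": self.theta_mean,
        }
        for name, v in vals.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite generator parameter {name}={v!r}")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.length_mu <= 0 or self.width_mu <= 0:
            raise ValueError("fiber lengths and widths must be > 0")
        if self.wiggle_sigma < 0:
            raise ValueError("wiggle_sigma must be >= 0")
        if self.amp_sigma < 0:
            raise ValueError("amp_sigma must be >= 0")
        if self.mottle_sigma < 0:
            raise ValueError("mottle_sigma must be >= 0")
        if self.n_px <= 0:
            raise ValueError("n_px must be > 0")
        if self.fov_um <= 0:
            raise ValueError("fov_um must be > 0")
        if self.photon_budget_bwd >= self.photon_budget_fwd:
            raise ValueError(
                "photon_budget_bwd must be smaller than photon_budget_fwd "
                "(the backward SHG signal is intrinsically weaker)"
            )

    @property
    def pixel_size_um(self) -> float:
        return self.fov_um / self.n_px


@dataclass(frozen=True)
class FiberPath:
    """A fiber centerline in pixel coordinates with a per-point radius (px)."""

    points: np.ndarray  # (n, 2) rows of (row, col)
    radii: np.ndarray  # (n,)
    theta0: float  # initial tangent angle, radians in [0, pi)
    amplitude: float = 1.0  # relative brightness of this fiber

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def straightness(self) -> float:
        arc = self.arc_length
        if arc == 0:
            return 1.0
        s = self.chord_length / arc
        return 1.0 if s > 1.0 - 1e-12 else s  # exact in the zero-noise limit


def polyline_straightness(points: np.ndarray) -> float:
    """Chord length over arc length of an ordered point path; 1 for a line."""
    points = np.asarray(points, dtype=float)
    arc = float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))
    if arc == 0:
        return 1.0
    return float(np.linalg.norm(points[-1] - points[0])) / arc


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery scoring."""

    fibers: List[FiberPath]
    mean_straightness: float
    coverage: float
    theta_mean: float
    kappa: float
    noiseless_fwd: np.ndarray  # expected forward signal (counts), no background

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")
        if self.fibers and not (0.0 < self.mean_straightness <= 1.0 + 1e-12):
            raise ValueError("mean straightness must lie in (0, 1]")


def _sample_axial_von_mises(
    rng: np.random.Generator, theta_mean: float, kappa: float, size: int | None = None
) -> np.ndarray | float:
    """Axial orientations in [0, pi): von Mises on doubled angles.

    Fiber orientation is an axis, not a direction, so the von Mises law is
    applied to 2*theta and halved back onto the half-circle.
    """
    doubled = rng.vonmises(2.0 * theta_mean, kappa, size=size)
    return np.mod(doubled / 2.0, np.pi)


def sample_fiber(params: GeneratorParams, rng: np.random.Generator) -> FiberPath:
    """Draw one fiber centerline as a correlated random walk.

    The initial tangent follows the axial von Mises law; each subsequent
    one-pixel arc step perturbs the tangent angle by N(0, wiggle_sigma).
    Total arc length is lognormal and the constant per-point radius is half a
    lognormal full width.  ``amp_sigma`` adds lognormal per-fiber brightness
    variability (0 = all fibers equally bright).
    """
    params.validate()
    px = params.pixel_size_um
    length_um = float(rng.lognormal(math.log(params.length_mu), params.length_sigma))
    width_um = float(rng.lognormal(math.log(params.width_mu), params.width_sigma))
    n_steps = max(1, int(round(length_um / px)))
    theta0 = float(_sample_axial_von_mises(rng, params.theta_mean, params.kappa))

    # start anywhere in the field, including near edges (fibers may exit)
    start = rng.uniform(0.0, params.n_px, size=2)
    angles = np.full(n_steps, theta0)
    if params.wiggle_sigma > 0:
        angles = theta0 + np.cumsum(
            np.concatenate([[0.0], rng.normal(0.0, params.wiggle_sigma, n_steps - 1)])
        )
    steps = np.column_stack([np.sin(angles), np.cos(angles)])  # (row, col) steps
    points = np.vstack([start, start + np.cumsum(steps, axis=0)])
    radii = np.full(len(points), width_um / 2.0 / px)
    amp = float(rng.lognormal(0.0, params.amp_sigma)) if params.amp_sigma > 0 else 1.0
    return FiberPath(points=points, radii=radii, theta0=theta0, amplitude=amp)


def _render_fiber(canvas: np.ndarray, fiber: FiberPath) -> None:
    """Additively stamp one fiber's density: Gaussian cross-section, peak ~= 1.

    The cross-section is Gaussian in the true perpendicular distance to the
    centerline, truncated at +-1.5 sigma with sigma = width/3, so the stated
    fiber width spans the rendered support; the saturating detector response
    applied in :func:`render_field` then yields flat-topped fibers whose
    visible width matches the drawn width.
    """
    from scipy.spatial import cKDTree

    n = canvas.shape[0]
    width_px = 2.0 * float(fiber.radii[0])
    sigma = max(width_px / 3.0, 0.35)
    reach = 1.5 * sigma

    # resample the centerline finely so distance-to-points ~ distance-to-curve
    seg = np.diff(fiber.points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = float(seg_len.sum())
    if arc == 0:
        return
    n_samp = max(2, int(math.ceil(arc / 0.25)) + 1)
    t = np.linspace(0.0, arc, n_samp)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pts = np.column_stack(
        [np.interp(t, cum, fiber.points[:, 0]), np.interp(t, cum, fiber.points[:, 1])]
    )

    margin = int(math.ceil(reach)) + 1
    r0 = max(int(math.floor(pts[:, 0].min())) - margin, 0)
    r1 = min(int(math.ceil(pts[:, 0].max())) + margin + 1, n)
    c0 = max(int(math.floor(pts[:, 1].min())) - margin, 0)
    c1 = min(int(math.ceil(pts[:, 1].max())) + margin + 1, n)
    if r0 >= r1 or c0 >= c1:
        return  # entirely outside the field

    rr, cc = np.mgrid[r0:r1, c0:c1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, _ = cKDTree(pts).query(grid, distance_upper_bound=reach)
    inside = np.isfinite(d)
    vals = np.zeros(len(grid))
    vals[inside] = fiber.amplitude * np.exp(-0.5 * (d[inside] / sigma) ** 2)
    canvas[r0:r1, c0:c1] += vals.reshape(rr.shape)


def render_field(
    params: GeneratorParams, rng: np.random.Generator | None = None
) -> Tuple[SHGField, SHGField, GroundTruth]:
    """Render one two-channel field plus its ground truth.

    Fibers composite additively; the forward channel is the rendered intensity
    scaled to ``photon_budget_fwd`` plus background, Poisson sampled.  The
    backward channel shares geometry but is modulated by short-correlation
    multiplicative speckle and scaled to the smaller ``photon_budget_bwd``.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    canvas = np.zeros((params.n_px, params.n_px))
    fibers: List[FiberPath] = []
    for _ in range(params.n_fibers):
        f = sample_fiber(params, rng)
        fibers.append(f)
        _render_fiber(canvas, f)

    # saturating detector-like response: overlaps add in the density field but
    # the emitted intensity plateaus, giving flat-topped fibers with crisp
    # edges as in display-scaled photon-count images
    profile = 1.0 - np.exp(-_SATURATION * canvas)

    # smooth multiplicative mottle: tissue-scale brightness variation shared
    # by both channels; its correlation length (~1/3 of the field) keeps its
    # spectral content below the frequencies the analysis annulus examines
    if params.mottle_sigma > 0:
        field_noise = ndimage.gaussian_filter(
            rng.standard_normal(canvas.shape), params.n_px / 3.0, mode="wrap"
        )
        sd = field_noise.std()
        if sd > 0:
            field_noise = (field_noise - field_noise.mean()) / sd
        mottle = np.exp(params.mottle_sigma * field_noise - 0.5 * params.mottle_sigma**2)
    else:
        mottle = 1.0
    signal_fwd = profile * mottle * params.photon_budget_fwd
    counts_fwd = rng.poisson(signal_fwd + params.background).astype(np.uint16)

    # fine-scale (1-2 px correlation) multiplicative speckle on the backward channel
    speckle = ndimage.gaussian_filter(rng.standard_normal(canvas.shape), 0.75)
    sd = speckle.std()
    if sd > 0:
        speckle /= sd
    modulation = np.clip(1.0 + 0.15 * speckle, 0.0, None)
    signal_bwd = profile * mottle * modulation * params.photon_budget_bwd
    counts_bwd = rng.poisson(signal_bwd + params.background).astype(np.uint16)

    coverage = float(np.mean(signal_fwd > params.background))
    straightness = (
        float(np.mean([f.straightness for f in fibers])) if fibers else 1.0
    )
    truth = GroundTruth(
        fibers=fibers,
        mean_straightness=straightness,
        coverage=coverage,
        theta_mean=params.theta_mean,
        kappa=params.kappa,
        noiseless_fwd=signal_fwd,
    )
    fwd = SHGField(pixels=counts_fwd, channel=Channel.FORWARD, pixel_size_um=params.pixel_size_um)
    bwd = SHGField(pixels=counts_bwd, channel=Channel.BACKWARD, pixel_size_um=params.pixel_size_um)
    return fwd, bwd, truth


# Class presets for the four tissue groups, at crop scale (45 um / 128 px).
# Relative to distal normal, the HGSOC preset is denser, brighter and more
# variable in brightness, more aligned (higher kappa), straighter (lower
# wiggle) and slightly thinner; the p53 and STIC precursor presets sit
# between normal and HGSOC with small offsets (~20% and ~40% of the way).
_CROP = dict(fov_um=45.0, n_px=128, length_mu=25.0, length_sigma=0.35,
             width_sigma=0.25, background=3.0)

CLASS_PRESETS: Dict[str, GeneratorParams] = {
    "distal_normal": GeneratorParams(
        n_fibers=46, kappa=0.6, wiggle_sigma=0.22, width_mu=3.2,
        amp_sigma=0.0, mottle_sigma=0.05,
        photon_budget_fwd=120.0, photon_budget_bwd=35.0, **_CROP,
    ),
    "p53_signature": GeneratorParams(
        n_fibers=60, kappa=1.0, wiggle_sigma=0.19, width_mu=3.05,
        amp_sigma=0.10, mottle_sigma=0.08,
        photon_budget_fwd=145.0, photon_budget_bwd=48.0, **_CROP,
    ),
    "STIC": GeneratorParams(
        n_fibers=75, kappa=1.6, wiggle_sigma=0.16, width_mu=2.9,
        amp_sigma=0.20, mottle_sigma=0.12,
        photon_budget_fwd=175.0, photon_budget_bwd=58.0, **_CROP,
    ),
    "HGSOC": GeneratorParams(
        n_fibers=140, kappa=8.0, wiggle_sigma=0.07, width_mu=2.4,
        amp_sigma=0.45, mottle_sigma=0.22,
        photon_budget_fwd=260.0, photon_budget_bwd=110.0, **_CROP,
    ),
}


def generate_dataset(
    class_presets: Dict[str, GeneratorParams] | None = None,
    n_crops_per_class: int = 30,
    seed: int = 0,
) -> Tuple[List[Tuple[str, SHGField, SHGField]], List[GroundTruth]]:
    """Generate labeled two-channel crops for >= 2 tissue classes.

    Each crop is an independent field at the preset's raster size with its
    mean orientation drawn uniformly (tissue orientation on the slide is
    arbitrary; only the concentration about the mean is class-specific).
    Reproducible bit-for-bit given ``seed``.

    Returns ``(crops, truths)`` where ``crops[i] = (label, fwd, bwd)``.
    """
    if class_presets is None:
        class_presets = CLASS_PRESETS
    if len(class_presets) < 2:
        raise ValueError("need presets for at least 2 classes")
    if n_crops_per_class < 1:
        raise ValueError("n_crops_per_class must be >= 1")

    rng = np.random.default_rng(seed)
    crops: List[Tuple[str, SHGField, SHGField]] = []
    truths: List[GroundTruth] = []
    for label in sorted(class_presets):
        preset = class_presets[label]
        for i in range(n_crops_per_class):
            p = replace(preset, theta_mean=float(rng.uniform(0.0, np.pi)))
            fwd, bwd, truth = render_field(p, rng)
            fwd.stack_id = bwd.stack_id = f"{label}_{i:03d}"
            crops.append((label, fwd, bwd))
            truths.append(truth)
    return crops, truths
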