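"""Synthetic FFA-like phantoms with exact ground truth.

Clinical angiography frames cannot ship with the package, so the test bed
is a seeded renderer that emulates the structures the segmentation model
assumes: bright curvilinear vessels with Gaussian cross-section, bright
near-circular microaneurysm (MA) dots with areas falling both inside and
outside the 5-100 px acceptance band, a smooth low-order illumination
gradient, and additive Gaussian noise. A configurable fraction of MAs is
placed close to a vessel (real MAs sit next to capillaries), but lesions
never overlap a vessel or each other, so every lesion has its own exact
truth component.

Truth masks are geometric, not intensity-thresholded renders: a pixel
belongs to a lesion iff the lesion's Gaussian contribution there exceeds
half its peak contrast, i.e. iff the pixel lies within the lesion's
half-maximum radius. The vessel truth uses the same half-maximum rule on
the vessel profile, and MA truth pixels are carved out of the vessel truth
so the two masks are disjoint.

What the phantom does NOT emulate: dye leakage haloes, the optic disc and
macula, motion blur, vessel-crossing MAs. Results on phantoms demonstrate
the pipeline's mechanics, not clinical-grade performance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi

__all__ = ["PhantomSpec", "LesionRecord", "PhantomOutput", "generate", "generate_suite"]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of a unit-sigma Gaussian


@dataclass
class PhantomSpec:
    """Rendering parameters. Intensities are 8-bit gray levels.

    ``ma_radius_range`` is the half-maximum radius of the rendered dot, so a
    radius range of 1.5-6 px yields truth areas of roughly 7-113 px — some
    lesions deliberately exceed the 100-px area cut. ``vessel_width_range``
    is the full width at half maximum of the vessel profile.
    """

    height: int = 384
    width: int = 384
    n_vessels: int = 4
    vessel_width_range: tuple[float, float] = (3.0, 12.0)
    vessel_contrast: float = 80.0
    n_mas: int = 20
    ma_radius_range: tuple[float, float] = (1.5, 6.0)
    ma_contrast_range: tuple[float, float] = (40.0, 90.0)
    background_level: float = 70.0
    background_gradient_amplitude: float = 20.0
    noise_sigma: float = 5.0
    ma_near_vessel_fraction: float = 0.5
    near_vessel_distance: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("phantom dimensions must be >= 64")
        if min(self.n_vessels, self.n_mas) < 0:
            raise ValueError("structure counts must be >= 0")
        for lo, hi in (
            self.vessel_width_range,
            self.ma_radius_range,
            self.ma_contrast_range,
        ):
            if lo > hi:
                raise ValueError("ranges must be ordered (low, high)")
        if not 0.0 <= self.ma_near_vessel_fraction <= 1.0:
            raise ValueError("ma_near_vessel_fraction must lie in [0, 1]")


@dataclass
class LesionRecord:
    center: tuple[float, float]
    radius: float       # half-maximum radius, px
    contrast: float     # peak intensity above local background
    area: int           # exact truth-mask pixel count
    near_vessel: bool


@dataclass
class PhantomOutput:
    image: np.ndarray          # float64 in [0, 255]
    ma_truth: np.ndarray       # bool
    vessel_truth: np.ndarray   # bool, disjoint from ma_truth
    manifest: list[LesionRecord]
    n_placement_failures: int
    spec: PhantomSpec


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial illumination field."""
    y, x = np.mgrid[0 : spec.height, 0 : spec.width]
    xn = 2.0 * x / (spec.width - 1) - 1.0
    yn = 2.0 * y / (spec.height - 1) - 1.0
    coef = rng.uniform(-1.0, 1.0, size=5)
    surf = (
        coef[0] * xn
        + coef[1] * yn
        + coef[2] * xn * yn
        + coef[3] * xn * xn
        + coef[4] * yn * yn
    )
    span = surf.max() - surf.min()
    if span > 0:
        surf = (surf - surf.min()) / span - 0.5
    return spec.background_level + spec.background_gradient_amplitude * surf


def _vessel_centerline(
    spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random-walk path across the frame; returns (n, 2) row/col."""
    h, w = spec.height, spec.width
    side = rng.integers(0, 4)
    if side == 0:
        pos = np.array([0.0, rng.uniform(0, w - 1)])
        heading = rng.uniform(np.pi / 4, 3 * np.pi / 4)       # downward
    elif side == 1:
        pos = np.array([h - 1.0, rng.uniform(0, w - 1)])
        heading = rng.uniform(-3 * np.pi / 4, -np.pi / 4)     # upward
    elif side == 2:
        pos = np.array([rng.uniform(0, h - 1), 0.0])
        heading = rng.uniform(-np.pi / 4, np.pi / 4)          # rightward
    else:
        pos = np.array([rng.uniform(0, h - 1), w - 1.0])
        heading = rng.uniform(3 * np.pi / 4, 5 * np.pi / 4)   # leftward
    pts = [pos.copy()]
    max_len = 2 * (h + w)
    for _ in range(max_len):
        heading += rng.normal(0.0, 0.06)  # curvature bound
        pos = pos + np.array([np.sin(heading), np.cos(heading)])
        if not (0 <= pos[0] < h and 0 <= pos[1] < w):
            break
        pts.append(pos.copy())
    return np.array(pts)


def _rasterize_centerline(path: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    idx = np.rint(path).astype(int)
    idx[:, 0] = np.clip(idx[:, 0], 0, shape[0] - 1)
    idx[:, 1] = np.clip(idx[:, 1], 0, shape[1] - 1)
    canvas[idx[:, 0], idx[:, 1]] = True
    return canvas


def generate(spec: PhantomSpec | None = None) -> PhantomOutput:
    """Render one phantom; byte-identical output for identical specs."""
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = _background(spec, rng)

    # --- vessels -----------------------------------------------------------
    vessel_truth = np.zeros((h, w), dtype=bool)
    vessel_dist = np.full((h, w), np.inf)  # distance to nearest centerline
    max_halfwidth = 0.0
    for _ in range(spec.n_vessels):
        path = _vessel_centerline(spec, rng)
        if len(path) < 10:
            continue
        width_fwhm = rng.uniform(*spec.vessel_width_range)
        sigma = width_fwhm / _FWHM
        center = _rasterize_centerline(path, (h, w))
        d = ndi.distance_transform_edt(~center)
        img += spec.vessel_contrast * np.exp(-(d * d) / (2.0 * sigma * sigma))
        vessel_truth |= d <= width_fwhm / 2.0
        vessel_dist = np.minimum(vessel_dist, d)
        max_halfwidth = max(max_halfwidth, width_fwhm / 2.0)

    # --- microaneurysm dots ------------------------------------------------
    yy, xx = np.mgrid[0:h, 0:w]
    manifest: list[LesionRecord] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    failures = 0
    n_near_target = int(round(spec.ma_near_vessel_fraction * spec.n_mas))
    margin = 8  # keep lesion centers away from the frame edge

    for k in range(spec.n_mas):
        want_near = k < n_near_target
        r = rng.uniform(*spec.ma_radius_range)
        contrast = rng.uniform(*spec.ma_contrast_range)
        ok = False
        for _ in range(300):
            row = rng.uniform(margin, h - 1 - margin)
            col = rng.uniform(margin, w - 1 - margin)
            dv = vessel_dist[int(round(row)), int(round(col))]
            clearance = r + max_halfwidth + 2.0
            if np.isfinite(dv):
                if want_near and not (clearance <= dv <= spec.near_vessel_distance):
                    continue
                if not want_near and dv <= max(clearance, spec.near_vessel_distance):
                    continue
            if any(
                np.hypot(row - pr, col - pc) < r + prad + 2.0
                for pr, pc, prad in placed
            ):
                continue
            ok = True
            break
        if not ok:
            failures += 1
            continue
        sigma = r / np.sqrt(2.0 * np.log(2.0))  # half max exactly at radius r
        d2 = (yy - row) ** 2 + (xx - col) ** 2
        img += contrast * np.exp(-d2 / (2.0 * sigma * sigma))
        footprint = d2 <= r * r
        area = int(footprint.sum())
        if area == 0:  # cannot happen for r >= 1, defensive
            failures += 1
            continue
        placed.append((row, col, r))
        manifest.append(
            LesionRecord(
                center=(row, col),
                radius=r,
                contrast=contrast,
                area=area,
                near_vessel=bool(np.isfinite(dv) and dv <= spec.near_vessel_distance),
            )
        )

    ma_truth = np.zeros((h, w), dtype=bool)
    for rec in manifest:
        d2 = (yy - rec.center[0]) ** 2 + (xx - rec.center[1]) ** 2
        ma_truth |= d2 <= rec.radius**2
    vessel_truth &= ~ma_truth  # truth masks are disjoint

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=(h, w))
    np.clip(img, 0.0, 255.0, out=img)

    return PhantomOutput(
        image=img,
        ma_truth=ma_truth,
        vessel_truth=vessel_truth,
        manifest=manifest,
        n_placement_failures=failures,
        spec=spec,
    )


def generate_suite(
    base_spec: PhantomSpec | None = None,
    contrasts: tuple[float, ...] = (30.0, 55.0, 80.0),
    noise_sigmas: tuple[float, ...] = (2.0, 5.0, 8.0),
) -> list[PhantomOutput]:
    """Deterministic family over a contrast x noise grid.

    Phantom (i, j) uses MA contrasts centered on ``contrasts[i]`` (+/- 10)
    and noise level ``noise_sigmas[j]``; its seed is derived from the base
    seed so each grid cell has a distinct but reproducible layout.
    """
    base = base_spec or PhantomSpec()
    outputs = []
    for i, c in enumerate(contrasts):
        for j, ns in enumerate(noise_sigmas):
            spec = PhantomSpec(
                **{
                    **asdict(base),
                    "ma_contrast_range": (max(5.0, c - 10.0), c + 10.0),
                    "noise_sigma": ns,
                    "seed": (base.seed * 1000 + i * len(noise_sigmas) + j + 1)
                    % (2**31 - 1),
                }
            )
            outputs.append(generate(spec))
    return outputs
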