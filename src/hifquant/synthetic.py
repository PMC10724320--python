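"""Ground-truthed synthetic inputs for the whole pipeline.

Emulates AEC-stained conjunctival epithelium: hematoxylin-counterstained
nuclei carrying red-brown chromogen granules of 1.2–2.2 µm, goblet cells
(granule-free, faintly tinted, no counterstained nucleus), and a pale
background — imaged as a small focal stack in which every granule is sharp
in exactly one plane and Gaussian-blurred elsewhere.  Vessel photographs
with a known vessel-pixel fraction are generated for the density pipeline.

Every draw is deterministic given (seed, specimen_index), and each field
carries a full ground-truth record, so detection, classification and the
group statistics can all be validated against known answers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage as ndi
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .fusion import FocalStack
from .granules import (
    Granule,
    GranuleSizeThresholds,
    SizeClass,
    classify_granule_size,
    classify_nucleus_pattern,
    pattern_to_category,
)

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "GranuleTruth",
    "NucleusTruth",
    "FieldTruth",
    "VesselTruth",
    "CohortEntry",
    "hif1a_cohort_spec",
    "hif2a_cohort_spec",
    "sample_positivity",
    "sample_field_truth",
    "render_stack",
    "generate_specimen_stack",
    "generate_cohort",
    "generate_vessel_image",
    "write_cohort",
    "load_truth",
]

# Rendering palette (RGB, uint8 scale).  Chosen so the counterstain is
# blue-dominant, the chromogen red-dominant, and the faint cytoplasmic /
# goblet tint stays below the granule redness threshold.
BACKGROUND_RGB = np.array([235.0, 232.0, 228.0])
NUCLEUS_RGB = np.array([115.0, 105.0, 170.0])
GRANULE_RGB = np.array([165.0, 70.0, 50.0])
GOBLET_RGB = np.array([228.0, 216.0, 210.0])

DEFOCUS_SIGMA_PER_PLANE = 2.0  # px of Gaussian blur per plane of defocus


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm: label, size, and its positivity distribution."""

    label: str
    n_specimens: int
    mean_positivity: float  # percent, mean of the truncated law
    dispersion: float  # percent, scale of the underlying normal


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one marker's cohort."""

    groups: tuple[GroupSpec, ...]
    marker: str = "HIF1a"
    nuclei_per_field: tuple[int, int] = (22, 32)
    granule_diameter_small: tuple[float, float] = (1.2, 1.6)
    granule_diameter_large: tuple[float, float] = (1.6, 2.2)
    few_max: int = 4
    goblet_fraction: float = 0.1
    um_per_pixel: float = 0.25
    n_planes: int = 3
    noise_sd: float = 2.0
    field_shape: tuple[int, int] = (384, 384)
    nucleus_radius_um: tuple[float, float] = (3.8, 5.0)
    goblet_radius_um: tuple[float, float] = (4.0, 6.0)
    seed: int = 0

    def validate(self) -> None:
        for g in self.groups:
            if not 0.0 <= g.mean_positivity <= 100.0:
                raise ValueError(f"group {g.label!r}: mean positivity must be in [0, 100]")
            if g.dispersion < 0:
                raise ValueError(f"group {g.label!r}: dispersion must be nonnegative")
            if g.n_specimens < 0:
                raise ValueError(f"group {g.label!r}: negative specimen count")
        for iv in (self.granule_diameter_small, self.granule_diameter_large):
            if not iv[0] < iv[1]:
                raise ValueError("diameter intervals must be nonempty")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        if not 0.0 <= self.goblet_fraction <= 1.0:
            raise ValueError("goblet_fraction must be in [0, 1]")
        if self.nuclei_per_field[0] < 1 or self.nuclei_per_field[0] > self.nuclei_per_field[1]:
            raise ValueError("nuclei_per_field must be a nonempty count range")
        # largest granule must fit inside the smallest nucleus with margin,
        # and must span at least ~3 px at the given calibration
        if self.granule_diameter_large[1] >= 2 * self.nucleus_radius_um[0] - 1.0:
            raise ValueError("granule diameter interval exceeds the nucleus size")
        if self.granule_diameter_small[0] / self.um_per_pixel < 3.0:
            raise ValueError(
                "granules are unresolvable at this calibration (< 3 px across)"
            )

    @property
    def n_specimens(self) -> int:
        return sum(g.n_specimens for g in self.groups)

    def group_of(self, specimen_index: int) -> GroupSpec:
        if not 0 <= specimen_index < self.n_specimens:
            raise IndexError("specimen_index out of range")
        cum = 0
        for g in self.groups:
            cum += g.n_specimens
            if specimen_index < cum:
                return g
        raise AssertionError("unreachable")

    @property
    def thresholds(self) -> GranuleSizeThresholds:
        return GranuleSizeThresholds(
            small_min=self.granule_diameter_small[0],
            small_max=self.granule_diameter_small[1],
            large_max=self.granule_diameter_large[1],
        )


def hif1a_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Default HIF1a cohort: 55 primary / 6 recurrent / 20 control, group
    positivity means (11, 18, 46)% with dispersions (20, 36, 30)%."""
    spec = CohortSpec(
        groups=(
            GroupSpec("primary", 55, 11.0, 20.0),
            GroupSpec("recurrent", 6, 18.0, 36.0),
            GroupSpec("control", 20, 46.0, 30.0),
        ),
        marker="HIF1a",
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def hif2a_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Default HIF2a cohort: 84 primary / 28 recurrent / 20 control, group
    positivity means (38, 21, 66)% with dispersions (31, 27, 31)%."""
    spec = CohortSpec(
        groups=(
            GroupSpec("primary", 84, 38.0, 31.0),
            GroupSpec("recurrent", 28, 21.0, 27.0),
            GroupSpec("control", 20, 66.0, 31.0),
        ),
        marker="HIF2a",
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# Positivity sampling: mean-matched truncated normal on [0, 100]
# ---------------------------------------------------------------------------

_LOC_CACHE: dict[tuple[float, float], float] = {}


def _truncnorm_location(target_mean: float, sd: float) -> float:
    """Location parameter whose [0, 100]-truncated normal has the target mean.

    Plain truncation shifts the mean (a normal centered at 11 with sd 20
    truncated to [0, 100] averages ~21), so the location is solved
    numerically to keep the requested group mean exact.
    """
    key = (round(target_mean, 6), round(sd, 6))
    if key in _LOC_CACHE:
        return _LOC_CACHE[key]

    def gap(mu: float) -> float:
        a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    loc = brentq(gap, -20.0 * sd, 100.0 + 20.0 * sd, xtol=1e-10)
    _LOC_CACHE[key] = loc
    return loc


def sample_positivity(rng: np.random.Generator, mean: float, dispersion: float) -> float:
    """Draw one per-specimen true positivity percentage in [0, 100]."""
    if not 0.0 <= mean <= 100.0:
        raise ValueError("mean must be in [0, 100]")
    if dispersion == 0.0 or mean in (0.0, 100.0):
        return float(mean)
    loc = _truncnorm_location(mean, dispersion)
    a, b = (0.0 - loc) / dispersion, (100.0 - loc) / dispersion
    return float(truncnorm.rvs(a, b, loc=loc, scale=dispersion, random_state=rng))


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class GranuleTruth:
    center_px: tuple[float, float]  # (row, col)
    diameter_um: float
    plane: int  # focal plane in which the granule is sharp


@dataclass
class NucleusTruth:
    center_px: tuple[float, float]
    radius_um: float
    goblet: bool
    granules: list[GranuleTruth] = field(default_factory=list)
    pattern: int | None = None
    category: int | None = None

    def mask(self, shape: tuple[int, int], um_per_pixel: float) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        r_px = self.radius_um / um_per_pixel
        return (rr - self.center_px[0]) ** 2 + (cc - self.center_px[1]) ** 2 <= r_px**2

    def granule_list(self, thresholds: GranuleSizeThresholds) -> list[Granule]:
        """True granules as `Granule` records (for classifier validation)."""
        out = []
        for g in self.granules:
            out.append(
                Granule(
                    center=g.center_px,
                    area_px=0,
                    equivalent_diameter_um=g.diameter_um,
                    size_class=classify_granule_size(g.diameter_um, thresholds),
                )
            )
        return out


@dataclass
class FieldTruth:
    nuclei: list[NucleusTruth]
    target_positivity: float  # percent drawn from the group law
    positivity: float  # realized percent: positive / non-goblet * 100

    @property
    def n_non_goblet(self) -> int:
        return sum(1 for n in self.nuclei if not n.goblet)

    @property
    def n_goblet(self) -> int:
        return sum(1 for n in self.nuclei if n.goblet)


@dataclass
class VesselTruth:
    mask: np.ndarray = field(repr=False)
    roi: np.ndarray = field(repr=False)
    fraction: float


@dataclass
class CohortEntry:
    specimen_id: str
    group: str
    marker: str
    stack: FocalStack
    truth: FieldTruth


# ---------------------------------------------------------------------------
# Field sampling
# ---------------------------------------------------------------------------


def _sample_pattern_counts(
    rng: np.random.Generator, positive: bool, few_max: int
) -> tuple[int, int, int]:
    """Draw (pattern, n_small, n_large) for one nucleus."""
    if positive:
        pattern = int(rng.choice([2, 3, 4]))
    else:
        pattern = int(rng.choice([5, 1]))
    if pattern == 5:
        return 5, 0, 0
    if pattern == 1:
        return 1, int(rng.integers(1, few_max + 1)), 0
    if pattern == 2:
        return 2, int(rng.integers(few_max + 1, few_max + 5)), 0
    if pattern == 3:
        return 3, 0, int(rng.integers(1, few_max + 1))
    return 4, 0, int(rng.integers(few_max + 1, few_max + 4))


def _place_granules(
    rng: np.random.Generator,
    radius_um: float,
    diameters: list[float],
    edge_margin_um: float = 0.4,
    gap_um: float = 0.6,
) -> tuple[float, list[tuple[float, float, float]]]:
    """Place non-merging granules inside a nucleus, growing it if needed.

    Returns (final radius µm, list of (dy µm, dx µm, diameter µm)).
    Largest granules are placed first; if a configuration cannot be packed
    the nucleus radius grows by 8% and placement restarts.
    """
    r = radius_um
    order = sorted(diameters, reverse=True)
    for _ in range(25):
        placed: list[tuple[float, float, float]] = []
        ok = True
        for d in order:
            rmax = r - d / 2.0 - edge_margin_um
            if rmax <= 0:
                ok = False
                break
            success = False
            for _ in range(400):
                u = rng.random()
                theta = rng.uniform(0.0, 2.0 * np.pi)
                rad = rmax * np.sqrt(u)
                dy, dx = rad * np.sin(theta), rad * np.cos(theta)
                if all(
                    np.hypot(dy - py, dx - px) >= (d + pd) / 2.0 + gap_um
                    for py, px, pd in placed
                ):
                    placed.append((dy, dx, d))
                    success = True
                    break
            if not success:
                ok = False
                break
        if ok:
            return r, placed
        r *= 1.08
    raise RuntimeError("could not pack granules into nucleus")  # pragma: no cover


def sample_field_truth(
    spec: CohortSpec, rng: np.random.Generator, target_positivity: float
) -> FieldTruth:
    """Draw the layout and classification truth of one epithelial field.

    Each non-goblet nucleus is positive with probability equal to the
    specimen's target positivity; the recorded per-specimen positivity is
    the *realized* fraction, so the bookkeeping invariant
    positivity == 100 * n_positive / n_non_goblet holds exactly.
    """
    H, W = spec.field_shape
    upp = spec.um_per_pixel
    n_nuclei = int(rng.integers(spec.nuclei_per_field[0], spec.nuclei_per_field[1] + 1))
    p = target_positivity / 100.0
    s_lo, s_hi = spec.granule_diameter_small
    l_lo, l_hi = spec.granule_diameter_large
    l_lo = np.nextafter(l_lo, l_hi)  # the large interval is open at its left end

    nuclei: list[NucleusTruth] = []
    for i in range(n_nuclei):
        goblet = bool(rng.random() < spec.goblet_fraction)
        if goblet and i == 0:
            goblet = False  # guarantee at least one counted nucleus
        if goblet:
            radius = float(rng.uniform(*spec.goblet_radius_um))
            granule_offsets: list[tuple[float, float, float]] = []
            pattern = category = None
        else:
            radius = float(rng.uniform(*spec.nucleus_radius_um))
            positive = bool(rng.random() < p)
            pattern, n_small, n_large = _sample_pattern_counts(rng, positive, spec.few_max)
            diams = [float(rng.uniform(s_lo, s_hi)) for _ in range(n_small)]
            diams += [float(rng.uniform(l_lo, l_hi)) for _ in range(n_large)]
            radius, granule_offsets = _place_granules(rng, radius, diams)
            category = pattern_to_category(pattern)

        # place the nucleus in the field, away from others and the border
        r_px = radius / upp
        placed = False
        for _ in range(600):
            cy = rng.uniform(r_px + 3.0, H - r_px - 3.0)
            cx = rng.uniform(r_px + 3.0, W - r_px - 3.0)
            if all(
                np.hypot(cy - n.center_px[0], cx - n.center_px[1])
                >= r_px + n.radius_um / upp + 0.8 / upp
                for n in nuclei
            ):
                placed = True
                break
        if not placed:
            continue  # field full; truth reflects what is rendered

        granules = [
            GranuleTruth(
                center_px=(cy + dy / upp, cx + dx / upp),
                diameter_um=d,
                plane=int(rng.integers(0, spec.n_planes)),
            )
            for dy, dx, d in granule_offsets
        ]
        nuclei.append(
            NucleusTruth(
                center_px=(cy, cx),
                radius_um=radius,
                goblet=goblet,
                granules=granules,
                pattern=pattern,
                category=category,
            )
        )

    counted = [n for n in nuclei if not n.goblet]
    n_positive = sum(1 for n in counted if n.category in (2, 3, 4))
    realized = 100.0 * n_positive / len(counted)
    return FieldTruth(nuclei=nuclei, target_positivity=target_positivity, positivity=realized)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _disk_coverage(shape: tuple[int, int], center: tuple[float, float], r_px: float) -> np.ndarray:
    """Anti-aliased disk: per-pixel coverage ramp of width one pixel."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    return np.clip(r_px + 0.5 - dist, 0.0, 1.0)


def _paint(canvas: np.ndarray, alpha: np.ndarray, color: np.ndarray) -> None:
    canvas *= (1.0 - alpha)[..., None]
    canvas += alpha[..., None] * color


def render_stack(
    truth: FieldTruth, spec: CohortSpec, rng: np.random.Generator
) -> FocalStack:
    """Render a field-truth layout into an n-plane RGB focal stack.

    Nuclei and background are identical across planes; each granule is
    drawn sharp in its own plane and blurred with sigma proportional to the
    plane distance elsewhere, giving focus stacking a real signal.
    """
    H, W = spec.field_shape
    upp = spec.um_per_pixel
    base = np.empty((H, W, 3), dtype=np.float64)
    base[:] = BACKGROUND_RGB

    for nuc in truth.nuclei:
        r_px = nuc.radius_um / upp
        color = GOBLET_RGB if nuc.goblet else NUCLEUS_RGB + rng.uniform(-6.0, 6.0, size=3)
        cy, cx = nuc.center_px
        pad = int(np.ceil(r_px)) + 2
        y0, y1 = max(0, int(cy) - pad), min(H, int(cy) + pad + 1)
        x0, x1 = max(0, int(cx) - pad), min(W, int(cx) + pad + 1)
        cov = _disk_coverage((y1 - y0, x1 - x0), (cy - y0, cx - x0), r_px)
        _paint(base[y0:y1, x0:x1], cov, color)

    planes = []
    sigma_max = DEFOCUS_SIGMA_PER_PLANE * max(1, spec.n_planes - 1)
    for plane_idx in range(spec.n_planes):
        alpha = np.zeros((H, W), dtype=np.float64)
        for nuc in truth.nuclei:
            for g in nuc.granules:
                r_px = g.diameter_um / 2.0 / upp
                pad = int(np.ceil(r_px + 4.0 * sigma_max)) + 2
                cy, cx = g.center_px
                y0, y1 = max(0, int(cy) - pad), min(H, int(cy) + pad + 1)
                x0, x1 = max(0, int(cx) - pad), min(W, int(cx) + pad + 1)
                cov = _disk_coverage((y1 - y0, x1 - x0), (cy - y0, cx - x0), r_px)
                sigma = DEFOCUS_SIGMA_PER_PLANE * abs(plane_idx - g.plane)
                if sigma > 0:
                    cov = ndi.gaussian_filter(cov, sigma)
                alpha[y0:y1, x0:x1] = np.maximum(alpha[y0:y1, x0:x1], cov)
        img = base.copy()
        _paint(img, np.clip(alpha, 0.0, 1.0), GRANULE_RGB)
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        planes.append(np.clip(img, 0.0, 255.0).astype(np.uint8))

    return FocalStack(planes=np.stack(planes), um_per_pixel=upp)


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def _specimen_rng(spec: CohortSpec, specimen_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, specimen_index]))


def generate_specimen_stack(
    spec: CohortSpec, specimen_index: int
) -> tuple[FocalStack, FieldTruth]:
    """Generate one specimen's focal stack and its ground truth.

    Deterministic given (spec.seed, specimen_index); the specimen's group
    is determined by its index within the concatenated group ranges.
    """
    spec.validate()
    group = spec.group_of(specimen_index)
    rng = _specimen_rng(spec, specimen_index)
    target = sample_positivity(rng, group.mean_positivity, group.dispersion)
    truth = sample_field_truth(spec, rng, target)
    stack = render_stack(truth, spec, rng)
    return stack, truth


def generate_cohort_truths(spec: CohortSpec) -> list[tuple[str, FieldTruth]]:
    """Cohort truth channel only — no rendering.

    Draws the same per-specimen positivity and field layout as
    `generate_cohort` (identical per-specimen rng streams up to rendering)
    but skips image synthesis; used for fast statistical simulations.
    """
    spec.validate()
    out = []
    idx = 0
    for g in spec.groups:
        for _ in range(g.n_specimens):
            rng = _specimen_rng(spec, idx)
            target = sample_positivity(rng, g.mean_positivity, g.dispersion)
            out.append((g.label, sample_field_truth(spec, rng, target)))
            idx += 1
    return out


def generate_cohort(spec: CohortSpec) -> list[CohortEntry]:
    """Generate every specimen of a cohort, in group order."""
    spec.validate()
    entries = []
    idx = 0
    for g in spec.groups:
        for _ in range(g.n_specimens):
            stack, truth = generate_specimen_stack(spec, idx)
            entries.append(
                CohortEntry(
                    specimen_id=f"S{idx:03d}",
                    group=g.label,
                    marker=spec.marker,
                    stack=stack,
                    truth=truth,
                )
            )
            idx += 1
    return entries


# ---------------------------------------------------------------------------
# Vessel photographs
# ---------------------------------------------------------------------------

VESSEL_RGB = np.array([165.0, 45.0, 50.0])
VESSEL_BG_RGB = np.array([236.0, 228.0, 222.0])


def _default_roi(height: int, width: int) -> np.ndarray:
    rr, cc = np.mgrid[:height, :width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    return ((rr - cy) / (0.42 * height)) ** 2 + ((cc - cx) / (0.42 * width)) ** 2 <= 1.0


def generate_vessel_image(
    width: int,
    height: int,
    target_fraction: float,
    seed: int,
    roi_mask: np.ndarray | None = None,
    stroke_width_px: float = 3.0,
    noise_sd: float = 2.0,
) -> tuple[np.ndarray, VesselTruth]:
    """Red curvilinear vessel strokes on a pale background.

    Strokes (smooth random walks of width ``stroke_width_px``) are added
    until the vessel-mask fraction within the ROI reaches the target; each
    stroke adds ~1% so the realized fraction lands within ±2 percentage
    points of the target, else an explicit error is raised.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    roi = _default_roi(height, width) if roi_mask is None else np.asarray(roi_mask, dtype=bool)
    if roi.shape != (height, width):
        raise ValueError("roi_mask shape must be (height, width)")
    roi_area = int(roi.sum())
    if roi_area == 0:
        raise ValueError("ROI is empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))

    mask = np.zeros((height, width), dtype=bool)
    rr_idx, cc_idx = np.nonzero(roi)
    half_w = stroke_width_px / 2.0
    max_strokes = 800

    def fraction() -> float:
        return float((mask & roi).sum()) / roi_area

    n_strokes = 0
    while fraction() < target_fraction:
        if n_strokes >= max_strokes:
            raise ValueError(
                f"target_fraction {target_fraction} unreachable with "
                f"stroke width {stroke_width_px} inside this ROI"
            )
        k = int(rng.integers(0, roi_area))
        y, x = float(rr_idx[k]), float(cc_idx[k])
        heading = rng.uniform(0.0, 2.0 * np.pi)
        length = int(rng.integers(80, 240))
        for _ in range(length):
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < height and 0 <= ix < width):
                break
            y0, y1 = max(0, iy - 3), min(height, iy + 4)
            x0, x1 = max(0, ix - 3), min(width, ix + 4)
            gy, gx = np.mgrid[y0:y1, x0:x1]
            mask[y0:y1, x0:x1] |= np.hypot(gy - y, gx - x) <= half_w
            heading += rng.normal(0.0, 0.15)
            y += 1.5 * np.sin(heading)
            x += 1.5 * np.cos(heading)
        n_strokes += 1

    realized = fraction()
    if abs(realized - target_fraction) > 0.02:
        raise ValueError(
            f"realized fraction {realized:.3f} misses target {target_fraction} by > 0.02"
        )

    canvas = np.empty((height, width, 3), dtype=np.float64)
    canvas[:] = VESSEL_BG_RGB
    alpha = np.clip(ndi.gaussian_filter(mask.astype(np.float64), 0.7) * 1.3, 0.0, 1.0)
    _paint(canvas, alpha, VESSEL_RGB)
    canvas += rng.normal(0.0, noise_sd, size=canvas.shape)
    image = np.clip(canvas, 0.0, 255.0).astype(np.uint8)
    return image, VesselTruth(mask=mask, roi=roi, fraction=realized)


# ---------------------------------------------------------------------------
# Persistence: TIFF stacks, JSON truth sidecars, CSV manifest
# ---------------------------------------------------------------------------


def _truth_to_json(truth: FieldTruth) -> dict:
    return {
        "target_positivity": truth.target_positivity,
        "positivity": truth.positivity,
        "nuclei": [
            {
                "center_px": list(n.center_px),
                "radius_um": n.radius_um,
                "goblet": n.goblet,
                "pattern": n.pattern,
                "category": n.category,
                "granules": [asdict(g) for g in n.granules],
            }
            for n in truth.nuclei
        ],
    }


def load_truth(path) -> FieldTruth:
    with open(path) as fh:
        d = json.load(fh)
    nuclei = [
        NucleusTruth(
            center_px=tuple(n["center_px"]),
            radius_um=n["radius_um"],
            goblet=n["goblet"],
            pattern=n["pattern"],
            category=n["category"],
            granules=[
                GranuleTruth(
                    center_px=tuple(g["center_px"]),
                    diameter_um=g["diameter_um"],
                    plane=g["plane"],
                )
                for g in n["granules"]
            ],
        )
        for n in d["nuclei"]
    ]
    return FieldTruth(
        nuclei=nuclei, target_positivity=d["target_positivity"], positivity=d["positivity"]
    )


def write_cohort(entries: list[CohortEntry], outdir) -> "object":
    """Write stacks as multi-page TIFF + JSON truth sidecars + manifest CSV.

    Returns the manifest path.  Manifest columns: specimen_id, group,
    marker, image, truth.
    """
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in entries:
        img_path = outdir / f"{e.specimen_id}.tif"
        truth_path = outdir / f"{e.specimen_id}.json"
        tifffile.imwrite(str(img_path), e.stack.planes)
        with open(truth_path, "w") as fh:
            json.dump(_truth_to_json(e.truth), fh)
        rows.append(
            {
                "specimen_id": e.specimen_id,
                "group": e.group,
                "marker": e.marker,
                "image": img_path.name,
                "truth": truth_path.name,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
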