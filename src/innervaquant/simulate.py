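"""Synthetic wound-section fluorescence images with known ground truth.

Each generated section emulates a transverse skin-wound section mounted on
glass: a horizontal tissue band (epidermis over dermis) flanked above and
below by empty glass, divided laterally into five stripes —
outer edge 1 | wound bed | wound center | wound bed | outer edge 2.
Nerve fibers are curvilinear bright polylines drawn by a persistent-direction
random walk; non-specific signal is modelled as a diffuse tissue background
with a low-frequency illumination gradient, sparse autofluorescent speckle of
intermediate intensity, and additive Gaussian noise.

The programmed fiber fraction per (region, layer) cell is achieved *exactly*
in the ground-truth mask (strokes are trimmed to the target pixel count), so
downstream density measurements can be validated against known truth.

Geometry follows the healing biology: sections from days 3 and 7 carry no
epidermis over the wound bed and wound center (re-epithelialization has not
yet covered them), while edges, day-10+, and uninjured sections do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError, ValidationError
from .imgio import LAYER_NAMES, REGION_NAMES, MarkerImage, RegionLabelSet

__all__ = [
    "SyntheticSpec",
    "SyntheticSection",
    "generate_section",
    "generate_time_course",
    "paired_patches",
    "day_cells",
    "DEFAULT_DAY_FRACTIONS",
    "UNINJURED_FRACTION",
]

VALID_DAYS = (0, 3, 7, 10, 15)

#: Whole-wound fiber-fraction trend over the healing time course
#: (day -> target positive-pixel fraction within tissue).
DEFAULT_DAY_FRACTIONS: dict[int, float] = {3: 0.02, 7: 0.045, 10: 0.18, 15: 0.6}

#: Fraction used for the uninjured (day-0) condition in demo runs. Real
#: uninjured skin is close to saturation; 0.75 is the densest mat of
#: curvilinear strokes the generator can lay down with a comfortable margin
#: below its 0.9 feasibility ceiling.
UNINJURED_FRACTION = 0.75

# Tissue band occupies the central 28% of the frame height; the epidermis is
# the top 15% of the tissue band. Keeping tissue a minority of the frame
# mirrors real section scans (mostly glass) and keeps fiber pixels a minority
# of the whole-image intensity distribution even at day-15 densities.
_TISSUE_TOP = 0.36
_TISSUE_BOTTOM = 0.64
_EPIDERMIS_FRAC = 0.15

# Lateral stripes as (region label, width fraction); labels 1/2/3/4 are
# wound bed / outer edge 1 / wound center / outer edge 2.
_STRIPES = ((2, 0.15), (1, 0.20), (3, 0.30), (1, 0.20), (4, 0.15))

_MAX_CELL_FRACTION = 0.9
_TURN_SD_DEG = 20.0

# Stamp offsets for stroke widths 1..3 px.
_WIDTH_OFFSETS = {
    1: np.array([[0, 0]]),
    2: np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
    3: np.array([[dr, dc] for dr in (-1, 0, 1) for dc in (-1, 0, 1)]),
}
_WIDTH_CHOICES = np.array([1, 2, 3])
_WIDTH_PROBS = np.array([0.2, 0.4, 0.4])  # mostly 2-3 px: fine-caliber fibers


@dataclass
class SyntheticSpec:
    """Full parameterization of one generated section.

    ``fiber_fraction`` maps (region name, layer name) to the target fraction
    of that cell's pixels covered by fibers. Intensities are on the [0, 1]
    scale of the marker channel.
    """

    height: int = 384
    width: int = 512
    day_label: int = 0
    fiber_fraction: Mapping[tuple[str, str], float] = field(default_factory=dict)
    fiber_intensity_range: tuple[float, float] = (0.55, 0.95)
    background_level: float = 0.16
    background_gradient_amp: float = 0.01
    speckle_density: float = 0.005
    noise_sigma: float = 0.05
    seed: int = 0
    pixel_size_um: float = 1.0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValidationError("section must be at least 8x8 pixels")
        if self.day_label not in VALID_DAYS:
            raise ValidationError(
                f"day_label must be one of {VALID_DAYS}, got {self.day_label}"
            )
        low, high = self.fiber_intensity_range
        if not (0.0 < low <= high <= 1.0):
            raise ValidationError("fiber_intensity_range must satisfy 0 < low <= high <= 1")
        if not 0.0 <= self.background_level < 1.0:
            raise ValidationError("background_level must lie in [0, 1)")
        if self.background_gradient_amp < 0 or self.speckle_density < 0:
            raise ValidationError("gradient amplitude and speckle density must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        # separability margin: a noise-free image must be cleanly thresholdable
        if low <= self.background_level + self.background_gradient_amp:
            raise ValidationError(
                "fiber intensity low must exceed background_level + gradient amplitude"
            )
        for cell, frac in self.fiber_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"fiber fraction for {cell} outside [0, 1]")


@dataclass
class SyntheticSection:
    """A generated section: image, label masks, ground truth, and its spec."""

    image: MarkerImage
    labels: RegionLabelSet
    truth_mask: np.ndarray
    spec: SyntheticSpec
    sample_id: str = ""

    def achieved_fraction(self, region: str, layer: str) -> float:
        cell = _cell_mask(self.labels, region, layer)
        area = int(cell.sum())
        if area == 0:
            raise ValidationError(f"cell ({region}, {layer}) has zero area")
        return float(self.truth_mask[cell].sum()) / area


def section_geometry(height: int, width: int, day_label: int) -> tuple[np.ndarray, np.ndarray]:
    """Build the region and layer masks for a section of the given day.

    Region stripes span the full frame height (as an annotator would draw
    lateral boundaries); the layer mask carries 0 outside the tissue band.
    """
    region = np.zeros((height, width), dtype=np.int64)
    layer = np.zeros((height, width), dtype=np.int64)
    r0 = int(round(_TISSUE_TOP * height))
    r1 = int(round(_TISSUE_BOTTOM * height))
    re = r0 + max(1, int(round(_EPIDERMIS_FRAC * (r1 - r0))))

    c = 0
    edges = []
    for label, frac in _STRIPES:
        c_next = min(width, c + int(round(frac * width)))
        edges.append((label, c, c_next))
        c = c_next
    # absorb rounding slack into the last stripe
    if edges[-1][2] != width:
        label, c0, _ = edges[-1]
        edges[-1] = (label, c0, width)

    for label, c0, c1 in edges:
        region[:, c0:c1] = label
        # wound bed and center lack epidermis before day 10 (not yet
        # re-epithelialized); edges and uninjured skin always carry it
        has_epidermis = label in (2, 4) or day_label == 0 or day_label >= 10
        if has_epidermis:
            layer[r0:re, c0:c1] = 1
        layer[re:r1, c0:c1] = 2
    return region, layer


def day_cells(day_label: int) -> list[tuple[str, str]]:
    """(region, layer) cells that exist in a section of the given day."""
    region_mask, layer_mask = section_geometry(64, 64, day_label)
    cells = []
    for r in np.unique(region_mask):
        if r == 0:
            continue
        for l in (1, 2):
            if np.any((region_mask == r) & (layer_mask == l)):
                cells.append((REGION_NAMES[int(r)], LAYER_NAMES[l]))
    return cells


def _cell_mask(labels: RegionLabelSet, region: str, layer: str) -> np.ndarray:
    region_label = labels.region_label_for(region)
    sel = labels.region_mask == region_label
    if layer == "whole":
        return sel & (labels.layer_mask > 0)
    layer_label = {v: k for k, v in labels.layer_names.items()}[layer]
    return sel & (labels.layer_mask == layer_label)


def _stroke_pixels(
    rng: np.random.Generator,
    start: tuple[int, int],
    length: int,
    width: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterized pixels of one persistent-direction random-walk stroke.

    Returns an (n, 2) array of unique (row, col) pixels in path order, so a
    caller can trim the stroke from its tail end.
    """
    theta = rng.uniform(0.0, 2.0 * math.pi)
    turns = rng.normal(0.0, math.radians(_TURN_SD_DEG), size=length)
    angles = theta + np.cumsum(turns)
    steps = np.stack([np.sin(angles), np.cos(angles)], axis=1)
    path = np.asarray(start, dtype=float) + np.cumsum(steps, axis=0)
    px = np.round(path).astype(np.int64)
    stamped = (px[:, None, :] + _WIDTH_OFFSETS[width][None, :, :]).reshape(-1, 2)
    inside = (
        (stamped[:, 0] >= 0)
        & (stamped[:, 0] < shape[0])
        & (stamped[:, 1] >= 0)
        & (stamped[:, 1] < shape[1])
    )
    stamped = stamped[inside]
    if stamped.size == 0:
        return stamped.reshape(0, 2)
    flat = stamped[:, 0] * shape[1] + stamped[:, 1]
    _, first = np.unique(flat, return_index=True)
    return stamped[np.sort(first)]


def _fill_cell(
    rng: np.random.Generator,
    cell: np.ndarray,
    target: int,
    truth: np.ndarray,
) -> None:
    """Draw strokes inside ``cell`` until exactly ``target`` truth pixels are set."""
    if target == 0:
        return
    rows, cols = np.nonzero(cell)
    placed = 0
    barren_streak = 0
    shape = truth.shape
    while placed < target:
        i = rng.integers(0, rows.size)
        width = int(rng.choice(_WIDTH_CHOICES, p=_WIDTH_PROBS))
        length = int(rng.integers(30, 121))
        stroke = _stroke_pixels(rng, (int(rows[i]), int(cols[i])), length, width, shape)
        if stroke.shape[0]:
            keep = cell[stroke[:, 0], stroke[:, 1]] & ~truth[stroke[:, 0], stroke[:, 1]]
            stroke = stroke[keep]
        if stroke.shape[0] == 0:
            barren_streak += 1
            if barren_streak > 500:
                raise GenerationError(
                    "cannot reach requested fiber fraction; cell saturated"
                )
            continue
        barren_streak = 0
        if placed + stroke.shape[0] > target:
            stroke = stroke[: target - placed]
        truth[stroke[:, 0], stroke[:, 1]] = True
        placed += stroke.shape[0]


def generate_section(spec: SyntheticSpec, sample_id: str = "") -> SyntheticSection:
    """Render one synthetic section; deterministic for a fixed spec/seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    region_mask, layer_mask = section_geometry(h, w, spec.day_label)
    labels = RegionLabelSet(region_mask=region_mask, layer_mask=layer_mask)

    truth = np.zeros((h, w), dtype=bool)
    layer_by_name = {v: k for k, v in LAYER_NAMES.items()}
    for (region, layer), frac in sorted(spec.fiber_fraction.items()):
        if frac == 0.0:
            continue
        if frac > _MAX_CELL_FRACTION:
            raise GenerationError(
                f"fiber fraction {frac} for ({region}, {layer}) exceeds the "
                f"feasible stroke coverage {_MAX_CELL_FRACTION}"
            )
        region_label = labels.region_label_for(region)
        cell = (region_mask == region_label) & (layer_mask == layer_by_name[layer])
        area = int(cell.sum())
        if area == 0:
            continue  # cell absent at this day (e.g. epidermis before day 10)
        _fill_cell(rng, cell, int(round(frac * area)), truth)

    # The whole tissue band fluoresces, including the scab/granulation surface
    # over a not-yet-re-epithelialized wound (layer label 0 there): background
    # autofluorescence does not respect the annotation layers.
    band = np.zeros((h, w), dtype=bool)
    band[int(round(_TISSUE_TOP * h)) : int(round(_TISSUE_BOTTOM * h)), :] = True
    tissue = band
    img = np.zeros((h, w), dtype=np.float64)
    img[tissue] = spec.background_level
    # smooth illumination gradient over the whole frame
    phase_r, phase_c = rng.uniform(0.0, 2.0 * math.pi, size=2)
    rr = np.arange(h)[:, None] / h
    cc = np.arange(w)[None, :] / w
    img += spec.background_gradient_amp * 0.5 * (
        np.sin(2.0 * math.pi * cc + phase_c) + np.sin(2.0 * math.pi * rr + phase_r)
    )
    img = np.clip(img, 0.0, 1.0)

    low, high = spec.fiber_intensity_range
    if spec.speckle_density > 0:
        # autofluorescent debris: 2x2 blobs of intermediate intensity (large
        # enough to survive a 3x3 median filter, as real debris does)
        candidates = np.flatnonzero(tissue & ~truth)
        n_blobs = min(
            int(round(spec.speckle_density * tissue.sum() / 4.0)), candidates.size
        )
        if n_blobs:
            chosen = rng.choice(candidates, size=n_blobs, replace=False)
            levels = rng.uniform(spec.background_level, low, size=n_blobs)
            rows0, cols0 = np.unravel_index(chosen, img.shape)
            for dr in (0, 1):
                for dc in (0, 1):
                    rr2 = np.minimum(rows0 + dr, h - 1)
                    cc2 = np.minimum(cols0 + dc, w - 1)
                    keep = ~truth[rr2, cc2]
                    img[rr2[keep], cc2[keep]] = levels[keep]

    n_fiber = int(truth.sum())
    if n_fiber:
        img[truth] = rng.uniform(low, high, size=n_fiber)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    image = MarkerImage(
        pixels=img,
        source_path=f"synthetic://day{spec.day_label}/seed{spec.seed}",
        channel_name="red",
        pixel_size_um=spec.pixel_size_um,
        bit_depth_origin=16,
    )
    section = SyntheticSection(
        image=image, labels=labels, truth_mask=truth, spec=spec, sample_id=sample_id
    )
    # ground-truth consistency: achieved fraction per cell within +-0.005
    for (region, layer), frac in spec.fiber_fraction.items():
        cell = _cell_mask(labels, region, layer)
        if cell.sum() == 0:
            continue
        achieved = float(truth[cell].sum()) / float(cell.sum())
        # 0.005 absolute, widened only by integer-count granularity in tiny cells
        tol = max(0.005, 1.0 / float(cell.sum()))
        if abs(achieved - frac) > tol:
            raise GenerationError(
                f"achieved fraction {achieved:.4f} for ({region}, {layer}) "
                f"misses target {frac:.4f}"
            )
    return section


def _child_seed(master: int, day: int, replicate: int) -> int:
    """Deterministic per-replicate seed; adding days never reshuffles others."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(day, replicate))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def generate_time_course(
    base_spec: SyntheticSpec,
    day_fractions: Mapping[int, float] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[SyntheticSection]:
    """Generate ``n_replicates`` sections per day with jittered fractions.

    Replicate fiber fractions jitter uniformly within +-8% relative of the
    day's programmed value, emulating animal-to-animal variability while
    staying inside the 10% band the downstream tests assume.
    """
    if day_fractions is None:
        day_fractions = DEFAULT_DAY_FRACTIONS
    if not day_fractions:
        raise ValidationError("day_fractions must not be empty")
    unknown = set(day_fractions) - set(VALID_DAYS)
    if unknown:
        raise ValidationError(f"unknown days {sorted(unknown)}; valid: {VALID_DAYS}")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")

    sections = []
    for day in sorted(day_fractions):
        base_frac = day_fractions[day]
        for rep in range(n_replicates):
            child = _child_seed(seed, day, rep)
            jitter = 1.0 + np.random.default_rng(child).uniform(-0.08, 0.08)
            frac = min(base_frac * jitter, _MAX_CELL_FRACTION)
            fractions = {cell: frac for cell in day_cells(day)}
            spec = replace(
                base_spec, day_label=day, fiber_fraction=fractions, seed=child
            )
            sections.append(generate_section(spec, sample_id=f"d{day:02d}r{rep}"))
    return sections


def paired_patches(
    spec: SyntheticSpec,
    patch_size: int,
    n: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample (clean, noisy) training patches from a noise-free render.

    The clean patch is the noise-free section (fibers, background, gradient
    and speckle); the noisy patch adds Gaussian noise at ``spec.noise_sigma``
    and clips to [0, 1]. Patches are drawn so they overlap the tissue band.
    """
    if patch_size > min(spec.height, spec.width):
        raise ValidationError("patch_size exceeds section dimensions")
    if n < 1:
        raise ValidationError("n must be >= 1")
    clean_spec = replace(spec, noise_sigma=0.0)
    section = generate_section(clean_spec)
    clean_img = section.image.pixels

    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(97,)))
    r_top = int(round(_TISSUE_TOP * spec.height))
    r_bot = int(round(_TISSUE_BOTTOM * spec.height))
    lo = max(0, r_top - patch_size // 2)
    hi = min(spec.height - patch_size, max(lo, r_bot - patch_size // 2))
    pairs = []
    for _ in range(n):
        r = int(rng.integers(lo, hi + 1))
        c = int(rng.integers(0, spec.width - patch_size + 1))
        clean = clean_img[r : r + patch_size, c : c + patch_size].copy()
        noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
        pairs.append((clean, np.clip(noisy, 0.0, 1.0)))
    return pairs
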