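"""Whole-section readouts: positive-area fraction and high-power-field counts.

Mirrors how a pathologist scores a section: the fraction of (tissue) area
occupied by marker-positive zones, and the number of immunoreactive cells
counted over a handful of nonoverlapping high-power fields placed over the
section.  Fields are square, sized in micrometres (default 350 um, the
diameter of a typical x400 high-power field), and placed either at random
(seeded, rejection-sampled) or on a regular grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PackingError, ValidationError
from .zones import ZoneMap

DEFAULT_FIELD_SIZE_UM = 350.0
DEFAULT_N_FIELDS = 5
_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class FieldGrid:
    """Nonoverlapping square sampling fields inside one raster.

    ``offsets`` are (row, col) top-left pixel corners; each field spans the
    half-open square ``[r, r + size_px) x [c, c + size_px)``.
    """

    field_size_um: float
    field_size_px: int
    n_fields: int
    offsets: list[tuple[int, int]]
    rng_seed: int | None


@dataclass(frozen=True)
class FieldCount:
    per_field_counts: list[int]
    mean_count: float
    sd_count: float


def area_fraction(zones: ZoneMap, tissue_mask: np.ndarray | None = None) -> float:
    """Marker-positive area fraction: zone support / tissue area.

    With no ``tissue_mask`` the whole raster counts as tissue.
    """
    support = zones.support
    if tissue_mask is None:
        return float(support.mean())
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != support.shape:
        raise ValidationError("tissue_mask shape does not match zones")
    n_tissue = int(tissue_mask.sum())
    if n_tissue == 0:
        raise ValidationError("tissue mask is empty")
    return float((support & tissue_mask).sum()) / n_tissue


def _grid_capacity(shape: tuple[int, int], size_px: int) -> int:
    return (shape[0] // size_px) * (shape[1] // size_px)


def place_fields(
    image_shape: tuple[int, int],
    field_size_um: float = DEFAULT_FIELD_SIZE_UM,
    pixel_size_um: float = 1.0,
    n_fields: int = DEFAULT_N_FIELDS,
    seed: int | None = 0,
    mode: str = "random",
) -> FieldGrid:
    """Place ``n_fields`` nonoverlapping square fields inside the raster.

    ``mode="random"`` rejection-samples top-left corners (deterministic
    given ``seed``); ``mode="grid"`` fills a regular raster-scan grid.
    Raises :class:`PackingError`, naming the feasible maximum, when the
    requested count cannot fit.
    """
    if n_fields < 1:
        raise ValidationError("n_fields must be >= 1")
    size_px = int(round(field_size_um / pixel_size_um))
    if size_px < 1 or size_px > min(image_shape):
        raise ValidationError(
            f"field of {field_size_um} um = {size_px} px does not fit in {image_shape}"
        )
    capacity = _grid_capacity(image_shape, size_px)
    if n_fields > capacity:
        raise PackingError(
            f"cannot place {n_fields} nonoverlapping fields of {size_px} px "
            f"in {image_shape}; at most {capacity} fit",
            max_feasible=capacity,
        )
    max_r = image_shape[0] - size_px
    max_c = image_shape[1] - size_px

    if mode == "grid":
        offsets = []
        for r in range(0, image_shape[0] - size_px + 1, size_px):
            for c in range(0, image_shape[1] - size_px + 1, size_px):
                offsets.append((r, c))
                if len(offsets) == n_fields:
                    return FieldGrid(field_size_um, size_px, n_fields, offsets, seed)
        raise PackingError("grid placement failed", max_feasible=len(offsets))
    if mode != "random":
        raise ValidationError(f"unknown placement mode {mode!r}")

    rng = np.random.default_rng(seed)
    offsets = []
    for _ in range(_MAX_ATTEMPTS):
        r = int(rng.integers(0, max_r + 1))
        c = int(rng.integers(0, max_c + 1))
        if all(
            abs(r - r2) >= size_px or abs(c - c2) >= size_px for r2, c2 in offsets
        ):
            offsets.append((r, c))
            if len(offsets) == n_fields:
                return FieldGrid(field_size_um, size_px, n_fields, offsets, seed)
    # random packing stalled; regular grid is the feasibility certificate
    return place_fields(
        image_shape, field_size_um, pixel_size_um, n_fields, seed, mode="grid"
    )


def count_cells_per_field(zones: ZoneMap, grid: FieldGrid) -> FieldCount:
    """Count zones per field by centroid membership.

    A zone belongs to the (single) field whose half-open square contains
    its centroid, so no cell is ever counted twice.
    """
    shape = zones.labels.shape
    for r, c in grid.offsets:
        if r < 0 or c < 0 or r + grid.field_size_px > shape[0] or c + grid.field_size_px > shape[1]:
            raise ValidationError("field grid extends outside the zone raster")
    counts = [0] * grid.n_fields
    s = grid.field_size_px
    for zone in zones.zones:
        cr, cc = zone.centroid_rc
        for i, (r, c) in enumerate(grid.offsets):
            if r <= cr < r + s and c <= cc < c + s:
                counts[i] += 1
                break
    arr = np.asarray(counts, dtype=float)
    return FieldCount(
        per_field_counts=counts,
        mean_count=float(arr.mean()),
        sd_count=float(arr.std(ddof=1)) if grid.n_fields > 1 else 0.0,
    )
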