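"""Seeded synthetic data: two-channel IF scenes with ground truth, group
measurement tables, and CFSE cytotoxicity event tables.

The scene generator emulates a double-marker immunofluorescence
microphotograph of two cell populations — e.g. CD8+ effectors (channel A)
and NPMc+ target cells (channel B).  Cells are disks with radii drawn from
a Gaussian, placed in physical (micrometre) coordinates; a controllable
fraction of B cells is planted touching an A cell (membrane apposition
with a small overlap) and the rest are kept well clear of every A cell.
The rendered intensities are blurred by a Gaussian point-spread function,
offset by a constant background and corrupted by Poisson shot noise plus
Gaussian read noise.  Ground-truth label masks, the planted contact pairs
and the true overlap area accompany every scene, so detection, contact
scoring and field counting can all be validated against known truth.

The zoom factor changes only the sampling density (pixels per micrometre),
never the physical scene — exactly what re-acquiring the same section at a
different magnification would do.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import PackingError, ValidationError
from .image import MultichannelImage, write_image
from .stats import GroupTable, LysisResult, specific_lysis

CHANNEL_A = "CD8"
CHANNEL_B = "NPM"

_MAX_PLACE_ATTEMPTS = 2000


@dataclass(frozen=True)
class SceneParams:
    """Generator settings; the defaults describe a sparse x400 field.

    ``image_size_px`` and ``pixel_size_um`` refer to zoom factor 1; the
    physical field of view is their product.  ``cell_radius_um`` is
    (mean, SD) of the disk radius.  ``target_contact_fraction`` is the
    fraction of B cells planted touching an A cell; contacting pairs
    overlap by ``contact_overlap_um`` along the center line, and
    non-contacting B cells stay at least ``clearance_um`` from every A
    boundary.  SNR is defined as (peak - background) / noise SD at the
    background.
    """

    image_size_px: int = 256
    pixel_size_um: float = 0.5
    n_cells_A: int = 12
    n_cells_B: int = 12
    cell_radius_um: tuple[float, float] = (3.5, 0.3)
    target_contact_fraction: float = 0.3
    peak_intensity: tuple[float, float] = (150.0, 150.0)
    background_level: float = 10.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    psf_sigma_um: float = 0.5
    zoom_factor: float = 1.0
    seed: int = 0
    contact_overlap_um: float = 1.0
    clearance_um: float = 5.0
    min_separation_um: float = 3.0

    def __post_init__(self):
        if not (0.0 <= self.target_contact_fraction <= 1.0):
            raise ValidationError("target_contact_fraction must lie in [0, 1]")
        for name in ("image_size_px", "pixel_size_um", "zoom_factor",
                     "background_level", "psf_sigma_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.cell_radius_um[0] <= 0:
            raise ValidationError("mean cell radius must be positive")

    @property
    def extent_um(self) -> float:
        return self.image_size_px * self.pixel_size_um

    @property
    def snr(self) -> float:
        noise_var = self.gaussian_noise_sd ** 2
        if self.poisson_noise:
            noise_var += self.background_level
        peak = min(self.peak_intensity)
        return (peak - self.background_level) / max(np.sqrt(noise_var), 1e-12)


@dataclass
class SyntheticScene:
    """A rendered scene plus its ground truth."""

    image: MultichannelImage
    truth_masks: dict[str, np.ndarray]
    true_pairs: list[tuple[int, int]]
    realized_contact_fraction: float
    true_overlap_area_um2: float
    centers_um: dict[str, np.ndarray]  # (n, 3): row_um, col_um, radius_um
    params: SceneParams

    @property
    def true_coverage_fraction(self) -> dict[str, float]:
        return {
            name: float((mask > 0).mean()) for name, mask in self.truth_masks.items()
        }


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    extent: float,
    existing: list[tuple[float, float, float]],
    min_gap: float,
    what: str,
) -> list[tuple[float, float, float]]:
    """Uniform placement with a minimum boundary gap to ``existing`` disks."""
    placed: list[tuple[float, float, float]] = []
    for i in range(n):
        r = radii[i]
        for _ in range(_MAX_PLACE_ATTEMPTS):
            y = rng.uniform(r, extent - r)
            x = rng.uniform(r, extent - r)
            ok = all(
                np.hypot(y - y2, x - x2) >= r + r2 + min_gap
                for y2, x2, r2 in existing + placed
            )
            if ok:
                placed.append((y, x, r))
                break
        else:
            raise PackingError(
                f"could not place {what} disk {i + 1}/{n}; scene too crowded",
                max_feasible=len(placed),
            )
    return placed


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one two-channel scene; pure function of (params, seed)."""
    extent = params.extent_um
    mean_r, sd_r = params.cell_radius_um
    total_cells = params.n_cells_A + params.n_cells_B
    if total_cells * np.pi * (mean_r + 2 * sd_r) ** 2 > 0.4 * extent ** 2:
        raise PackingError("total cell area exceeds 40% of the frame")

    rng = np.random.default_rng(params.seed)
    radii_a = np.clip(rng.normal(mean_r, sd_r, params.n_cells_A), 0.5 * mean_r, None)
    radii_b = np.clip(rng.normal(mean_r, sd_r, params.n_cells_B), 0.5 * mean_r, None)

    cells_a = _place_disks(
        rng, params.n_cells_A, radii_a, extent, [],
        params.min_separation_um, "channel-A",
    )

    n_contact = int(round(params.target_contact_fraction * params.n_cells_B))
    cells_b: list[tuple[float, float, float]] = []
    true_pairs: list[tuple[int, int]] = []

    # contacting B cells: apposed to a random A cell with a small overlap
    for i in range(n_contact):
        r = radii_b[i]
        for _ in range(_MAX_PLACE_ATTEMPTS):
            a_idx = int(rng.integers(0, params.n_cells_A))
            ya, xa, ra = cells_a[a_idx]
            theta = rng.uniform(0, 2 * np.pi)
            d = ra + r - params.contact_overlap_um
            y, x = ya + d * np.sin(theta), xa + d * np.cos(theta)
            if not (r <= y <= extent - r and r <= x <= extent - r):
                continue
            # clear of every other A cell and of already-placed B cells
            ok = all(
                np.hypot(y - y2, x - x2) >= r + r2 + params.clearance_um
                for j, (y2, x2, r2) in enumerate(cells_a) if j != a_idx
            ) and all(
                np.hypot(y - y2, x - x2) >= r + r2 + params.min_separation_um
                for y2, x2, r2 in cells_b
            )
            if ok:
                cells_b.append((y, x, r))
                true_pairs.append((a_idx + 1, i + 1))
                break
        else:
            raise PackingError(
                f"could not place contacting B cell {i + 1}/{n_contact}",
                max_feasible=len(cells_b),
            )

    # remaining B cells: well clear of every A cell
    free = _place_disks(
        rng, params.n_cells_B - n_contact,
        radii_b[n_contact:], extent,
        [(y, x, r + params.clearance_um - params.min_separation_um)
         for y, x, r in cells_a] + cells_b,
        params.min_separation_um, "channel-B",
    )
    cells_b.extend(free)

    # rasterize at the effective sampling density
    eff_px = params.pixel_size_um / params.zoom_factor
    size = int(round(params.image_size_px * params.zoom_factor))
    yy = (np.arange(size) + 0.5) * eff_px
    labels = {}
    clean = {}
    for name, cells, peak in (
        (CHANNEL_A, cells_a, params.peak_intensity[0]),
        (CHANNEL_B, cells_b, params.peak_intensity[1]),
    ):
        lab = np.zeros((size, size), dtype=np.int32)
        img = np.zeros((size, size), dtype=np.float64)
        for cid, (y, x, r) in enumerate(cells, start=1):
            r0 = max(int((y - r) / eff_px) - 1, 0)
            r1 = min(int((y + r) / eff_px) + 2, size)
            c0 = max(int((x - r) / eff_px) - 1, 0)
            c1 = min(int((x + r) / eff_px) + 2, size)
            dy = yy[r0:r1, None] - y
            dx = yy[None, c0:c1] - x
            disk = dy ** 2 + dx ** 2 <= r ** 2
            lab[r0:r1, c0:c1][disk] = cid
            img[r0:r1, c0:c1][disk] = peak
        labels[name] = lab
        clean[name] = gaussian_filter(img, params.psf_sigma_um / eff_px)

    channels = {}
    for name in (CHANNEL_A, CHANNEL_B):
        img = clean[name] + params.background_level
        if params.poisson_noise:
            img = rng.poisson(img).astype(np.float64)
        img = img + rng.normal(0.0, params.gaussian_noise_sd, img.shape)
        channels[name] = np.clip(img, 0.0, None)

    overlap_px = int(((labels[CHANNEL_A] > 0) & (labels[CHANNEL_B] > 0)).sum())
    image = MultichannelImage(channels, eff_px, name=f"scene_seed{params.seed}")
    return SyntheticScene(
        image=image,
        truth_masks=labels,
        true_pairs=true_pairs,
        realized_contact_fraction=(
            len(true_pairs) / params.n_cells_B if params.n_cells_B else 0.0
        ),
        true_overlap_area_um2=overlap_px * eff_px ** 2,
        centers_um={
            CHANNEL_A: np.array(cells_a, dtype=float).reshape(-1, 3),
            CHANNEL_B: np.array(cells_b, dtype=float).reshape(-1, 3),
        },
        params=params,
    )


def generate_group_tables(
    n_per_group: int,
    group_means: list[float],
    group_sd: float,
    seed: int | None = 0,
    group_names: list[str] | None = None,
) -> GroupTable:
    """Gaussian per-animal measurements, one block per group."""
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if group_sd <= 0:
        raise ValidationError("group_sd must be > 0")
    if len(group_means) < 2:
        raise ValidationError("need >= 2 groups")
    if group_names is None:
        defaults = ["untreated", "WT-NET/DC", "NPMc+-NET/DC"]
        group_names = [
            defaults[i] if i < len(defaults) else f"group{i + 1}"
            for i in range(len(group_means))
        ]
    rng = np.random.default_rng(seed)
    rows = []
    animal = 1
    for name, mu in zip(group_names, group_means):
        for value in rng.normal(mu, group_sd, n_per_group):
            rows.append({"animal": f"m{animal:03d}", "group": name, "value": value})
            animal += 1
    return GroupTable(pd.DataFrame(rows))


def generate_cfse_events(
    n_events: int = 10_000,
    frac_hi: float = 0.5,
    kill_fraction_hi: float = 0.0,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, LysisResult]:
    """Simulate a CFSE hi/low in-vivo cytotoxicity readout.

    ``n_events`` target cells are injected as a ``frac_hi`` : (1-frac_hi)
    mix of CFSE-high (peptide-pulsed) and CFSE-low populations with
    log-normal dye intensities; a ``kill_fraction_hi`` share of the high
    population is eliminated before recovery.  Returns the recovered
    per-event intensities and the lysis value implied by the recovered
    hi/low percentages.
    """
    if n_events < 1000:
        raise ValidationError("n_events must be >= 1000")
    for name, value in (("frac_hi", frac_hi), ("kill_fraction_hi", kill_fraction_hi)):
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name}={value} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_hi = int(rng.binomial(n_events, frac_hi))
    n_low = n_events - n_hi
    n_hi_kept = int(rng.binomial(n_hi, 1.0 - kill_fraction_hi))
    # 10x dye-dose separation on a log scale
    hi = rng.lognormal(mean=np.log(1e4), sigma=0.3, size=n_hi_kept)
    low = rng.lognormal(mean=np.log(1e3), sigma=0.3, size=n_low)
    events = pd.DataFrame({
        "cfse_intensity": np.concatenate([hi, low]),
        "population": ["hi"] * n_hi_kept + ["low"] * n_low,
    })
    total = len(events)
    if n_hi_kept == 0:
        truth = LysisResult(0.0, 100.0 * n_low / total, 0.0)
    else:
        truth = specific_lysis(100.0 * n_hi_kept / total, 100.0 * n_low / total)
    return events, truth


def classify_cfse_events(events: pd.DataFrame, cutoff: float | None = None):
    """Gate recovered events into hi/low and return the lysis result.

    The default cutoff is the geometric midpoint of the two dye doses.
    """
    intensities = events["cfse_intensity"].to_numpy(dtype=float)
    if cutoff is None:
        cutoff = float(np.sqrt(1e4 * 1e3))
    n_hi = int((intensities > cutoff).sum())
    n_low = intensities.size - n_hi
    if n_low == 0:
        raise ValidationError("no CFSE-low events recovered; cannot normalize")
    total = intensities.size
    if n_hi == 0:
        return LysisResult(0.0, 100.0 * n_low / total, 0.0)
    return specific_lysis(100.0 * n_hi / total, 100.0 * n_low / total)


# ---------------------------------------------------------------------------
# scene serialization: 16-bit TIFF + JSON sidecar with RLE masks

def _rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask).ravel(order="C")
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    return {
        "shape": list(mask.shape),
        "values": flat[starts].tolist(),
        "lengths": lengths.tolist(),
    }


def _rle_decode(payload: dict) -> np.ndarray:
    values = np.asarray(payload["values"], dtype=np.int32)
    lengths = np.asarray(payload["lengths"], dtype=np.int64)
    return np.repeat(values, lengths).reshape(payload["shape"])


def write_scene(scene: SyntheticScene, out_dir: str | Path, stem: str | None = None):
    """Write the scene as a 2-page 16-bit TIFF plus a ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or scene.image.name
    tiff_path = out_dir / f"{stem}.tiff"
    write_image(tiff_path, scene.image)
    sidecar = {
        "channels": list(scene.image.channels),
        "pixel_size_um": scene.image.pixel_size_um,
        "params": asdict(scene.params),
        "true_pairs": [list(p) for p in scene.true_pairs],
        "realized_contact_fraction": scene.realized_contact_fraction,
        "true_overlap_area_um2": scene.true_overlap_area_um2,
        "snr": scene.params.snr,
        "truth_masks": {k: _rle_encode(v) for k, v in scene.truth_masks.items()},
    }
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh)
    return tiff_path


def read_scene_truth(json_path: str | Path) -> dict:
    """Load a ground-truth sidecar; masks are decoded back to rasters."""
    with open(json_path) as fh:
        payload = json.load(fh)
    payload["truth_masks"] = {
        k: _rle_decode(v) for k, v in payload["truth_masks"].items()
    }
    return payload
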