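"""Synthetic virtual nodule tissues.

The real digitized nodule sections behind the tissue model are not publicly
deposited, so this module regenerates tissues with their statistical
structure: an elongated lobe with a contiguous meristematic cap at the apex,
and a cortex in which large hypertrophied infected cells (each carrying a
Frankia compartment) are interspersed among small uninfected cells.

All layouts are built on an integer pixel grid (cells are pixel tiles), so
digitization through :func:`nodusim.tissue.import_label_map` round-trips
exactly and generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .tissue import Tissue, TissueError, import_label_map

logger = logging.getLogger(__name__)


@dataclass
class NoduleGenSpec:
    """Parameters of the synthetic nodule-lobe generator.

    ``infected_fraction_of_cortex`` is the fraction of cortical *cells*
    (not area) that are infected; ``infected_size_ratio`` is the
    infected/uninfected cell-area ratio (infected cells are hypertrophied).
    """

    n_cells_target: int = 200
    meristem_fraction: float = 0.10
    infected_fraction_of_cortex: float = 0.35
    infected_size_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_target < 10:
            raise ValueError("n_cells_target must be at least 10")
        for name in ("meristem_fraction", "infected_fraction_of_cortex"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.infected_size_ratio > 1.0:
            raise ValueError("infected_size_ratio must exceed 1")


def _block_dims(size_ratio: float) -> tuple[int, int]:
    """Pixel-tile dimensions of an infected cell (uninfected cells are 1 px)."""
    n = max(2, round(size_ratio))
    h = max(1, round(math.sqrt(n)))
    w = max(1, round(n / h))
    if h * w < 2:
        w = 2
    return h, w


def _lobe_mask(n_slots: int, elongation: float = 3.0) -> np.ndarray:
    """Boolean mask of an elongated elliptical lobe with ~n_slots pixels."""
    h = max(4, round(math.sqrt(4.0 * n_slots / (elongation * math.pi))))
    w = max(h + 2, round(elongation * h))
    # grow until the ellipse holds enough slots
    for _ in range(100):
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        mask = ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2 <= 1.0
        if mask.sum() >= n_slots:
            return mask
        w += 1
        if (w / h) > elongation + 1:
            h += 1
    return mask


def generate_nodule_tissue(spec: NoduleGenSpec) -> Tissue:
    """Generate one virtual nodule lobe per the generator spec.

    Layout: meristematic cap at the left apex of an elongated elliptical
    lobe (~``meristem_fraction`` of cells), cortex tiled with rectangular
    infected tiles (area ``infected_size_ratio`` x the unit uninfected cell,
    ``has_frankia`` true) interspersed among single-pixel uninfected cells.
    Every infected cell is guaranteed at least one uninfected neighbor
    (isolated tiles are converted back to uninfected pixels, logged).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    bh, bw = _block_dims(spec.infected_size_ratio)
    block_px = bh * bw

    n_mer = max(1, round(spec.meristem_fraction * spec.n_cells_target))
    n_cortex_cells = spec.n_cells_target - n_mer
    f = spec.infected_fraction_of_cortex
    n_inf_nominal = max(1, round(f * n_cortex_cells))
    n_uninf = n_cortex_cells - n_inf_nominal
    if n_uninf < 1:
        raise ValueError("spec infeasible: no uninfected cells in cortex")
    n_slots = n_mer + n_uninf + n_inf_nominal * block_px

    mask = _lobe_mask(n_slots)
    # recompute the tile count from the realized lobe so the infected
    # fraction of cortex *cells* hits the target despite mask rounding:
    # B / (B + S_cortex - block_px * B) = f  =>  B = f S / (1 + f(block_px-1))
    s_cortex = int(mask.sum()) - n_mer
    n_inf = max(1, round(f * s_cortex / (1.0 + f * (block_px - 1))))
    h, w = mask.shape
    # meristem cap: in-lobe pixels of the leftmost columns until quota met
    meristem = np.zeros_like(mask)
    got = 0
    for x in range(w):
        col = np.flatnonzero(mask[:, x])
        take = col[: max(0, n_mer - got)]
        meristem[take, x] = True
        got += take.size
        if got >= n_mer:
            break

    cortex = mask & ~meristem
    occupied = np.zeros_like(mask)
    placements: list[tuple[int, int]] = []

    def free_neighbor_count(y: int, x: int) -> int:
        """Free cortex pixels orthogonally adjacent to the tile at (y, x)."""
        n_free = 0
        for yy in range(y, y + bh):
            for xx in range(x, x + bw):
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx = yy + dy, xx + dx
                    if y <= ny < y + bh and x <= nx < x + bw:
                        continue
                    if 0 <= ny < h and 0 <= nx < w:
                        if cortex[ny, nx] and not occupied[ny, nx]:
                            n_free += 1
        return n_free

    def admissible(y: int, x: int) -> bool:
        region = np.s_[y : y + bh, x : x + bw]
        if not cortex[region].all() or occupied[region].any():
            return False
        occupied[region] = True
        ok = free_neighbor_count(y, x) >= 1 and all(
            free_neighbor_count(py, px) >= 1
            for py, px in placements
            if abs(py - y) <= bh and abs(px - x) <= bw
        )
        occupied[region] = False
        return ok

    attempts = 0
    max_attempts = 400 * n_inf
    while len(placements) < n_inf and attempts < max_attempts:
        attempts += 1
        y = int(rng.integers(0, h - bh + 1))
        x = int(rng.integers(0, w - bw + 1))
        if not admissible(y, x):
            continue
        occupied[y : y + bh, x : x + bw] = True
        placements.append((y, x))
    if len(placements) < n_inf:
        logger.warning(
            "placed %d/%d infected tiles before exhausting attempts",
            len(placements),
            n_inf,
        )

    # backstop repair: drop any tile left without an uninfected neighbor
    kept = []
    for y, x in placements:
        if free_neighbor_count(y, x) >= 1:
            kept.append((y, x))
        else:
            occupied[y : y + bh, x : x + bw] = False
            logger.warning(
                "repair: infected tile at (%d,%d) had no uninfected neighbor; "
                "converted back to uninfected pixels",
                y,
                x,
            )
    placements = kept

    # assign labels: meristem and uninfected pixels in scan order, then tiles
    label = np.zeros(mask.shape, dtype=np.int64)
    type_table: dict[int, str] = {}
    next_id = 1
    for y in range(h):
        for x in range(w):
            if meristem[y, x]:
                label[y, x] = next_id
                type_table[next_id] = "meristematic"
                next_id += 1
            elif cortex[y, x] and not occupied[y, x]:
                label[y, x] = next_id
                type_table[next_id] = "uninfected"
                next_id += 1
    for y, x in sorted(placements):
        label[y : y + bh, x : x + bw] = next_id
        type_table[next_id] = "infected"
        next_id += 1

    tissue = import_label_map(label, type_table, pixel_size=1.0)
    tissue.metadata = {
        "source": "synthetic_nodule",
        "generator": "nodusim.synthetic.generate_nodule_tissue",
        "seed": spec.seed,
        "n_cells_target": spec.n_cells_target,
        "meristem_fraction": spec.meristem_fraction,
        "infected_fraction_of_cortex": spec.infected_fraction_of_cortex,
        "infected_size_ratio": spec.infected_size_ratio,
        "pixel_size": 1.0,
    }
    return tissue


def generate_grid_tissue(nx: int, ny: int, type_of=None) -> Tissue:
    """Rectangular nx-by-ny grid of unit cells under 4-connectivity.

    ``type_of(row, col)`` maps positions to cell types (default all
    uninfected).  Areas are 1 and wall lengths 1; mainly a test fixture.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be positive")
    if type_of is None:
        type_of = lambda r, c: "uninfected"  # noqa: E731
    label = np.arange(1, nx * ny + 1, dtype=np.int64).reshape(ny, nx)
    table = {
        int(label[r, c]): type_of(r, c) for r in range(ny) for c in range(nx)
    }
    tissue = import_label_map(label, table, pixel_size=1.0)
    tissue.metadata = {
        "source": "synthetic_grid",
        "nx": nx,
        "ny": ny,
        "pixel_size": 1.0,
    }
    return tissue


def generate_two_cell_tissue(
    area_a: float = 1.0,
    area_b: float = 1.0,
    wall_length: float = 1.0,
    type_a: str = "infected",
    type_b: str = "uninfected",
) -> Tissue:
    """Minimal two-cell tissue (ids 1 and 2) for analytic-limit checks."""
    from .tissue import Cell, Interface, _require_valid

    tissue = Tissue(
        cells=[
            Cell(1, type_a, float(area_a)),
            Cell(2, type_b, float(area_b)),
        ],
        interfaces=[Interface(1, 2, float(wall_length))],
        metadata={"source": "synthetic_two_cell"},
    )
    _require_valid(tissue)
    return tissue


def render_label_map(tissue: Tissue) -> tuple[np.ndarray, dict[int, str]]:
    """Return the pixel label map and type table backing a generated tissue.

    Inverse of :func:`nodusim.tissue.import_label_map` on tissues produced
    by this module; raises for tissues without pixel backing.
    """
    if tissue.label_image is None or tissue.type_table is None:
        raise TissueError("tissue has no pixel backing to render")
    return tissue.label_image.copy(), dict(tissue.type_table)
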