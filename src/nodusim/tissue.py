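"""Virtual nodule tissues: cell-adjacency graphs digitized from label maps.

A tissue is a graph whose nodes are cells (with a type, an area and an
optional *Frankia* compartment) and whose edges are cell-cell interfaces
carrying the length of the shared wall.  Geometry is nondimensional: when a
tissue is digitized from a label-map image, areas are pixel counts times
``pixel_size**2`` and wall lengths are adjacent-pixel-pair counts times
``pixel_size``.

Cell types follow the three-type convention of actinorhizal nodule sections:
``infected`` (hypertrophied cortical cells hosting Frankia), ``uninfected``
(small cortical cells) and ``meristematic`` (apical dividing cells).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

SCHEMA = "tissue/1"

CELL_TYPES = ("infected", "uninfected", "meristematic")


class TissueError(ValueError):
    """Raised for malformed tissue files or invalid tissue construction."""


@dataclass
class Cell:
    """One cell of a virtual tissue.

    ``has_frankia`` marks the presence of an intracellular Frankia
    compartment (an optional auxin source in flux simulations); by default it
    is true exactly for infected cells.
    """

    cell_id: int
    cell_type: str
    area: float
    has_frankia: bool | None = None
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise TissueError(
                f"cell {self.cell_id}: unknown cell_type {self.cell_type!r}"
            )
        if self.has_frankia is None:
            self.has_frankia = self.cell_type == "infected"


@dataclass
class Interface:
    """Shared wall between two cells, identified by the unordered id pair."""

    cell_a: int
    cell_b: int
    wall_length: float

    def key(self) -> tuple[int, int]:
        return (self.cell_a, self.cell_b) if self.cell_a < self.cell_b else (
            self.cell_b,
            self.cell_a,
        )


@dataclass
class Tissue:
    """A connected cell-adjacency graph plus free-form provenance metadata.

    ``label_image`` and ``type_table`` hold the pixel backing for tissues
    built from (or rendered to) label maps; they are not serialized and do
    not participate in equality.
    """

    cells: list[Cell]
    interfaces: list[Interface]
    metadata: dict = field(default_factory=dict)
    label_image: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )
    type_table: dict[int, str] | None = field(
        default=None, repr=False, compare=False
    )

    # -- convenience accessors -------------------------------------------

    def cell_ids(self) -> list[int]:
        return [c.cell_id for c in self.cells]

    def cell_by_id(self, cell_id: int) -> Cell:
        try:
            return self._index()[cell_id]
        except KeyError:
            raise TissueError(f"no cell with id {cell_id}") from None

    def _index(self) -> dict[int, Cell]:
        idx = getattr(self, "_cell_index", None)
        if idx is None or len(idx) != len(self.cells):
            idx = {c.cell_id: c for c in self.cells}
            object.__setattr__(self, "_cell_index", idx)
        return idx

    def n_cells(self) -> int:
        return len(self.cells)

    def types(self) -> list[str]:
        return [c.cell_type for c in self.cells]

    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.cells], dtype=float)

    def neighbors(self, cell_id: int) -> list[int]:
        out = []
        for itf in self.interfaces:
            if itf.cell_a == cell_id:
                out.append(itf.cell_b)
            elif itf.cell_b == cell_id:
                out.append(itf.cell_a)
        return out


# ---------------------------------------------------------------------------
# validation


def validate_tissue(tissue: Tissue) -> list[str]:
    """Check every tissue invariant; return a list of violations (empty = valid).

    Violations are data, not exceptions: each entry names the offending
    record so hand-digitized inputs can be repaired.
    """
    report: list[str] = []
    seen: dict[int, int] = {}
    for c in tissue.cells:
        if c.cell_id in seen:
            report.append(f"duplicate cell_id {c.cell_id}")
        seen[c.cell_id] = 1
        if not (isinstance(c.cell_id, (int, np.integer)) and c.cell_id > 0):
            report.append(f"cell {c.cell_id}: cell_id must be a positive integer")
        if c.cell_type not in CELL_TYPES:
            report.append(f"cell {c.cell_id}: unknown cell_type {c.cell_type!r}")
        if not (c.area > 0):
            report.append(f"cell {c.cell_id}: nonpositive area {c.area}")
        if (
            c.has_frankia
            and c.cell_type != "infected"
            and not tissue.metadata.get("allow_frankia_outside_infected", False)
        ):
            report.append(
                f"cell {c.cell_id}: has_frankia on non-infected cell "
                f"({c.cell_type}); set metadata allow_frankia_outside_infected "
                "to override"
            )
    ids = set(seen)
    pairs: dict[tuple[int, int], int] = {}
    for itf in tissue.interfaces:
        ref = f"interface ({itf.cell_a},{itf.cell_b})"
        if itf.cell_a == itf.cell_b:
            report.append(f"{ref}: self-interface")
        key = itf.key()
        if key in pairs:
            report.append(f"{ref}: duplicate interface pair")
        pairs[key] = 1
        for cid in (itf.cell_a, itf.cell_b):
            if cid not in ids:
                report.append(f"{ref}: references unknown cell {cid}")
        if not (itf.wall_length > 0):
            report.append(f"{ref}: nonpositive wall_length {itf.wall_length}")
    # connectivity (only meaningful when the graph is otherwise well formed)
    if len(tissue.cells) >= 2 and not report:
        order = {cid: k for k, cid in enumerate(sorted(ids))}
        rows = [order[i.cell_a] for i in tissue.interfaces]
        cols = [order[i.cell_b] for i in tissue.interfaces]
        n = len(order)
        adj = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        ncomp, labels = connected_components(adj, directed=False)
        if ncomp > 1:
            inv = {v: k for k, v in order.items()}
            for comp in range(1, ncomp):
                members = [inv[k] for k in np.flatnonzero(labels == comp)]
                report.append(
                    f"tissue not connected: cells {members} form a separate "
                    "component"
                )
        degree = np.zeros(n)
        for r, c_ in zip(rows, cols):
            degree[r] += 1
            degree[c_] += 1
        for k in np.flatnonzero(degree == 0):
            inv = {v: kk for kk, v in order.items()}
            report.append(f"cell {inv[k]} appears in no interface")
    return report


def _require_valid(tissue: Tissue) -> None:
    report = validate_tissue(tissue)
    if report:
        raise TissueError("invalid tissue: " + "; ".join(report))


# ---------------------------------------------------------------------------
# serialization


def _tissue_to_obj(tissue: Tissue) -> dict:
    return {
        "schema": SCHEMA,
        "metadata": tissue.metadata,
        "cells": [
            {
                "id": int(c.cell_id),
                "type": c.cell_type,
                "area": float(c.area),
                "has_frankia": bool(c.has_frankia),
                "centroid": (
                    [float(c.centroid[0]), float(c.centroid[1])]
                    if c.centroid is not None
                    else None
                ),
            }
            for c in sorted(tissue.cells, key=lambda c: c.cell_id)
        ],
        "interfaces": [
            {
                "a": int(i.key()[0]),
                "b": int(i.key()[1]),
                "wall_length": float(i.wall_length),
            }
            for i in sorted(tissue.interfaces, key=lambda i: i.key())
        ],
    }


def save_tissue(tissue: Tissue, path: str | Path) -> None:
    """Write a validated tissue as versioned JSON.

    Output is canonical (sorted cells/interfaces, sorted keys, fixed
    separators) so identical tissues produce byte-identical files.
    """
    _require_valid(tissue)
    text = json.dumps(_tissue_to_obj(tissue), sort_keys=True, indent=1)
    Path(path).write_text(text + "\n")


def load_tissue(path: str | Path) -> Tissue:
    """Load and validate a tissue JSON file."""
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TissueError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(obj, dict) or obj.get("schema") != SCHEMA:
        raise TissueError(
            f"{path}: missing or unsupported schema (expected {SCHEMA!r})"
        )
    cells = []
    for rec in obj.get("cells", []):
        cells.append(
            Cell(
                cell_id=int(rec["id"]),
                cell_type=rec["type"],
                area=float(rec["area"]),
                has_frankia=rec.get("has_frankia"),
                centroid=tuple(rec["centroid"]) if rec.get("centroid") else None,
            )
        )
    interfaces = [
        Interface(int(r["a"]), int(r["b"]), float(r["wall_length"]))
        for r in obj.get("interfaces", [])
    ]
    tissue = Tissue(cells=cells, interfaces=interfaces, metadata=obj.get("metadata", {}))
    report = validate_tissue(tissue)
    if report:
        raise TissueError(f"{path}: " + "; ".join(report))
    return tissue


# ---------------------------------------------------------------------------
# label-map digitization


def import_label_map(
    image: np.ndarray,
    type_table: dict[int, str],
    pixel_size: float = 1.0,
) -> Tissue:
    """Digitize an integer label map into a tissue graph.

    One cell per nonzero label (label 0 is background); area is pixel count
    times ``pixel_size**2``; one interface per pair of labels adjacent under
    4-connectivity, with wall length equal to the number of adjacent pixel
    pairs times ``pixel_size``; centroid is the mean pixel coordinate
    (row, col).  Non-contiguous label regions are accepted with a warning.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise TissueError("label map must be a 2-D array")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)):
            raise TissueError("label map must contain integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise TissueError("label map must contain nonnegative labels")
    if pixel_size <= 0:
        raise TissueError("pixel_size must be positive")
    labels = np.unique(arr)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise TissueError("label map is all background")
    missing = [int(l) for l in labels if int(l) not in type_table]
    if missing:
        raise TissueError(f"labels missing from type table: {missing}")

    cells = []
    for lab in labels:
        mask = arr == lab
        npix = int(mask.sum())
        comp, ncomp = ndimage.label(mask)
        if ncomp > 1:
            msg = f"label {int(lab)} region is not contiguous ({ncomp} parts)"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        rr, cc = np.nonzero(mask)
        cells.append(
            Cell(
                cell_id=int(lab),
                cell_type=type_table[int(lab)],
                area=npix * pixel_size**2,
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )

    # count adjacent pixel pairs per unordered label pair (4-connectivity)
    counts: dict[tuple[int, int], int] = {}
    for a, b in (
        (arr[:-1, :].ravel(), arr[1:, :].ravel()),
        (arr[:, :-1].ravel(), arr[:, 1:].ravel()),
    ):
        sel = (a != b) & (a != 0) & (b != 0)
        lo = np.minimum(a[sel], b[sel])
        hi = np.maximum(a[sel], b[sel])
        pair, n = np.unique(np.stack([lo, hi]), axis=1, return_counts=True)
        for (pa, pb), k in zip(pair.T, n):
            key = (int(pa), int(pb))
            counts[key] = counts.get(key, 0) + int(k)
    interfaces = [
        Interface(a, b, k * pixel_size) for (a, b), k in sorted(counts.items())
    ]
    return Tissue(
        cells=cells,
        interfaces=interfaces,
        metadata={"source": "label_map", "pixel_size": pixel_size},
        label_image=arr.copy(),
        type_table={int(l): type_table[int(l)] for l in labels},
    )
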