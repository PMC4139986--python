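"""Accumulation-pattern classification and tissue rendering.

The simulation's qualitative output is *where* auxin ends up: the
classifier compares area-weighted mean steady-state concentrations per cell
type and labels the set of types sitting within ``epsilon`` (relative) of
the top mean:

* ``infected`` / ``uninfected`` / ``meristem`` — that type alone tops the
  ranking;
* ``infected_and_meristem`` — infected and meristematic cells jointly top
  the ranking, above the uninfected cells (the biologically observed
  accumulation pattern in *D. trinervis* nodules);
* ``uniform_ambiguous`` — any other near-top set (no clear winner).

The margin rule is this package's operationalization of "accumulation";
the underlying study reports patterns visually, without a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluxes import SimulationResult
from .tissue import Tissue

_TYPE_LABEL = {
    "infected": "infected",
    "uninfected": "uninfected",
    "meristematic": "meristem",
}

# section-image cell-type colors: infected red, uninfected yellow, meristem blue
TYPE_COLORS = {
    "infected": (0.85, 0.10, 0.10),
    "uninfected": (0.95, 0.85, 0.15),
    "meristematic": (0.15, 0.25, 0.85),
}


@dataclass
class PatternCall:
    """Per-cell-type concentration summary plus the categorical label."""

    mean_by_type: dict[str, float]
    ranking: list[str]
    label: str
    margin: float
    epsilon: float = 0.01
    converged: bool = True
    area_weighted: bool = True
    extras: dict = field(default_factory=dict)


def mean_concentration_by_type(
    concentrations: np.ndarray,
    tissue: Tissue,
    area_weighted: bool = True,
) -> dict[str, float]:
    """Mean concentration per present cell type (area-weighted by default)."""
    a = np.asarray(concentrations, dtype=float)
    if a.shape != (len(tissue.cells),):
        raise ValueError(
            f"{a.shape[0] if a.ndim else 0} concentrations for "
            f"{len(tissue.cells)} cells"
        )
    areas = tissue.areas()
    types = np.array(tissue.types())
    out = {}
    for t in ("infected", "uninfected", "meristematic"):
        sel = types == t
        if not sel.any():
            continue
        w = areas[sel] if area_weighted else np.ones(int(sel.sum()))
        out[t] = float(np.average(a[sel], weights=w))
    return out


def classify_pattern(
    result: SimulationResult,
    tissue: Tissue,
    epsilon: float = 0.01,
    area_weighted: bool = True,
) -> PatternCall:
    """Classify the accumulation pattern of a simulation result.

    Uses the result's pattern-bearing state (final steady state, or the
    exposure profile for transient scenarios).  Classification depends only
    on concentration ratios, so it is invariant to uniform rescaling.
    Non-converged results are classified anyway but flagged.
    """
    state = result.state_for_classification()
    means = mean_concentration_by_type(
        state.concentrations, tissue, area_weighted=area_weighted
    )
    ranking = sorted(means, key=lambda t: means[t], reverse=True)
    if len(means) == 1:
        only = ranking[0]
        return PatternCall(
            mean_by_type=means,
            ranking=ranking,
            label=_TYPE_LABEL[only],
            margin=float("inf"),
            epsilon=epsilon,
            converged=result.converged,
            area_weighted=area_weighted,
        )
    top, runner = means[ranking[0]], means[ranking[1]]
    margin = (top - runner) / abs(runner) if runner != 0 else (
        float("inf") if top > 0 else 0.0
    )

    # "accumulation in X" means X sits at the top of the concentration
    # ranking: the label names the set of types within epsilon (relative)
    # of the top mean
    near_top = {t for t in means if means[t] >= top * (1.0 - epsilon)} if top > 0 else set(means)
    label: str
    if near_top == {"infected", "meristematic"}:
        label = "infected_and_meristem"
    elif len(near_top) == 1:
        label = _TYPE_LABEL[ranking[0]]
    else:
        label = "uniform_ambiguous"
    return PatternCall(
        mean_by_type=means,
        ranking=ranking,
        label=label,
        margin=margin,
        epsilon=epsilon,
        converged=result.converged,
        area_weighted=area_weighted,
    )


def summarize(calls: list[PatternCall], keys: list[dict] | None = None) -> pd.DataFrame:
    """Count pattern labels, optionally grouped by per-call key dicts.

    ``keys`` (e.g. ``{"layout": ..., "scenario": ...}``) must align with
    ``calls``; counts sum to the input size.
    """
    if not calls:
        raise ValueError("summarize requires at least one pattern call")
    if keys is not None and len(keys) != len(calls):
        raise ValueError("keys must align one-to-one with calls")
    rows = []
    for k, call in enumerate(calls):
        row = dict(keys[k]) if keys is not None else {}
        row["pattern"] = call.label
        rows.append(row)
    df = pd.DataFrame(rows)
    group_cols = [c for c in df.columns]
    return (
        df.groupby(group_cols, sort=True)
        .size()
        .reset_index(name="count")
    )


def render_tissue(
    tissue: Tissue,
    path,
    state=None,
    mode: str = "types",
    cmap: str = "viridis",
    dpi: int = 150,
):
    """Render a tissue as a section image (PNG/SVG by file extension).

    ``types`` mode colors cells by type with the red/yellow/blue section
    convention; ``concentration`` mode shades cells by the supplied state
    with a colorbar.  Pixel-backed tissues render as label-map images;
    tissues with centroids only render as area-scaled markers.  Output is
    deterministic for fixed input.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import Normalize

    if mode not in ("types", "concentration"):
        raise ValueError(f"unknown render mode {mode!r}")
    if mode == "concentration":
        if state is None:
            raise ValueError("concentration mode requires a state")
        conc = np.asarray(
            state.concentrations if hasattr(state, "concentrations") else state,
            dtype=float,
        )
        if conc.shape != (len(tissue.cells),):
            raise ValueError("state length does not match tissue")

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.set_axis_off()
    if tissue.label_image is not None:
        label = tissue.label_image
        order = {c.cell_id: k for k, c in enumerate(tissue.cells)}
        rgb = np.ones(label.shape + (3,))
        if mode == "types":
            for c in tissue.cells:
                rgb[label == c.cell_id] = TYPE_COLORS[c.cell_type]
            ax.imshow(rgb, interpolation="nearest")
        else:
            norm = Normalize(vmin=float(conc.min()), vmax=float(conc.max() or 1.0))
            colormap = plt.get_cmap(cmap)
            for c in tissue.cells:
                rgb[label == c.cell_id] = colormap(norm(conc[order[c.cell_id]]))[:3]
            ax.imshow(rgb, interpolation="nearest")
            fig.colorbar(
                plt.cm.ScalarMappable(norm=norm, cmap=colormap),
                ax=ax,
                label="auxin concentration",
            )
    else:
        if any(c.centroid is None for c in tissue.cells):
            raise ValueError("tissue has neither pixel backing nor centroids")
        xs = [c.centroid[1] for c in tissue.cells]
        ys = [c.centroid[0] for c in tissue.cells]
        sizes = 40.0 * tissue.areas()
        if mode == "types":
            colors = [TYPE_COLORS[c.cell_type] for c in tissue.cells]
            ax.scatter(xs, ys, s=sizes, c=colors)
        else:
            sc = ax.scatter(xs, ys, s=sizes, c=conc, cmap=cmap)
            fig.colorbar(sc, ax=ax, label="auxin concentration")
        ax.invert_yaxis()
        ax.set_aspect("equal")
    fig.savefig(path, dpi=dpi, metadata={"Software": "nodusim"})
    plt.close(fig)
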