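"""Simulation scenarios and parameter-space exploration.

Three auxin-supply regimes are modeled on a nodule section:

* ``production_only`` — no initial auxin, basal production in every cell;
* ``initial_pool``    — a basal initial auxin level everywhere, no
  production (the pool decays; the readout is the time-integrated exposure
  profile, which carries the spatial pattern of the transient);
* ``frankia_source_low`` / ``frankia_source_high`` — an auxin source inside
  the Frankia compartment of infected cells, at two strengths.

The parameter sweep evaluates a grid over the wall/carrier permeabilities
and source strength with the direct steady-state solver, classifying each
configuration's accumulation pattern.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carriers import CarrierLayout, place_carriers
from .fluxes import (
    ModelParams,
    SimulationResult,
    pool_exposure,
    simulate,
    steady_state_direct,
)
from .patterns import PatternCall, classify_pattern
from .synthetic import NoduleGenSpec, generate_nodule_tissue
from .tissue import Tissue

logger = logging.getLogger(__name__)


@dataclass
class Scenario:
    """A named auxin-supply regime expressed as overrides of ModelParams."""

    name: str
    overrides: dict = field(default_factory=dict)

    def apply(self, base: ModelParams) -> ModelParams:
        params = base.with_overrides(**self.overrides)
        self._check(params)
        return params

    def _check(self, p: ModelParams) -> None:
        ok = True
        if self.name == "production_only":
            ok = p.a0 == 0 and p.sigma > 0 and p.s_frankia == 0
        elif self.name == "initial_pool":
            ok = p.a0 > 0 and p.sigma == 0 and p.s_frankia == 0
        elif self.name.startswith("frankia_source"):
            ok = p.s_frankia > 0 and p.a0 == 0 and p.sigma == 0
        if not ok:
            raise ValueError(
                f"scenario {self.name!r} invariants violated by parameters "
                f"(sigma={p.sigma}, a0={p.a0}, s_frankia={p.s_frankia})"
            )


def scenario_preset(name: str, base: ModelParams | None = None) -> Scenario:
    """Build a named scenario, sourcing magnitudes from ``base`` params."""
    base = base or ModelParams()
    sigma = base.sigma if base.sigma > 0 else 0.1
    a0 = base.a0 if base.a0 > 0 else 1.0
    s_low = base.s_frankia if base.s_frankia > 0 else 1.0
    presets = {
        "production_only": {"sigma": sigma, "a0": 0.0, "s_frankia": 0.0},
        "initial_pool": {"sigma": 0.0, "a0": a0, "s_frankia": 0.0},
        "frankia_source_low": {"sigma": 0.0, "a0": 0.0, "s_frankia": s_low},
        "frankia_source_high": {"sigma": 0.0, "a0": 0.0, "s_frankia": 10.0 * s_low},
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; options: {sorted(presets)}")
    return Scenario(name, presets[name])


SCENARIO_NAMES = (
    "production_only",
    "initial_pool",
    "frankia_source_low",
    "frankia_source_high",
)


def run_scenario(
    tissue: Tissue,
    layout: CarrierLayout,
    base_params: ModelParams,
    scenario: Scenario | str,
) -> SimulationResult:
    """Run one scenario to its pattern-bearing state.

    Steady-supply scenarios integrate to the steady state.  For the
    decaying ``initial_pool`` the pattern state is the time-integrated
    exposure profile (direct integral of the transient; the absolute level
    decays to zero and only the spatial pattern is meaningful).
    """
    if isinstance(scenario, str):
        scenario = scenario_preset(scenario, base_params)
    params = scenario.apply(base_params)
    result = simulate(tissue, layout, params)
    if scenario.name == "initial_pool":
        result.pattern_state = pool_exposure(tissue, layout, params)
    result.scenario = scenario.name
    return result


def run_nodule_panel(
    tissue_seeds: tuple[int, int, int] = (1, 2, 3),
    params: ModelParams | None = None,
    layout_preset: str = "discaria",
    scenarios: tuple[str, ...] = SCENARIO_NAMES,
    gen_spec: NoduleGenSpec | None = None,
    epsilon: float = 0.01,
) -> tuple[list[tuple[Tissue, SimulationResult, PatternCall]], pd.DataFrame]:
    """Simulate all scenarios on three synthetic nodules and classify patterns.

    Returns the per-run (tissue, result, call) triples and a summary table
    with one row per (tissue seed, scenario).
    """
    params = params or ModelParams()
    runs = []
    rows = []
    for seed in tissue_seeds:
        spec = gen_spec or NoduleGenSpec()
        spec = NoduleGenSpec(
            n_cells_target=spec.n_cells_target,
            meristem_fraction=spec.meristem_fraction,
            infected_fraction_of_cortex=spec.infected_fraction_of_cortex,
            infected_size_ratio=spec.infected_size_ratio,
            seed=seed,
        )
        tissue = generate_nodule_tissue(spec)
        layout = place_carriers(tissue, layout_preset)
        for name in scenarios:
            result = run_scenario(tissue, layout, params, name)
            call = classify_pattern(result, tissue, epsilon=epsilon)
            runs.append((tissue, result, call))
            rows.append(
                {
                    "tissue_seed": seed,
                    "layout": layout_preset,
                    "scenario": name,
                    "pattern": call.label,
                    "margin": call.margin,
                    "mean_infected": call.mean_by_type.get("infected", np.nan),
                    "mean_uninfected": call.mean_by_type.get("uninfected", np.nan),
                    "mean_meristem": call.mean_by_type.get("meristematic", np.nan),
                    "converged": result.converged,
                }
            )
    return runs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter-space exploration


DEFAULT_GRID = {
    # permeabilities in units of the passive wall leak; carriers span
    # comparable-to-passive up to strongly dominant (see methods note)
    "d_wall": [0.25, 0.5, 1.0, 2.0],
    "p_pin": [2.5, 8.0, 25.0, 80.0],
    "p_aux": [2.5, 8.0, 25.0, 80.0],
    "source_scale": [0.3, 1.0, 3.0, 10.0],
}


@dataclass
class SweepSpec:
    """Grid specification for the parameter-space exploration.

    ``source_scale`` maps to the basal production rate for production
    scenarios and to the Frankia source strength for frankia scenarios.
    ``delta`` stays fixed (> 0 so every configuration has a steady state).
    """

    grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    layouts: tuple[str, ...] = ("discaria",)
    scenarios: tuple[str, ...] = ("frankia_source_low",)
    delta: float = 1.0
    i_base: float = 1.0
    epsilon: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("sweep grid must be nonempty")
        for name, values in self.grid.items():
            if name not in DEFAULT_GRID:
                raise ValueError(f"unknown sweep axis {name!r}")
            if any(v < 0 for v in values):
                raise ValueError(f"negative value on sweep axis {name!r}")
        if not self.delta > 0:
            raise ValueError("delta must stay positive in sweeps")


def sweep_parameters(sweep: SweepSpec, tissue: Tissue | None = None) -> pd.DataFrame:
    """Exhaustively evaluate the sweep grid with the direct solver.

    One row per distinct (layout, scenario, parameter combination), in
    deterministic order; per-row failures are recorded in an ``error``
    column and never abort the sweep.
    """
    if tissue is None:
        tissue = generate_nodule_tissue(NoduleGenSpec(seed=sweep.seed))
    axes = {}
    for name in DEFAULT_GRID:
        values = sweep.grid.get(name, DEFAULT_GRID[name])
        deduped = sorted(set(float(v) for v in values))
        axes[name] = deduped
    layouts = {name: place_carriers(tissue, name) for name in sweep.layouts}

    rows = []
    config_id = 0
    for layout_name in sweep.layouts:
        for scenario_name in sweep.scenarios:
            for d_wall, p_pin, p_aux, src in itertools.product(
                axes["d_wall"], axes["p_pin"], axes["p_aux"], axes["source_scale"]
            ):
                row = {
                    "config_id": config_id,
                    "d_wall": d_wall,
                    "p_pin": p_pin,
                    "p_aux": p_aux,
                    "source_scale": src,
                    "scenario": scenario_name,
                    "layout": layout_name,
                }
                try:
                    if scenario_name == "production_only":
                        supply = {"sigma": src, "a0": 0.0, "s_frankia": 0.0}
                    elif scenario_name.startswith("frankia_source"):
                        supply = {"sigma": 0.0, "a0": 0.0, "s_frankia": src}
                    else:
                        raise ValueError(
                            "sweep fast path supports steady-supply scenarios "
                            "only (production or frankia source)"
                        )
                    params = ModelParams(
                        d_wall=d_wall,
                        p_pin=p_pin,
                        p_aux=p_aux,
                        i_base=sweep.i_base,
                        delta=sweep.delta,
                        **supply,
                    )
                    state = steady_state_direct(tissue, layouts[layout_name], params)
                    result = SimulationResult(
                        final_state=state,
                        converged=True,
                        n_steps=0,
                        params=params,
                        layout_name=layout_name,
                        scenario=scenario_name,
                    )
                    call = classify_pattern(result, tissue, epsilon=sweep.epsilon)
                    row.update(
                        pattern=call.label,
                        margin=call.margin,
                        mean_infected=call.mean_by_type.get("infected", np.nan),
                        mean_uninfected=call.mean_by_type.get("uninfected", np.nan),
                        mean_meristem=call.mean_by_type.get("meristematic", np.nan),
                        converged=True,
                        error="",
                    )
                except Exception as exc:  # recorded, never aborts the sweep
                    logger.warning("sweep row %d failed: %s", config_id, exc)
                    row.update(
                        pattern="error",
                        margin=np.nan,
                        mean_infected=np.nan,
                        mean_uninfected=np.nan,
                        mean_meristem=np.nan,
                        converged=False,
                        error=str(exc),
                    )
                rows.append(row)
                config_id += 1
    return pd.DataFrame(rows)


def find_reproducing_configs(table: pd.DataFrame, target_pattern: str) -> pd.DataFrame:
    """Rows of a sweep table whose accumulation pattern matches the target."""
    if "pattern" not in table.columns:
        raise ValueError("not a sweep table: missing 'pattern' column")
    return table[table["pattern"] == target_pattern].copy()


def sweep_report(table: pd.DataFrame) -> str:
    """Human-readable summary of a sweep, including the key negative count."""
    n = len(table)
    counts = table["pattern"].value_counts().to_dict()
    target = int(counts.get("infected_and_meristem", 0))
    lines = [
        f"parameter sweep: {n} configurations",
        "pattern counts: "
        + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
        f"configurations reproducing the biological pattern "
        f"(infected_and_meristem): {target}",
    ]
    return "\n".join(lines)
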