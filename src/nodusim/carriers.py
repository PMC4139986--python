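"""Cell-type-driven placement of membrane auxin carriers.

A carrier layout assigns to every (interface, membrane side) pair an
AUX1-like influx-carrier density and a PIN1-like efflux-carrier density.
Densities are dimensionless multipliers on the global carrier permeability
coefficients of the flux model; the presets encode presence (1) or absence
(0) as reported by immunolocalization / promoter-reporter studies.

Two contrasting presets are provided:

* ``discaria`` — PIN1 on every membrane of infected cells, AUX1 on every
  membrane of meristematic cells (the *Discaria trinervis* localization).
* ``casuarina`` — AUX1 on every membrane of infected cells, PIN1 on the
  membranes of uninfected cells that face an infected cell (the
  *Casuarina glauca* localization, a positive control known to drive auxin
  accumulation into infected cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue import Tissue


class LayoutError(ValueError):
    pass


@dataclass
class CarrierLayout:
    """Per-interface, per-side carrier densities.

    Arrays have shape (n_interfaces, 2); column 0 is the ``cell_a`` side of
    the interface, column 1 the ``cell_b`` side, in tissue interface order.
    """

    aux: np.ndarray
    pin: np.ndarray
    name: str = "custom"
    n_interfaces: int = field(init=False)

    def __post_init__(self) -> None:
        self.aux = np.asarray(self.aux, dtype=float)
        self.pin = np.asarray(self.pin, dtype=float)
        if self.aux.shape != self.pin.shape or self.aux.ndim != 2 or self.aux.shape[1] != 2:
            raise LayoutError("aux/pin must both have shape (n_interfaces, 2)")
        if (self.aux < 0).any() or (self.pin < 0).any():
            raise LayoutError("carrier densities must be nonnegative")
        self.n_interfaces = self.aux.shape[0]

    @classmethod
    def zeros(cls, tissue: Tissue, name: str = "none") -> "CarrierLayout":
        n = len(tissue.interfaces)
        return cls(aux=np.zeros((n, 2)), pin=np.zeros((n, 2)), name=name)

    def validate_for(self, tissue: Tissue) -> None:
        if self.n_interfaces != len(tissue.interfaces):
            raise LayoutError(
                f"layout covers {self.n_interfaces} interfaces but tissue has "
                f"{len(tissue.interfaces)}"
            )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CarrierLayout)
            and self.aux.shape == other.aux.shape
            and np.array_equal(self.aux, other.aux)
            and np.array_equal(self.pin, other.pin)
        )


def _side_types(tissue: Tissue) -> list[tuple[str, str]]:
    """(type of cell_a, type of cell_b) per interface."""
    return [
        (
            tissue.cell_by_id(i.cell_a).cell_type,
            tissue.cell_by_id(i.cell_b).cell_type,
        )
        for i in tissue.interfaces
    ]


def place_carriers_discaria(tissue: Tissue) -> CarrierLayout:
    """PIN1 on all infected-cell membranes, AUX1 on all meristematic membranes."""
    layout = CarrierLayout.zeros(tissue, name="discaria")
    for k, (ta, tb) in enumerate(_side_types(tissue)):
        for side, t in enumerate((ta, tb)):
            if t == "infected":
                layout.pin[k, side] = 1.0
            if t == "meristematic":
                layout.aux[k, side] = 1.0
    return layout


def place_carriers_casuarina(tissue: Tissue) -> CarrierLayout:
    """AUX1 on infected-cell membranes; PIN1 on uninfected sides facing infected cells."""
    layout = CarrierLayout.zeros(tissue, name="casuarina")
    for k, (ta, tb) in enumerate(_side_types(tissue)):
        types = (ta, tb)
        for side in (0, 1):
            facing = types[1 - side]
            if types[side] == "infected":
                layout.aux[k, side] = 1.0
            if types[side] == "uninfected" and facing == "infected":
                layout.pin[k, side] = 1.0
    return layout


def place_carriers_custom(
    tissue: Tissue,
    rules: list[tuple[str, str, str, float]],
) -> CarrierLayout:
    """Apply ordered (side_type, facing_type-or-'any', carrier, density) rules.

    Later rules override earlier ones for the same (side, carrier).
    ``carrier`` is ``'aux'`` or ``'pin'``.
    """
    layout = CarrierLayout.zeros(tissue, name="custom")
    arrays = {"aux": layout.aux, "pin": layout.pin}
    side_types = _side_types(tissue)
    for rule in rules:
        try:
            side_type, facing_type, carrier, density = rule
        except (TypeError, ValueError):
            raise LayoutError(f"malformed rule {rule!r}") from None
        if carrier not in arrays:
            raise LayoutError(f"unknown carrier {carrier!r} in rule {rule!r}")
        density = float(density)
        if density < 0:
            raise LayoutError(f"negative density in rule {rule!r}")
        for k, (ta, tb) in enumerate(side_types):
            types = (ta, tb)
            for side in (0, 1):
                if types[side] != side_type:
                    continue
                if facing_type not in ("any", types[1 - side]):
                    continue
                arrays[carrier][k, side] = density
    return layout


PRESETS = {
    "discaria": place_carriers_discaria,
    "casuarina": place_carriers_casuarina,
    "none": CarrierLayout.zeros,
}


def place_carriers(tissue: Tissue, preset: str) -> CarrierLayout:
    """Look up a named preset and apply it."""
    try:
        fn = PRESETS[preset]
    except KeyError:
        raise LayoutError(
            f"unknown layout preset {preset!r}; options: {sorted(PRESETS)}"
        ) from None
    return fn(tissue)
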