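import numpy as np
import pytest

from nodusim import (
    Cell,
    Interface,
    ModelParams,
    Tissue,
    CarrierLayout,
    generate_grid_tissue,
    generate_two_cell_tissue,
)


@pytest.fixture
def grid3() -> Tissue:
    return generate_grid_tissue(3, 3)


@pytest.fixture
def two_cell() -> Tissue:
    return generate_two_cell_tissue()


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


def random_grid_tissue(rng: np.random.Generator, nx: int, ny: int) -> Tissue:
    """Connected grid-topology tissue with random types, areas and walls."""
    types = rng.choice(["infected", "uninfected", "meristematic"], size=nx * ny)
    cells = [
        Cell(k + 1, types[k], area=float(rng.uniform(0.5, 4.0)))
        for k in range(nx * ny)
    ]
    interfaces = []
    for r in range(ny):
        for c in range(nx):
            k = r * nx + c + 1
            if c + 1 < nx:
                interfaces.append(Interface(k, k + 1, float(rng.uniform(0.5, 2.0))))
            if r + 1 < ny:
                interfaces.append(Interface(k, k + nx, float(rng.uniform(0.5, 2.0))))
    return Tissue(cells=cells, interfaces=interfaces, metadata={"source": "random_grid"})


def random_layout(rng: np.random.Generator, tissue: Tissue) -> CarrierLayout:
    n = len(tissue.interfaces)
    return CarrierLayout(
        aux=rng.uniform(0.0, 2.0, size=(n, 2)),
        pin=rng.uniform(0.0, 2.0, size=(n, 2)),
        name="random",
    )


def random_params(rng: np.random.Generator) -> ModelParams:
    return ModelParams(
        d_wall=float(rng.uniform(0.2, 2.0)),
        p_pin=float(rng.uniform(0.0, 15.0)),
        p_aux=float(rng.uniform(0.0, 15.0)),
        i_base=float(rng.uniform(0.5, 2.0)),
        sigma=float(rng.uniform(0.05, 1.0)),
        delta=float(rng.uniform(0.5, 2.0)),
        s_frankia=float(rng.uniform(0.0, 2.0)),
        a0=float(rng.uniform(0.0, 2.0)),
        steady_tol=1e-12,
        t_max=400.0,
    )
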