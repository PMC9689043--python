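import numpy as np
import pytest

from lusim.phantom import Grid2D, MaterialMap


@pytest.fixture
def small_grid() -> Grid2D:
    return Grid2D(nx=64, ny=48, dx=1e-4, dy=1e-4, x0=-3.2e-3, y0=0.0)


def homogeneous_material(grid: Grid2D, c: float = 1570.0, rho: float = 1090.0,
                         pml_width: float = 0.0) -> MaterialMap:
    return MaterialMap(
        grid=grid,
        velocity=np.full(grid.shape, c),
        density=np.full(grid.shape, rho),
        ldz_mask=np.zeros(grid.shape, dtype=bool),
        pml_width=pml_width,
    )


@pytest.fixture
def homogeneous_muscle(small_grid) -> MaterialMap:
    return homogeneous_material(small_grid)
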