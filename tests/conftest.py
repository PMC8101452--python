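import numpy as np
import pytest

from climniche.climate_space import fit_climate_transform, to_env_space
from climniche.grids import GridSpec, PCStack
from climniche.synthetic import generate_current_climate


@pytest.fixture(scope="session")
def current_stack():
    """A 30x30 synthetic bioclim stack with 5% nodata."""
    return generate_current_climate(
        GridSpec(30, 30, nodata_fraction=0.05), seed=11
    )


@pytest.fixture(scope="session")
def transform(current_stack):
    return fit_climate_transform(current_stack, k=3)


@pytest.fixture(scope="session")
def env(current_stack, transform):
    return to_env_space(current_stack, transform)


@pytest.fixture(scope="session")
def make_pc_stack():
    """Factory: wrap an (n_rows*n_cols, k) score table as a fully-valid PCStack."""

    def _make(scores: np.ndarray, n_rows: int, n_cols: int, cell_area: float = 1.0):
        scores = np.asarray(scores, dtype=float)
        k = scores.shape[1]
        if scores.shape[0] != n_rows * n_cols:
            raise ValueError("scores must fill the grid")
        data = scores.T.reshape(k, n_rows, n_cols)
        grid = GridSpec(n_rows, n_cols, cell_area=cell_area)
        return PCStack(
            names=tuple(f"PC{i + 1}" for i in range(k)),
            data=data,
            mask=np.ones((n_rows, n_cols), dtype=bool),
            grid=grid,
        )

    return _make
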