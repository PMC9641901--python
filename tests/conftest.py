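import numpy as np
import pytest

import aedespop as ap


@pytest.fixture(scope="session")
def registry():
    return ap.load_registry()


@pytest.fixture(scope="session", params=["aegypti", "albopictus", "japonicus", "koreicus"])
def species_params(request):
    return ap.get_species_params(request.param)


@pytest.fixture(scope="session")
def albopictus():
    return ap.get_species_params("albopictus")


@pytest.fixture(scope="session")
def aegypti():
    return ap.get_species_params("aegypti")


@pytest.fixture(scope="session")
def punctual_warm():
    return ap.make_toy_scenario("punctual_warm", seed=1)


@pytest.fixture(scope="session")
def regional_10cell():
    return ap.make_toy_scenario("regional_10cell", seed=2)


@pytest.fixture(scope="session")
def lattice_3x3():
    return ap.make_toy_scenario("lattice_3x3", seed=3)


def make_result(counts, scale="rg", cellsize=250.0, start="2014-01-01"):
    """Hand-built SimulationResult from a (iterations, days, cells, 4) array."""
    counts = np.asarray(counts, dtype=np.int64)
    it, nd, nc, _ = counts.shape
    import pandas as pd

    config = ap.SimulationConfig(
        scale=scale,
        start_date=start,
        end_date=str((pd.Timestamp(start) + pd.Timedelta(days=nd - 1)).date()),
        iterations=it,
        cellsize=cellsize,
    )
    return ap.SimulationResult(
        counts=counts,
        eggs_laid=np.zeros((it, nd, nc), dtype=np.int64),
        host_seeking=np.zeros((it, nd, nc), dtype=np.int64),
        dates=pd.date_range(start, periods=nd, freq="D"),
        cell_ids=[f"c{i}" for i in range(nc)],
        config=config,
        iteration_seeds=list(range(it)),
    )
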