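import numpy as np
import pytest

from landconnect.genetics import GenotypeTable
from landconnect.raster import Raster


@pytest.fixture
def uniform_raster():
    """5x5 all-habitat raster at 100 m cells."""
    return Raster(np.full((5, 5), 10.0), cell_size=100.0)


@pytest.fixture
def tiny_table():
    """3 sites x 3 individuals x 2 loci, fully scored, with coordinates."""
    calls = np.array(
        [
            # site A: mostly allele 1 at both loci
            [[1, 1], [1, 1]],
            [[1, 1], [1, 2]],
            [[1, 2], [1, 1]],
            # site B: mixed
            [[1, 2], [2, 2]],
            [[2, 2], [1, 2]],
            [[1, 2], [2, 2]],
            # site C: mostly allele 2
            [[2, 2], [2, 2]],
            [[2, 2], [2, 2]],
            [[1, 2], [2, 2]],
        ]
    )
    return GenotypeTable(
        individual_ids=[f"I{i}" for i in range(9)],
        site_ids=["A"] * 3 + ["B"] * 3 + ["C"] * 3,
        loci=["L1", "L2"],
        calls=calls,
        sites={"A": (100.0, 100.0), "B": (500.0, 100.0), "C": (300.0, 600.0)},
    )


def random_cost_raster(seed: int, shape=(6, 6), nodata_holes: int = 0) -> Raster:
    """Random positive-cost raster, optionally with NoData holes that keep
    the lattice connected."""
    rng = np.random.default_rng(seed)
    data = np.exp(rng.uniform(np.log(1.0), np.log(1000.0), shape))
    if nodata_holes:
        # punch interior holes only, keeping the border intact (stays connected)
        rows = rng.integers(1, shape[0] - 1, nodata_holes)
        cols = rng.integers(1, shape[1] - 1, nodata_holes)
        data[rows, cols] = np.nan
    return Raster(data, cell_size=100.0)
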