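import numpy as np
import pandas as pd
import pytest

from cyanoclock.trace_model import FilamentSeries, TRACES_COLUMNS


def make_series(rows: list[dict]) -> FilamentSeries:
    """Build a FilamentSeries from shorthand row dicts (defaults filled in)."""
    filled = []
    for r in rows:
        d = {"time_h": 0.0, "filament_id": "F0", "cell_id": "c0", "parent_id": None,
             "pos_index": 0, "cell_type": "vegetative", "gfp": 100.0, "af": 100.0,
             "area": 4.0}
        d.update(r)
        filled.append(d)
    return FilamentSeries(filled[0]["filament_id"], pd.DataFrame(filled)[TRACES_COLUMNS])


@pytest.fixture
def two_cell_series() -> FilamentSeries:
    """Two cells over three frames, no divisions."""
    rows = []
    for k, t in enumerate([0.0, 0.5, 1.0]):
        for i in range(2):
            rows.append({"time_h": t, "cell_id": f"c{i}", "pos_index": i,
                         "gfp": 100.0 + 10 * k + i, "af": 50.0})
    return make_series(rows)


@pytest.fixture
def division_series() -> FilamentSeries:
    """One cell dividing at the second frame into two daughters."""
    rows = [
        {"time_h": 0.0, "cell_id": "m", "pos_index": 0, "gfp": 200.0, "area": 8.0},
        {"time_h": 0.5, "cell_id": "d0", "parent_id": "m", "pos_index": 0,
         "gfp": 98.0, "area": 4.0},
        {"time_h": 0.5, "cell_id": "d1", "parent_id": "m", "pos_index": 1,
         "gfp": 102.0, "area": 4.0},
        {"time_h": 1.0, "cell_id": "d0", "parent_id": "m", "pos_index": 0,
         "gfp": 99.0, "area": 4.0},
        {"time_h": 1.0, "cell_id": "d1", "parent_id": "m", "pos_index": 1,
         "gfp": 103.0, "area": 4.0},
    ]
    return make_series(rows)


@pytest.fixture
def patterned_series() -> FilamentSeries:
    """Single frame with pattern H V V V H (one bounded interval)."""
    types = ["heterocyst", "vegetative", "vegetative", "vegetative", "heterocyst"]
    rows = [{"time_h": 0.0, "cell_id": f"c{i}", "pos_index": i, "cell_type": ct}
            for i, ct in enumerate(types)]
    rows += [{"time_h": 0.5, "cell_id": f"c{i}", "pos_index": i, "cell_type": ct}
             for i, ct in enumerate(types)]
    return make_series(rows)
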