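import numpy as np
import pandas as pd
import pytest

from bacipln.data_io import CatchTable


def make_table(rows):
    """Build a CatchTable from (lake, station, year, species, count, role) tuples."""
    df = pd.DataFrame(
        rows, columns=["lake", "station", "year", "species", "count", "role"]
    )
    return CatchTable(df)


@pytest.fixture
def toy_table():
    """One lake, stations A (all of 1995-1997) and B (missing 1996)."""
    rows = []
    for year in (1995, 1996, 1997):
        rows.append(("LakeX", "A", year, "Walleye", 3, "impact"))
        if year != 1996:
            rows.append(("LakeX", "B", year, "Walleye", 5, "impact"))
    return make_table(rows)


def random_table(rng, n_lakes=3, n_stations=4, years=(1990, 2014), drop_frac=0.1):
    """Random toy table with some station-years dropped."""
    rows = []
    for li in range(n_lakes):
        lake = f"L{li}"
        for si in range(n_stations):
            for year in range(years[0], years[1] + 1):
                if rng.random() < drop_frac:
                    continue
                rows.append(
                    (lake, f"S{si}", year, "Walleye", int(rng.poisson(4.0)), "impact")
                )
    return make_table(rows)
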