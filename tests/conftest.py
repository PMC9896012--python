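import numpy as np
import pandas as pd
import pytest

from tfcrosstalk.simulate import OccupancyModel


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def make_site_table(rows):
    """Helper: site table with the generator's schema from terse tuples
    (site_id, start, end, site_class, strength, motif positions dict)."""
    records = []
    for sid, start, end, cls, strength, motif_pos in rows:
        records.append(
            {
                "site_id": sid,
                "chrom": "chrS",
                "start": start,
                "end": end,
                "site_class": cls,
                "strength": strength,
                "strand": "+",
                "motif_offset": 40 if "&" in cls else 0,
                "motif_AHR": motif_pos.get("AHR", -1),
                "motif_HIF1": motif_pos.get("HIF1", -1),
                "motif_HIF2": motif_pos.get("HIF2", -1),
            }
        )
    return pd.DataFrame(records).set_index("site_id")


@pytest.fixture
def single_site_model():
    """One AHR-only site, activities switchable between two conditions."""
    sites = make_site_table([("s1", 100, 500, "AHR", 10.0, {"AHR": 300})])
    return OccupancyModel(
        activities={
            "ahr_only": {"AHR": 1.0, "HIF1": 0.0, "HIF2": 0.0},
            "ahr_plus_hif": {"AHR": 1.0, "HIF1": 1.0, "HIF2": 0.0},
        },
        K=1.0,
        sites=sites,
    )
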