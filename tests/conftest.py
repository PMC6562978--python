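import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from roosurvey.landscape import ClearedZone, Landscape


@pytest.fixture()
def square_landscape():
    """One 400 x 400 m cleared zone ('HB') surrounded by forest."""
    zone = ClearedZone(label="HB", polygon=box(100, 100, 500, 500))
    return Landscape(zones=[zone], extent=box(0, 0, 600, 600))


@pytest.fixture()
def two_zone_landscape():
    zones = [
        ClearedZone(label="HB", polygon=box(100, 100, 513.5, 513.5)),
        ClearedZone(label="HH", polygon=box(700, 100, 1100, 500)),
    ]
    return Landscape(zones=zones, extent=box(0, 0, 1300, 700))


def make_individuals(xy, session=1, zone="HB", demo_class="MA",
                     in_pouch=None, ids=None):
    xy = np.asarray(xy, float)
    n = len(xy)
    return pd.DataFrame(
        {
            "session": session,
            "id": ids if ids is not None else np.arange(n),
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
            "zone": zone,
            "demo_class": ([demo_class] * n if isinstance(demo_class, str)
                           else list(demo_class)),
            "in_pouch": in_pouch if in_pouch is not None else 0,
            "disturbed": 0,
        }
    )


@pytest.fixture()
def individuals_factory():
    return make_individuals
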