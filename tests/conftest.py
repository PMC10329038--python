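from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from hiveburst import synthetic_hive as sh
from hiveburst.tracking_io import TrackingTable, TrialMetadata, from_dataframe


def make_meta(T_total=3600, entrance_open_t=None, **kw) -> TrialMetadata:
    kw.setdefault("trial_id", "test")
    kw.setdefault("start_datetime", datetime(2012, 7, 4, 6, 0, 0))
    if entrance_open_t is None:
        entrance_open_t = min(600, max(1, T_total // 2))
    return TrialMetadata(
        entrance_open_t=entrance_open_t, T_total=T_total, **kw
    )


def make_table(rows, meta=None) -> TrackingTable:
    """rows: iterable of (bee_id, t, x, y, nx, ny)."""
    df = pd.DataFrame(rows, columns=["bee_id", "t", "x", "y", "nx", "ny"])
    return from_dataframe(df, meta or make_meta())


def walk_rows(bee_id, times, rng, x0=500.0, y0=500.0, step=3.0, turn=0.2):
    """Correlated-random-walk rows for one bee at the given times."""
    theta = rng.uniform(-np.pi, np.pi)
    x, y = x0, y0
    rows = []
    for t in times:
        theta += rng.normal(0, turn)
        r = abs(rng.normal(0, step))
        x = float(np.clip(x + r * np.cos(theta), 0, 6576))
        y = float(np.clip(y + r * np.sin(theta), 0, 4384))
        rows.append((bee_id, int(t), x, y, float(np.cos(theta)), float(np.sin(theta))))
    return rows


@pytest.fixture(scope="session")
def dance_demo():
    cfg = sh.preset_config("dance_demo", seed=0)
    table, gt = sh.simulate(cfg, seed=0)
    return cfg, table, gt


@pytest.fixture(scope="session")
def pioneer_demo():
    cfg = sh.preset_config("pioneer_recovery", seed=1)
    table, gt = sh.simulate(cfg, seed=1)
    return cfg, table, gt
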