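import pandas as pd
import pytest

import fleetsentinel as fs


@pytest.fixture(scope="session")
def small_bundle():
    """4-year, 8-vessel scenario with one heatwave year; fast enough for units."""
    cfg = fs.ScenarioConfig(years=(2018, 2021), n_vessels=8, heatwave_years=(2020,), seed=5)
    return fs.gen_scenario(cfg)


@pytest.fixture(scope="session")
def small_linked(small_bundle):
    return fs.link(small_bundle.pings, small_bundle.receipts, trip_cap=16)


@pytest.fixture(scope="session")
def signal_bundle():
    """Full 15-year study-like scenario: heatwave years 2014-2016, northward
    habitat shifts, fleet tracking habitat with weight 0.8."""
    return fs.gen_scenario(fs.ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def null_bundle():
    """Same fleet and record length but no heatwave forcing or habitat shifts."""
    cfg = fs.ScenarioConfig(
        seed=7, ssta_amplitude=0.0, habitat_shift_lat=0.0, habitat_shift_shore=0.0,
        cpue_heatwave_factor=1.0,
    )
    return fs.gen_scenario(cfg)


def pipeline_y_series(bundle):
    """linkage -> processed vms_y and albacore habitat_y series."""
    linked = fs.link(bundle.pings, bundle.receipts, trip_cap=16)
    return fs.indicators.build_indicators(
        linked, habitat=bundle.habitat, coastline=bundle.coastline, eez=bundle.eez,
        compute=["vms_y", "habitat_y:albacore"],
    )


@pytest.fixture(scope="session")
def signal_y(signal_bundle):
    return pipeline_y_series(signal_bundle)


@pytest.fixture(scope="session")
def null_y(null_bundle):
    return pipeline_y_series(null_bundle)


def make_pings(rows):
    """Small ping frame from dicts with defaults filled in."""
    defaults = dict(vessel_id="V1", lat=44.0, lon=-126.0, event_type="at_sea",
                    time_forward=60.0, speed=2.0, gis_flag=False)
    recs = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        recs.append(d)
    df = pd.DataFrame(recs)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_receipts(rows):
    defaults = dict(vessel_id="V1", species="albacore", pounds=1000.0, price_per_pound=2.5)
    recs = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        recs.append(d)
    df = pd.DataFrame(recs)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df
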