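"""Shared fixtures: hand-built toy datasets and a small simulated study."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

import telemeshare as tm

TZ = "Africa/Johannesburg"


def make_receivers(specs):
    """specs: list of (receiver_id, longitude, zone)."""
    rows = []
    for rid, lon, zone in specs:
        rows.append(
            {
                "receiver_id": rid,
                "longitude": lon,
                "latitude": -33.9,
                "depth_m": 20.0,
                "zone": zone,
                "active_start": dt.date(2010, 1, 1),
                "active_end": dt.date(2021, 1, 1),
                "region": tm.assign_region(lon, (25.85, 26.25)),
            }
        )
    return pd.DataFrame(rows)


def make_tags(specs, study_end="2020-12-31"):
    """specs: list of dicts with at least transmitter_id, species, tag_date."""
    rows = []
    for spec in specs:
        row = {
            "transmitter_id": spec["transmitter_id"],
            "species": spec.get("species", "C_taurus"),
            "life_stage": spec.get("life_stage", "adult"),
            "length_mm": spec.get("length_mm", 2000.0),
            "tag_date": pd.to_datetime(spec["tag_date"]).date(),
            "tag_region": spec.get("tag_region", "coastal"),
            "battery_expiry": pd.to_datetime(
                spec.get("battery_expiry", "2030-01-01")
            ).date(),
            "recapture_date": pd.to_datetime(spec["recapture_date"]).date()
            if spec.get("recapture_date")
            else None,
            "last_outside_detection": pd.to_datetime(
                spec["last_outside_detection"]
            ).date()
            if spec.get("last_outside_detection")
            else None,
            "study_end": pd.to_datetime(spec.get("study_end", study_end)).date(),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def make_detections(rows):
    """rows: list of (timestamp string, transmitter_id, receiver_id)."""
    df = pd.DataFrame(rows, columns=["timestamp", "transmitter_id", "receiver_id"])
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.tz_localize(TZ)
    return df.sort_values("timestamp", ignore_index=True)


def build_dataset(det, tags, receivers, min_days=1):
    return tm.filter_dataset(det, tags, receivers, min_days=min_days)


SMALL_SCENARIO = tm.Scenario(
    n_receivers=12,
    study_span=("2014-01-01", "2015-12-31"),
    n_individuals={
        ("A_japonicus", "adult"): 6,
        ("L_amia", "adult"): 6,
        ("C_taurus", "subadult"): 8,
        ("C_carcharias", "juvenile"): 8,
    },
    seed=11,
)


@pytest.fixture(scope="session")
def sim_result():
    return tm.simulate_detections(SMALL_SCENARIO)


@pytest.fixture(scope="session")
def sim_dataset(sim_result):
    det, tags, receivers, _ = sim_result
    return tm.filter_dataset(det, tags, receivers, min_days=10)
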