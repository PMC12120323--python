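"""Ingest and filter raw acoustic-telemetry tables.

Three CSV inputs in the style of receiver-download exports:

* ``detections.csv`` — ``timestamp,transmitter_id,receiver_id`` (ISO-8601);
* ``receivers.csv`` — ``receiver_id,longitude,latitude,depth_m,zone,
  active_start,active_end``;
* ``tags.csv`` — ``transmitter_id,species,life_stage,length_mm,tag_date,
  tag_region,battery_expiry,recapture_date,last_outside_detection``.

Filtering applies the study's inclusion rules: estuary receivers (and their
detections) are dropped, detections are clamped to each individual's
monitoring window, and individuals detected on fewer than ``min_days``
distinct days on marine receivers are removed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    LIFE_STAGES,
    SPECIES,
    TAG_REGIONS,
    ZONES,
    AnalysisConfig,
    assign_region,
)

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ("timestamp", "transmitter_id", "receiver_id")


class ValidationError(ValueError):
    """A fatal problem with an input table."""


@dataclasses.dataclass
class FilteredDataset:
    """Clean analysis dataset after inclusion filtering.

    Attributes
    ----------
    detections
        Retained detections (timestamp tz-aware, plus ``date`` column in the
        analysis timezone).
    tags
        Tag metadata for retained individuals only, with derived
        ``monitoring_end`` and ``days_monitored`` columns.
    receivers
        Marine receivers only.
    exclusion_log
        One row per excluded individual: ``transmitter_id, reason``.
        Reasons partition the excluded set.
    dropped_detection_counts
        Per-reason counts of detections removed (unknown transmitter,
        unknown receiver, estuary receiver, outside monitoring window).
    """

    detections: pd.DataFrame
    tags: pd.DataFrame
    receivers: pd.DataFrame
    exclusion_log: pd.DataFrame
    dropped_detection_counts: dict[str, int]

    @property
    def individuals(self) -> list[str]:
        return list(self.tags["transmitter_id"])


def load_detections(path: str | Path, tz: str = "Africa/Johannesburg") -> pd.DataFrame:
    """Read a detection log CSV into a chronologically sorted frame.

    Malformed rows (blank IDs, unparseable timestamps) are counted and
    reported via ``df.attrs['n_rejected']`` and the log, not silently
    dropped.  More than 1% unparseable timestamps is treated as a corrupt
    export and raises.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in DETECTION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"detection log missing column(s): {missing}")

    n_in = len(raw)
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True, format="ISO8601")
    n_bad_ts = int(ts.isna().sum())
    if n_in and n_bad_ts / n_in > 0.01:
        raise ValidationError(
            f"{n_bad_ts}/{n_in} timestamps unparseable (>1%); refusing to continue"
        )
    ids_ok = (
        raw["transmitter_id"].notna()
        & (raw["transmitter_id"].str.strip() != "")
        & raw["receiver_id"].notna()
        & (raw["receiver_id"].str.strip() != "")
    )
    keep = ts.notna() & ids_ok
    out = pd.DataFrame(
        {
            "timestamp": ts[keep].dt.tz_convert(tz),
            "transmitter_id": raw.loc[keep, "transmitter_id"].str.strip(),
            "receiver_id": raw.loc[keep, "receiver_id"].str.strip(),
        }
    ).sort_values("timestamp", kind="mergesort", ignore_index=True)
    n_rejected = n_in - len(out)
    if n_rejected:
        logger.warning("detections: rejected %d of %d malformed rows", n_rejected, n_in)
    out.attrs["n_rejected"] = n_rejected
    out.attrs["n_input_rows"] = n_in
    return out


def load_receivers(
    path: str | Path, region_breaks: tuple[float, float] = (25.85, 26.25)
) -> pd.DataFrame:
    """Read receiver metadata and assign west/central/east regions.

    Region assignment is deterministic from longitude with a half-open
    convention (a receiver exactly at the first break is central).
    """
    df = pd.read_csv(path)
    required = {
        "receiver_id",
        "longitude",
        "latitude",
        "depth_m",
        "zone",
        "active_start",
        "active_end",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"receiver table missing column(s): {sorted(missing)}")
    df["receiver_id"] = df["receiver_id"].astype(str)
    if df["receiver_id"].duplicated().any():
        dup = df.loc[df["receiver_id"].duplicated(), "receiver_id"].tolist()
        raise ValidationError(f"duplicate receiver_id(s): {dup}")
    bad_zone = ~df["zone"].isin(ZONES)
    if bad_zone.any():
        raise ValidationError(
            f"invalid zone value(s): {sorted(df.loc[bad_zone, 'zone'].unique())}"
        )
    if (df["depth_m"].astype(float) < 0).any():
        raise ValidationError("negative receiver depth")
    df["active_start"] = pd.to_datetime(df["active_start"]).dt.date
    df["active_end"] = pd.to_datetime(df["active_end"]).dt.date
    if (pd.Series(df["active_start"]) >= pd.Series(df["active_end"])).any():
        raise ValidationError("receiver active_interval must have start < end")
    df["region"] = [assign_region(lon, region_breaks) for lon in df["longitude"]]
    return df


def load_tags(path: str | Path, study_end: "pd.Timestamp | str") -> pd.DataFrame:
    """Read tag metadata; validates enums and date ordering."""
    df = pd.read_csv(path, dtype={"transmitter_id": str})
    required = {
        "transmitter_id",
        "species",
        "life_stage",
        "length_mm",
        "tag_date",
        "tag_region",
        "battery_expiry",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"tag table missing column(s): {sorted(missing)}")
    if df["transmitter_id"].duplicated().any():
        raise ValidationError("duplicate transmitter_id in tag table")
    for col, allowed in (
        ("species", SPECIES),
        ("life_stage", LIFE_STAGES),
        ("tag_region", TAG_REGIONS),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            raise ValidationError(
                f"invalid {col} value(s): {sorted(df.loc[bad, col].unique())}"
            )
    if (df["length_mm"].astype(float) <= 0).any():
        raise ValidationError("length_mm must be positive")
    for col in ("tag_date", "battery_expiry", "recapture_date", "last_outside_detection"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], errors="raise").dt.date
        else:
            df[col] = pd.NaT
    if (pd.Series(df["tag_date"]) >= pd.Series(df["battery_expiry"])).any():
        raise ValidationError("tag_date must precede battery_expiry")
    recap = df["recapture_date"].notna()
    if (df.loc[recap, "recapture_date"] < df.loc[recap, "tag_date"]).any():
        raise ValidationError("recapture_date before tag_date")
    df["study_end"] = pd.to_datetime(study_end).date()
    return df


def monitoring_end(tag: "pd.Series | dict") -> "object":
    """End of an individual's monitoring window.

    The minimum of: study end, recapture date, battery expiry, and the
    last known detection outside the bay — absent fields are ignored.
    """
    candidates = [tag["study_end"], tag["battery_expiry"]]
    for key in ("recapture_date", "last_outside_detection"):
        val = tag.get(key) if isinstance(tag, dict) else tag.get(key, None)
        if val is not None and not pd.isna(val):
            candidates.append(val)
    end = min(candidates)
    if end < tag["tag_date"]:
        raise ValidationError(
            f"monitoring_end {end} precedes tag_date {tag['tag_date']} "
            f"for {tag['transmitter_id']}"
        )
    return end


def filter_dataset(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    receivers: pd.DataFrame,
    min_days: int = 10,
    config: AnalysisConfig | None = None,
) -> FilteredDataset:
    """Apply the study's inclusion filters.

    Order of operations: unknown transmitter IDs dropped (logged, not
    fatal — untagged animals and false detections are routine in field
    data); estuary receivers and their detections removed; detections
    outside each individual's ``[tag_date, monitoring_end]`` removed;
    finally individuals with fewer than ``min_days`` distinct detection
    days removed (exactly ``min_days`` is retained).
    """
    config = config or AnalysisConfig(min_days=min_days)
    dropped: dict[str, int] = {}

    det = detections.copy()
    known_tx = det["transmitter_id"].isin(tags["transmitter_id"])
    dropped["unknown_transmitter"] = int((~known_tx).sum())
    det = det[known_tx]

    known_rx = det["receiver_id"].isin(receivers["receiver_id"])
    dropped["unknown_receiver"] = int((~known_rx).sum())
    det = det[known_rx]

    marine = receivers[receivers["zone"] == "marine"].reset_index(drop=True)
    on_marine = det["receiver_id"].isin(marine["receiver_id"])
    dropped["estuary_receiver"] = int((~on_marine).sum())
    det = det[on_marine].copy()

    tags = tags.copy()
    tags["monitoring_end"] = [monitoring_end(row) for _, row in tags.iterrows()]
    extra = 1 if config.inclusive_days else 0
    tags["days_monitored"] = [
        (e - s).days + extra for s, e in zip(tags["tag_date"], tags["monitoring_end"])
    ]
    if (tags["days_monitored"] <= 0).any():
        raise ValidationError("individual with non-positive monitoring duration")

    det["date"] = det["timestamp"].dt.date
    windows = tags.set_index("transmitter_id")[["tag_date", "monitoring_end"]]
    start = det["transmitter_id"].map(windows["tag_date"])
    end = det["transmitter_id"].map(windows["monitoring_end"])
    in_window = (det["date"] >= start) & (det["date"] <= end)
    dropped["outside_monitoring_window"] = int((~in_window).sum())
    det = det[in_window].reset_index(drop=True)

    day_counts = det.groupby("transmitter_id")["date"].nunique()
    n_days = tags["transmitter_id"].map(day_counts).fillna(0).astype(int)
    retained = n_days >= config.min_days
    reasons = np.where(n_days == 0, "no_marine_detections", "below_min_days")
    exclusion_log = pd.DataFrame(
        {
            "transmitter_id": tags.loc[~retained, "transmitter_id"],
            "reason": reasons[~retained],
            "n_detection_days": n_days[~retained],
        }
    ).reset_index(drop=True)

    kept_tags = tags[retained].reset_index(drop=True)
    if kept_tags.empty:
        raise ValidationError(
            "no individuals retained after filtering "
            f"(min_days={config.min_days}, {len(tags)} tagged)"
        )
    det = det[det["transmitter_id"].isin(kept_tags["transmitter_id"])].reset_index(
        drop=True
    )
    for reason, n in dropped.items():
        if n:
            logger.info("filter: dropped %d detections (%s)", n, reason)
    logger.info(
        "filter: retained %d/%d individuals, %d detections",
        len(kept_tags),
        len(tags),
        len(det),
    )
    return FilteredDataset(
        detections=det,
        tags=kept_tags,
        receivers=marine,
        exclusion_log=exclusion_log,
        dropped_detection_counts=dropped,
    )


def cohort_summary(dataset: FilteredDataset, all_tags: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum bookkeeping: how many tagged vs retained.

    One row per species x life stage present in the tag table, plus an
    ``overall`` row.  ``pct_retained`` is rounded to the nearest integer,
    matching how such tables are conventionally printed.
    """
    retained_ids = set(dataset.tags["transmitter_id"])
    rows = []
    for (sp, stage), grp in all_tags.groupby(["species", "life_stage"], sort=True):
        n_tagged = len(grp)
        if n_tagged == 0:
            logger.warning("cohort_summary: empty stratum %s/%s omitted", sp, stage)
            continue
        n_ret = int(grp["transmitter_id"].isin(retained_ids).sum())
        rows.append(
            {
                "species": sp,
                "life_stage": stage,
                "n_tagged": n_tagged,
                "n_retained": n_ret,
                "pct_retained": _round_half_up(100 * n_ret / n_tagged),
            }
        )
    n_tagged = len(all_tags)
    n_ret = int(all_tags["transmitter_id"].isin(retained_ids).sum())
    rows.append(
        {
            "species": "overall",
            "life_stage": "overall",
            "n_tagged": n_tagged,
            "n_retained": n_ret,
            "pct_retained": _round_half_up(100 * n_ret / n_tagged),
        }
    )
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))
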