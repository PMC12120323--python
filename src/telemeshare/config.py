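"""Analysis configuration shared across the pipeline.

All timestamp handling converts to a single timezone before calendar-day
binning (detection indices are ratios of day counts, so the choice of day
boundary matters). The default is South African Standard Time (UTC+02:00,
no DST), the local time of the Algoa Bay array.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

#: canonical species codes used throughout the package
SPECIES = ("A_japonicus", "L_amia", "C_taurus", "C_carcharias")
LIFE_STAGES = ("juvenile", "subadult", "adult", "unknown")
ZONES = ("marine", "estuary")
REGIONS = ("west", "central", "east")
TAG_REGIONS = ("estuary", "coastal")


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide settings.

    Parameters
    ----------
    tz
        IANA timezone name used for all day binning.
    region_breaks
        Two longitudes (degrees E) splitting the receiver array into
        west / central / east.  Half-open convention: ``lon < break1`` is
        west, ``break1 <= lon < break2`` is central, else east.  Defaults
        partition Algoa Bay (Cape Recife ~25.7 E to Cape Padrone ~26.5 E)
        into rough thirds.
    min_days
        Minimum number of distinct marine detection days for an individual
        to be retained ("fewer than N days" are removed, so exactly N is
        kept).
    inclusive_days
        If True (default) the monitored-day count includes both the tagging
        day and the end day: ``(end - tag_date).days + 1``.  If False the
        tagging day is excluded.
    """

    tz: str = "Africa/Johannesburg"
    region_breaks: tuple[float, float] = (25.85, 26.25)
    min_days: int = 10
    inclusive_days: bool = True

    def __post_init__(self) -> None:
        b1, b2 = self.region_breaks
        if not b1 < b2:
            raise ValueError("region_breaks must be increasing")
        if self.min_days < 1:
            raise ValueError("min_days must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "region_breaks" in raw:
            raw["region_breaks"] = tuple(raw["region_breaks"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["region_breaks"] = list(data["region_breaks"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def assign_region(longitude: float, region_breaks: tuple[float, float]) -> str:
    """Deterministic west/central/east assignment from longitude."""
    b1, b2 = region_breaks
    if longitude < b1:
        return "west"
    if longitude < b2:
        return "central"
    return "east"
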