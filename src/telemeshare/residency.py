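"""Residency metrics and nonparametric group comparisons.

Two detection indices are computed per individual:

* ``di_total`` — distinct detection days as a proportion of the full
  monitoring window (tagging to study end / recapture / battery expiry /
  last known detection elsewhere, whichever comes first);
* ``di_bay`` — the same numerator over the days at liberty up to the last
  in-bay detection, a measure of residency *while using* the bay.

Because the ``di_bay`` denominator can never exceed the ``di_total`` one,
``di_total <= di_bay`` holds for every individual.

Group differences are tested nonparametrically: Mann-Whitney U for two
groups, Kruskal-Wallis for three or more with Dunn's post hoc z tests and
Benjamini-Hochberg adjustment of the pairwise p-values.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_ingest import FilteredDataset


@dataclasses.dataclass
class GroupComparison:
    test: str  # "kruskal_wallis" or "mann_whitney"
    statistic: float
    df: int | None
    p_value: float
    posthoc: pd.DataFrame | None  # columns: group_a, group_b, z, p_raw, p_adjusted


def detection_days(dataset: FilteredDataset, individual: str) -> set:
    """Distinct calendar dates (analysis timezone) with >= 1 marine detection."""
    if individual not in set(dataset.tags["transmitter_id"]):
        raise KeyError(f"unknown individual {individual!r}")
    det = dataset.detections
    return set(det.loc[det["transmitter_id"] == individual, "date"])


def detection_indices(dataset: FilteredDataset) -> pd.DataFrame:
    """Per-individual residency summary.

    Returns one row per retained individual with ``n_detection_days``,
    ``days_monitored_total``, ``days_to_last_bay_detection``, ``di_total``
    and ``di_bay``.  Day counts are whole days including the tagging day
    (see :class:`~telemeshare.config.AnalysisConfig.inclusive_days`).
    """
    det = dataset.detections
    per = det.groupby("transmitter_id")["date"].agg(["nunique", "max"])
    rows = []
    for row in dataset.tags.itertuples(index=False):
        tx = row.transmitter_id
        n_days = int(per.loc[tx, "nunique"])
        last = per.loc[tx, "max"]
        days_total = int(row.days_monitored)
        extra = days_total - (row.monitoring_end - row.tag_date).days  # 0 or 1
        days_bay = (last - row.tag_date).days + extra
        if days_total <= 0 or days_bay <= 0:
            raise ValueError(f"non-positive day denominator for {tx}")
        rows.append(
            {
                "transmitter_id": tx,
                "species": row.species,
                "life_stage": row.life_stage,
                "tag_region": row.tag_region,
                "n_detection_days": n_days,
                "days_monitored_total": days_total,
                "days_to_last_bay_detection": days_bay,
                "di_total": n_days / days_total,
                "di_bay": n_days / days_bay,
            }
        )
    return pd.DataFrame(rows)


def monthly_detection_table(dataset: FilteredDataset) -> pd.DataFrame:
    """Days detected per individual per calendar month.

    One row for every calendar month overlapping the individual's
    monitoring window (months with zero detections included);
    ``days_in_month`` is the full calendar length of the month, matching
    the month-length offset used by the seasonal model.
    """
    det = dataset.detections
    counts = (
        det.assign(year=[d.year for d in det["date"]], month=[d.month for d in det["date"]])
        .groupby(["transmitter_id", "year", "month"])["date"]
        .nunique()
    )
    rows = []
    for row in dataset.tags.itertuples(index=False):
        period = pd.period_range(row.tag_date, row.monitoring_end, freq="M")
        for per in period:
            n = int(counts.get((row.transmitter_id, per.year, per.month), 0))
            dim = per.days_in_month
            rows.append(
                {
                    "transmitter_id": row.transmitter_id,
                    "species": row.species,
                    "life_stage": row.life_stage,
                    "year": per.year,
                    "month": per.month,
                    "days_detected": n,
                    "days_in_month": dim,
                    "monthly_di": n / dim,
                }
            )
    return pd.DataFrame(rows)


def daily_detection_matrix(dataset: FilteredDataset) -> pd.DataFrame:
    """Long-format individual x date x region presence table.

    One row per (individual, date, region) with at least one detection —
    the data behind a daily-detection plot colour-coded by bay region.
    """
    det = dataset.detections.merge(
        dataset.receivers[["receiver_id", "region"]], on="receiver_id", how="left"
    )
    out = (
        det.groupby(["transmitter_id", "date", "region"], sort=True)
        .size()
        .rename("n_detections")
        .reset_index()
    )
    return out


def _dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's pairwise z tests on ranks with tie-corrected variance."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    labels = np.unique(groups)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    n_g = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / n_g[a] + 1.0 / n_g[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def compare_groups(
    values, groups, posthoc: bool = True
) -> GroupComparison:
    """Nonparametric comparison of a metric across groups.

    Two groups: Mann-Whitney U (asymptotic, tie-corrected).  Three or
    more: Kruskal-Wallis with chi-squared reference (df = k - 1), followed
    (optionally) by Dunn's test with Benjamini-Hochberg adjustment.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("each group needs n >= 2")
    samples = [values[groups == g] for g in labels]
    if len(np.unique(values)) == 1:
        # zero rank variance: defined degenerate result
        return GroupComparison(
            test="kruskal_wallis" if len(labels) > 2 else "mann_whitney",
            statistic=0.0,
            df=len(labels) - 1 if len(labels) > 2 else None,
            p_value=1.0,
            posthoc=None,
        )
    if len(labels) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], method="asymptotic")
        return GroupComparison(
            test="mann_whitney",
            statistic=float(res.statistic),
            df=None,
            p_value=float(res.pvalue),
            posthoc=None,
        )
    stat, p = stats.kruskal(*samples)
    ph = _dunn_posthoc(values, groups) if posthoc else None
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(stat),
        df=len(labels) - 1,
        p_value=float(p),
        posthoc=ph,
    )


def residency_summary_stats(indices: pd.DataFrame, by: str = "species") -> pd.DataFrame:
    """Mean / median / quartile summary of both detection indices per group."""
    q25 = lambda s: s.quantile(0.25)  # noqa: E731
    q75 = lambda s: s.quantile(0.75)  # noqa: E731
    q25.__name__, q75.__name__ = "q25", "q75"
    out = indices.groupby(by)[["di_total", "di_bay"]].agg(
        ["mean", "median", "min", "max", q25, q75]
    )
    out.columns = [f"{metric}_{stat}" for metric, stat in out.columns]
    return out.reset_index()
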