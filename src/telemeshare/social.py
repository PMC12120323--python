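"""Co-occurrence social networks under the gambit of the group.

Individuals detected at the same receiver within the same clock-aligned
hour bin are assumed to be associated ("gambit of the group").  Pairwise
association strength is the simple-ratio index

    SRI = x / (x + y_AB + y_A + y_B)

where, over all sampling periods (hour bins) in which at least one of the
pair was observed: ``x`` counts periods with both in the same group,
``y_AB`` periods with both observed but never together (e.g. at different
receivers), and ``y_A`` / ``y_B`` periods with only one observed.  SRI is
0 for pairs never co-occurring and 1 for pairs co-occurring whenever
either was seen.

Trait assortment (do conspecifics associate preferentially?) is the
weighted categorical assortativity coefficient

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i)

with ``e_ij`` the fraction of total edge weight between classes ``i`` and
``j`` (both directions counted) and ``a``, ``b`` its margins.  Its
significance is assessed by node permutation: trait labels are shuffled
across nodes (network fixed), and the p-value is the fraction of permuted
coefficients at least as assortative as the observed one (one-tailed by
default, +1 correction applied).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .io_ingest import FilteredDataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AssociationNetwork:
    """Individuals, their traits, and the SRI weight matrix."""

    individuals: list[str]
    traits: pd.DataFrame  # indexed by transmitter_id; columns species, life_stage
    sri: pd.DataFrame  # symmetric, zero diagonal, entries in [0, 1]
    counts: dict[str, pd.DataFrame]  # "x", "y_ab", "y_a", "y_b"
    zero_denominator_pairs: list[tuple[str, str]]


@dataclasses.dataclass
class AssortativityResult:
    trait: str
    observed_r: float
    permuted_r: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None


def group_by_window(
    dataset: FilteredDataset,
    start=None,
    end=None,
    window: str = "1h",
) -> pd.DataFrame:
    """Bucket detections into (hour bin, receiver) grouping events.

    Bins are consecutive, non-overlapping and clock-aligned; the returned
    frame has one row per (bin, receiver) with the member set and the
    global sampling-period index of the bin.
    """
    det = dataset.detections
    if start is not None:
        start_ts = pd.Timestamp(start)
        if start_ts.tz is None:
            start_ts = start_ts.tz_localize(det["timestamp"].dt.tz)
        det = det[det["timestamp"] >= start_ts]
    if end is not None:
        end_ts = pd.Timestamp(end)
        if end_ts.tz is None:
            end_ts = end_ts.tz_localize(dataset.detections["timestamp"].dt.tz)
        det = det[det["timestamp"] < end_ts]
    if det.empty:
        raise ValueError("no detections in the requested period")
    bins = det["timestamp"].dt.floor(window)
    grouped = (
        det.assign(bin=bins)
        .groupby(["bin", "receiver_id"])["transmitter_id"]
        .agg(lambda s: frozenset(s))
        .rename("members")
        .reset_index()
    )
    period_index = {b: i for i, b in enumerate(sorted(grouped["bin"].unique()))}
    grouped["sampling_period"] = grouped["bin"].map(period_index)
    return grouped


def simple_ratio_index(
    groups: pd.DataFrame,
    individuals: list[str] | None = None,
    traits: pd.DataFrame | None = None,
) -> AssociationNetwork:
    """Pairwise simple-ratio association indices from grouping events.

    ``individuals`` defaults to everyone appearing in ``groups``; an
    individual detected at two receivers within one bin counts as
    "observed" once in that period, and a pair seen at different
    receivers (never together) in a period contributes to ``y_AB`` once.
    """
    if individuals is None:
        individuals = sorted({m for ms in groups["members"] for m in ms})
    individuals = list(individuals)
    n = len(individuals)
    if n < 2:
        raise ValueError("need at least two individuals")
    idx = {t: i for i, t in enumerate(individuals)}

    periods = groups.groupby("sampling_period")
    seen = np.zeros((periods.ngroups, n), dtype=bool)  # observed in period
    together = {}  # (i, j) -> set of periods co-grouped
    for row_p, (_, grp) in enumerate(periods):
        for members in grp["members"]:
            ms = [idx[m] for m in members if m in idx]
            for i in ms:
                seen[row_p, i] = True
            ms.sort()
            for a in range(len(ms)):
                for b in range(a + 1, len(ms)):
                    together.setdefault((ms[a], ms[b]), set()).add(row_p)

    seen_f = seen.astype(float)
    both_seen = seen_f.T @ seen_f  # periods with both observed
    either_seen = seen.sum(axis=0)[:, None] + seen.sum(axis=0)[None, :] - both_seen
    x = np.zeros((n, n))
    for (i, j), pers in together.items():
        x[i, j] = x[j, i] = len(pers)
    y_ab = both_seen - x
    only = seen_f.sum(axis=0)
    y_a = only[:, None] - both_seen  # periods with A but not B
    y_b = only[None, :] - both_seen

    denom = x + y_ab + y_a + y_b  # == either_seen
    with np.errstate(divide="ignore", invalid="ignore"):
        sri = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sri, 0.0)
    zero_pairs = [
        (individuals[i], individuals[j])
        for i in range(n)
        for j in range(i + 1, n)
        if denom[i, j] == 0
    ]
    if zero_pairs:
        logger.info("%d pair(s) share no sampling periods (SRI set to 0)", len(zero_pairs))

    def _df(mat):
        return pd.DataFrame(mat, index=individuals, columns=individuals)

    if traits is not None:
        traits = traits.loc[individuals]
    return AssociationNetwork(
        individuals=individuals,
        traits=traits,
        sri=_df(sri),
        counts={
            "x": _df(x),
            "y_ab": _df(y_ab),
            "y_a": _df(y_a),
            "y_b": _df(y_b),
        },
        zero_denominator_pairs=zero_pairs,
    )


def _mixing_r(W: np.ndarray, codes: np.ndarray, n_classes: int) -> float:
    L = np.zeros((len(codes), n_classes))
    L[np.arange(len(codes)), codes] = 1.0
    E = L.T @ W @ L
    total = E.sum()
    if total <= 0:
        raise ValueError("empty network (all edge weights zero)")
    E /= total
    a = E.sum(axis=1)
    b = E.sum(axis=0)
    ab = float(a @ b)
    if np.isclose(ab, 1.0):
        # all edge weight inside a single class: the fully assortative limit
        return 1.0
    return float((np.trace(E) - ab) / (1.0 - ab))


def assortativity(net: AssociationNetwork, trait) -> float:
    """Weighted categorical assortativity of the association network.

    ``trait`` is either a column name of ``net.traits`` or a label vector
    aligned with ``net.individuals``.
    """
    labels = _trait_labels(net, trait)
    codes, n_classes = _codes(labels)
    if n_classes < 2:
        raise ValueError("need at least two trait classes")
    W = net.sri.to_numpy(dtype=float)
    return _mixing_r(W, codes, n_classes)


def _trait_labels(net: AssociationNetwork, trait) -> np.ndarray:
    if isinstance(trait, str):
        if net.traits is None or trait not in net.traits.columns:
            raise KeyError(f"trait {trait!r} not available")
        return net.traits[trait].to_numpy()
    labels = np.asarray(trait)
    if len(labels) != len(net.individuals):
        raise ValueError("trait vector length mismatch")
    return labels


def _codes(labels: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, len(uniq)


def node_permutation_test(
    net: AssociationNetwork,
    trait,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
) -> AssortativityResult:
    """Node-permutation null for the assortativity coefficient.

    Trait labels are shuffled over nodes (label multiset and network
    fixed) ``n_perm`` times; with the default one-tailed alternative the
    p-value is ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    labels = _trait_labels(net, trait)
    codes, n_classes = _codes(labels)
    if n_classes < 2:
        raise ValueError("trait is constant; nothing to permute")
    W = net.sri.to_numpy(dtype=float)
    r_obs = _mixing_r(W, codes, n_classes)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        permuted[i] = _mixing_r(W, rng.permutation(codes), n_classes)
    if alternative == "greater":
        exceed = int((permuted >= r_obs - 1e-12).sum())
    elif alternative == "two-sided":
        exceed = int((np.abs(permuted) >= abs(r_obs) - 1e-12).sum())
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = (1.0 + exceed) / (1.0 + n_perm)
    return AssortativityResult(
        trait=trait if isinstance(trait, str) else "custom",
        observed_r=r_obs,
        permuted_r=permuted,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


def build_association_network(
    dataset: FilteredDataset,
    start=None,
    end=None,
    window: str = "1h",
) -> AssociationNetwork:
    """End-to-end: hour-bin grouping then SRI, with traits attached.

    Individuals with no detections in the period are dropped from the
    network (only detected animals appear as nodes).
    """
    groups = group_by_window(dataset, start=start, end=end, window=window)
    traits = dataset.tags.set_index("transmitter_id")[["species", "life_stage"]]
    detected = sorted({m for ms in groups["members"] for m in ms})
    return simple_ratio_index(groups, individuals=detected, traits=traits)
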