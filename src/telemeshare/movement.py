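"""Movement networks over receivers and spatial-segregation testing.

Movement networks treat receivers as nodes; an edge is added (weight
incremented) whenever an individual's consecutive detections fall at two
distinct receivers within a 24-h window.  Node density is the fraction of
deployed receivers visited; edge density is the fraction of all unordered
receiver pairs realized — both use the full deployed array as the
denominator so individuals are comparable.

Spatial segregation is tested with a PERMANOVA on the Euclidean distances
between per-individual receiver-use profiles (each individual's detections
as proportions per receiver).  Sums of squares are sequential (Type I) in
the given term order on the Gower-centred inner-product matrix, pseudo-F
per term uses the residual mean square, and p-values come from free
permutation of observations.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import orth
from scipy.spatial.distance import pdist, squareform

from .io_ingest import FilteredDataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MovementNetwork:
    """Receiver graph for one individual or one aggregate group."""

    graph: nx.Graph  # weighted; nodes are visited receivers
    array_nodes: list[str]  # all deployed (marine) receivers
    owner: str
    detection_counts: pd.Series | None = None  # per-receiver, for node sizing

    @property
    def visited_nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "weight": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


@dataclasses.dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA table."""

    table: pd.DataFrame  # term, df, SS, MS, F, R2, p
    n_permutations: int
    seed: int | None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(n_perm={self.n_permutations})\n{self.table}"


def build_movement_network(
    dataset: FilteredDataset,
    individual: str,
    window: pd.Timedelta = pd.Timedelta(hours=24),
    directed: bool = False,
) -> MovementNetwork:
    """Transition network for one individual.

    Consecutive detections at distinct receivers separated by at most
    ``window`` add 1 to that receiver pair's weight; consecutive
    detections at the same receiver add nothing.
    """
    if individual not in set(dataset.tags["transmitter_id"]):
        raise KeyError(f"unknown individual {individual!r}")
    det = dataset.detections
    sub = det[det["transmitter_id"] == individual].sort_values("timestamp")
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    rx = sub["receiver_id"].to_numpy()
    ts = sub["timestamp"].to_numpy()
    g.add_nodes_from(np.unique(rx))
    for i in range(1, len(rx)):
        if rx[i] == rx[i - 1]:
            continue
        if (ts[i] - ts[i - 1]) > window.to_numpy():
            continue
        a, b = rx[i - 1], rx[i]
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    counts = sub.groupby("receiver_id").size()
    return MovementNetwork(
        graph=g,
        array_nodes=list(dataset.receivers["receiver_id"]),
        owner=individual,
        detection_counts=counts,
    )


def network_densities(net: MovementNetwork, array_size: int | None = None) -> dict:
    """Node and edge density against the deployed array.

    ``node_density = |visited| / array_size`` and
    ``edge_density = |edges| / C(array_size, 2)``.
    """
    array_size = array_size if array_size is not None else len(net.array_nodes)
    if array_size < 2:
        raise ValueError("array_size must be >= 2")
    n_visited = len(net.visited_nodes)
    if n_visited > array_size:
        raise ValueError("visited nodes exceed array size")
    n_possible_edges = array_size * (array_size - 1) // 2
    return {
        "node_density": n_visited / array_size,
        "edge_density": net.graph.number_of_edges() / n_possible_edges,
    }


def densities_table(dataset: FilteredDataset, **kwargs) -> pd.DataFrame:
    """Per-individual node/edge density table with traits attached."""
    rows = []
    for row in dataset.tags.itertuples(index=False):
        net = build_movement_network(dataset, row.transmitter_id, **kwargs)
        d = network_densities(net)
        rows.append(
            {
                "transmitter_id": row.transmitter_id,
                "species": row.species,
                "life_stage": row.life_stage,
                "n_nodes": len(net.visited_nodes),
                "n_edges": net.graph.number_of_edges(),
                **d,
            }
        )
    return pd.DataFrame(rows)


def aggregate_networks(
    nets: list[MovementNetwork], label: str = "aggregate"
) -> MovementNetwork:
    """Sum edge weights across networks (e.g. all individuals of a species).

    Per-receiver detection counts are summed as well and can be
    renormalized for node sizing in plots.
    """
    if not nets:
        raise ValueError("no networks to aggregate")
    g = nx.Graph()
    counts: pd.Series = pd.Series(dtype=float)
    for net in nets:
        g.add_nodes_from(net.graph.nodes)
        for a, b, d in net.graph.edges(data=True):
            if g.has_edge(a, b):
                g[a][b]["weight"] += d["weight"]
            else:
                g.add_edge(a, b, weight=d["weight"])
        if net.detection_counts is not None:
            counts = counts.add(net.detection_counts, fill_value=0)
    return MovementNetwork(
        graph=g,
        array_nodes=list(nets[0].array_nodes),
        owner=label,
        detection_counts=counts,
    )


def receiver_use_profiles(dataset: FilteredDataset) -> pd.DataFrame:
    """Per-individual proportion of detections at each deployed receiver.

    Rows are individuals, columns the full marine array; each row sums
    to 1 (receivers never visited get 0).
    """
    det = dataset.detections
    counts = (
        det.groupby(["transmitter_id", "receiver_id"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(
        index=dataset.tags["transmitter_id"],
        columns=dataset.receivers["receiver_id"],
        fill_value=0,
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"individual(s) with zero detections after filtering: {empty}")
    return counts.div(totals, axis=0)


# --------------------------------------------------------------------------
# PERMANOVA


def _term_columns(term: str, factors: pd.DataFrame) -> np.ndarray:
    """Full-rank-unreduced dummy expansion for one model term."""
    parts = term.split(":")
    for part in parts:
        if part not in factors.columns:
            raise ValueError(f"unknown factor {part!r} in term {term!r}")
    mats = []
    for part in parts:
        d = pd.get_dummies(factors[part], drop_first=True).to_numpy(float)
        mats.append(d)
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(out), -1)
    return out


def permanova(
    profiles: pd.DataFrame,
    factors: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    permutations: np.ndarray | None = None,
) -> PermanovaResult:
    """Permutational MANOVA on Euclidean distances between profiles.

    Parameters
    ----------
    profiles
        Observations x variables (e.g. receiver-use proportions); the
        distance matrix is Euclidean.
    factors
        One column per factor, aligned with ``profiles`` rows.
    terms
        Model terms in sequential (Type I) order; interactions as
        ``"a:b"``.  Defaults to all factor columns as main effects.
    n_perm, seed
        Number of free permutations of observations and the RNG seed.
    permutations
        Explicit permutation matrix (each row an index permutation);
        overrides ``n_perm``/``seed``, and the p-value becomes the exact
        fraction ``#{F_perm >= F_obs} / n_perm`` over the given set
        (identity included), which for a full enumeration is the exact
        permutation p.

    Aliased (rank-deficient) design columns are dropped with a warning and
    term df are reported as realized, so unbalanced designs with empty
    cells yield reduced interaction df.
    """
    X = np.asarray(profiles, dtype=float)
    n = len(X)
    if len(factors) != n:
        raise ValueError("factors and profiles must have the same length")
    terms = list(terms) if terms is not None else list(factors.columns)
    for col in factors.columns:
        if factors[col].nunique() < 2 and col in terms:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")

    d = pdist(X, metric="euclidean")
    D2 = squareform(d**2)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    ss_total = float(np.trace(G))

    # cumulative orthonormal bases for the sequential design
    design = [np.ones((n, 1))]
    hats: list[np.ndarray] = []
    dfs: list[int] = []
    prev_rank = 1
    prev_Q = orth(np.ones((n, 1)))
    for term in terms:
        design.append(_term_columns(term, factors))
        M = np.concatenate(design, axis=1)
        Q = orth(M)
        rank = Q.shape[1]
        df_t = rank - prev_rank
        if df_t < design[-1].shape[1]:
            logger.warning(
                "term %r: %d aliased column(s) dropped (df %d as realized)",
                term,
                design[-1].shape[1] - df_t,
                df_t,
            )
        hats.append(Q @ Q.T - prev_Q @ prev_Q.T)
        dfs.append(df_t)
        prev_rank, prev_Q = rank, Q
    rank_full = prev_rank
    H_full = prev_Q @ prev_Q.T
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (N <= model df)")
    R = np.eye(n) - H_full

    def _all_ss(Gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(H * Gmat)) for H in hats])
        ss_res = float(np.sum(R * Gmat))
        return ss_terms, ss_res

    ss_terms, ss_res = _all_ss(G)
    dfs_arr = np.array(dfs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        F_obs = (ss_terms / dfs_arr) / (ss_res / df_resid)

    if permutations is not None:
        perms = np.asarray(permutations, dtype=int)
        exact = True
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        exact = False
    exceed = np.zeros(len(terms))
    for perm in perms:
        Gp = G[np.ix_(perm, perm)]
        ss_t, ss_r = _all_ss(Gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            Fp = (ss_t / dfs_arr) / (ss_r / df_resid)
        exceed += Fp >= F_obs - 1e-12
    if exact:
        pvals = exceed / len(perms)
    else:
        pvals = (1.0 + exceed) / (1.0 + len(perms))

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": int(dfs[i]),
                "SS": ss_terms[i],
                "MS": ss_terms[i] / dfs[i] if dfs[i] else np.nan,
                "F": F_obs[i],
                "R2": ss_terms[i] / ss_total,
                "p": pvals[i],
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "df": int(df_resid),
            "SS": ss_res,
            "MS": ss_res / df_resid,
            "F": np.nan,
            "R2": ss_res / ss_total,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "F": np.nan,
            "R2": 1.0,
            "p": np.nan,
        }
    )
    return PermanovaResult(
        table=pd.DataFrame(rows), n_permutations=len(perms), seed=seed
    )
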