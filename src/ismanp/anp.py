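"""Analytic Network Process (ANP) on an ISM-derived influence network.

Local priorities come from Saaty 1-9 reciprocal judgment matrices via the
principal-eigenvector method, gated by the consistency ratio CR < 0.1.
Column j of the unweighted supermatrix W0 distributes factor j's influence
over the factors it reaches (entry (i, j) > 0 iff j influences i); factors
that influence nothing receive an absorbing diagonal 1 so every column sums
to one. Cluster weights scale the blocks of W0 (a_rc · W_rc) and columns are
renormalized, giving the column-stochastic weighted supermatrix W; its power
limit W∞ (Cesàro-averaged when the power sequence is periodic) yields the
global weight of every factor.

Orientation note. With the default ``orientation="influence"`` a factor that
nothing influences has a structurally zero row in W0 — and hence a global
weight of exactly 0 whatever the judgment values. This is the only
orientation under which root factors (empty antecedent sets) are forced to
zero weight; the classical Saaty "dependence" orientation (column j holds
priorities of j's *influencers*) is available behind the flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SAATY_RI",
    "Judgment",
    "PriorityVector",
    "ConsistencyReport",
    "NetworkStructure",
    "build_network",
    "priority_vector",
    "consistency",
    "assemble_unweighted",
    "cluster_weight_matrix",
    "apply_cluster_weights",
    "LimitResult",
    "limit_supermatrix",
    "global_weights",
    "AnpResult",
    "anp_pipeline",
    "AnalyticNetworkProcess",
]

#: Saaty (1980) random consistency indices for matrix orders 1..10.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}


@dataclass(frozen=True)
class Judgment:
    """A pairwise-comparison matrix over ``elements`` w.r.t. ``criterion``."""

    criterion: str
    elements: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.elements):
            raise ValueError("judgment matrix shape must match its element list")
        _validate_reciprocal(m)


def _validate_reciprocal(P: np.ndarray, rtol: float = 1e-6) -> None:
    if np.any(P <= 0):
        raise ValueError("judgment matrix entries must be positive")
    if not np.allclose(np.diag(P), 1.0, atol=1e-9):
        raise ValueError("judgment matrix diagonal must be 1")
    if not np.allclose(P * P.T, 1.0, rtol=rtol, atol=1e-9):
        raise ValueError("judgment matrix is not reciprocal (p_ji != 1/p_ij)")


class PriorityVector:
    """Normalized principal eigenvector plus its eigenvalue."""

    __slots__ = ("weights", "lambda_max")

    def __init__(self, weights: np.ndarray, lambda_max: float):
        self.weights = weights
        self.lambda_max = lambda_max


def priority_vector(P) -> PriorityVector:
    """Local weights of a reciprocal judgment matrix by the eigenvalue method.

    Returns the principal right eigenvector normalized to sum 1 and the
    principal eigenvalue λmax (≥ m for reciprocal matrices, = m iff the
    matrix is perfectly consistent).
    """
    P = np.asarray(P, dtype=float)
    _validate_reciprocal(P)
    eigval, eigvec = np.linalg.eig(P)
    k = int(np.argmax(eigval.real))
    v = np.abs(eigvec[:, k].real)
    return PriorityVector(weights=v / v.sum(), lambda_max=float(eigval[k].real))


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    order: int
    ci: float
    ri: float
    cr: float
    passed: bool


def consistency(P, cr_threshold: float = 0.1, extend_ri: bool = False) -> ConsistencyReport:
    """Consistency audit: CI = (λmax − m)/(m − 1), CR = CI / RI(m).

    CR is defined as 0 for m ≤ 2 (a 2x2 reciprocal matrix is always
    consistent). Matrix orders beyond 10 exceed the tabulated random index
    and raise by default; with ``extend_ri=True`` the order-10 index (a
    lower bound of RI for larger matrices, RI being increasing in m) is used
    instead, which *over*-estimates CR and therefore only tightens the gate.
    """
    P = np.asarray(P, dtype=float)
    m = P.shape[0]
    if m > max(SAATY_RI) and not extend_ri:
        raise ValueError(
            f"no random index tabulated for order {m} (>10); decompose the "
            "comparison into smaller matrices or pass extend_ri=True for a "
            "conservative gate"
        )
    pv = priority_vector(P)
    if m <= 2:
        ci, ri, cr = 0.0, SAATY_RI[m], 0.0
    else:
        ci = (pv.lambda_max - m) / (m - 1)
        ri = SAATY_RI[min(m, max(SAATY_RI))]
        cr = ci / ri
    return ConsistencyReport(
        lambda_max=pv.lambda_max, order=m, ci=ci, ri=ri, cr=cr, passed=cr < cr_threshold
    )


@dataclass(frozen=True)
class NetworkStructure:
    """Directed influence network over clustered factors.

    ``targets[j]`` holds the factors j influences (edge j→i), ``influencers[i]``
    the factors influencing i; both exclude self-edges.
    """

    factors: tuple[str, ...]
    cluster_of: Mapping[str, str]
    cluster_order: tuple[str, ...]
    targets: Mapping[str, tuple[str, ...]]
    influencers: Mapping[str, tuple[str, ...]]

    @property
    def sources(self) -> tuple[str, ...]:
        """Factors nothing influences (empty influencer set) — the roots."""
        return tuple(f for f in self.factors if not self.influencers[f])

    @property
    def sinks(self) -> tuple[str, ...]:
        """Factors influencing nothing — absorbing consequence factors."""
        return tuple(f for f in self.factors if not self.targets[f])

    def members(self, cluster: str) -> tuple[str, ...]:
        return tuple(f for f in self.factors if self.cluster_of[f] == cluster)


def build_network(
    relation_matrix,
    cluster_of: Mapping[str, str],
    cluster_order: Sequence[str] | None = None,
) -> NetworkStructure:
    """Build the ANP network from a relation matrix and a cluster assignment.

    ``relation_matrix`` may be an adjacency matrix (direct influences only)
    or a reachability matrix (direct and indirect, the usual ISM hand-off);
    an edge j→i is recorded for every off-diagonal 1 at (j, i).
    """
    from .ism import _to_frame  # shared matrix normalization

    df = _to_frame(relation_matrix)
    factors = tuple(df.index)
    unclustered = [f for f in factors if f not in cluster_of]
    if unclustered:
        raise ValueError(f"factors without a cluster assignment: {unclustered}")
    if cluster_order is None:
        seen: list[str] = []
        for f in factors:
            if cluster_of[f] not in seen:
                seen.append(cluster_of[f])
        cluster_order = tuple(seen)
    else:
        cluster_order = tuple(cluster_order)
        stray = {cluster_of[f] for f in factors} - set(cluster_order)
        if stray:
            raise ValueError(f"cluster_order is missing clusters {sorted(stray)}")
    vals = df.to_numpy(dtype=bool) & ~np.eye(len(factors), dtype=bool)
    targets = {
        f: tuple(df.columns[vals[i]]) for i, f in enumerate(factors)
    }
    influencers = {
        f: tuple(df.index[vals[:, i]]) for i, f in enumerate(factors)
    }
    empty = [c for c in cluster_order if not any(cluster_of[f] == c for f in factors)]
    if empty:
        raise ValueError(f"clusters without members: {empty}")
    return NetworkStructure(
        factors=factors,
        cluster_of=dict(cluster_of),
        cluster_order=cluster_order,
        targets=targets,
        influencers=influencers,
    )


def _compared_set(network: NetworkStructure, criterion: str, orientation: str) -> tuple[str, ...]:
    if orientation == "influence":
        return network.targets[criterion]
    if orientation == "dependence":
        return network.influencers[criterion]
    raise ValueError(f"unknown orientation {orientation!r}")


def assemble_unweighted(
    network: NetworkStructure,
    judgments: Mapping[str, Judgment] | None,
    orientation: Literal["influence", "dependence"] = "influence",
) -> pd.DataFrame:
    """Assemble the unweighted supermatrix W0 from per-criterion judgments.

    For every factor j with two or more compared elements a :class:`Judgment`
    keyed by j must be supplied over exactly that element set; its priority
    vector fills column j at the compared rows. Single-element criteria need
    no judgment (the lone entry is 1) and absorbing factors (empty compared
    set) get a diagonal 1 so every column sums to one. ``judgments`` may be
    the string ``"uniform"`` to compare everything as equally important.
    """
    factors = network.factors
    pos = {f: i for i, f in enumerate(factors)}
    W0 = np.zeros((len(factors), len(factors)))
    uniform = isinstance(judgments, str) and judgments == "uniform"
    for j in factors:
        compared = _compared_set(network, j, orientation)
        col = pos[j]
        if len(compared) == 0:
            W0[col, col] = 1.0
        elif len(compared) == 1:
            W0[pos[compared[0]], col] = 1.0
        else:
            if uniform:
                w = np.full(len(compared), 1.0 / len(compared))
            else:
                if judgments is None or j not in judgments:
                    raise ValueError(
                        f"missing judgment matrix for criterion {j!r} comparing "
                        f"{list(compared)}"
                    )
                judgment = judgments[j]
                if tuple(judgment.elements) != tuple(compared):
                    raise ValueError(
                        f"judgment for criterion {j!r} compares {list(judgment.elements)} "
                        f"but the network requires {list(compared)}"
                    )
                w = priority_vector(judgment.matrix).weights
            for element, weight in zip(compared, w):
                W0[pos[element], col] = weight
    return pd.DataFrame(W0, index=list(factors), columns=list(factors))


def _cluster_links(
    network: NetworkStructure, orientation: str
) -> dict[str, tuple[str, ...]]:
    """Clusters whose block in column-cluster c of W0 is structurally nonzero."""
    links: dict[str, set[str]] = {c: set() for c in network.cluster_order}
    for j in network.factors:
        c = network.cluster_of[j]
        compared = _compared_set(network, j, orientation)
        if not compared:
            links[c].add(c)  # absorbing self-loop sits in the diagonal block
        for element in compared:
            links[c].add(network.cluster_of[element])
    return {c: tuple(r for r in network.cluster_order if r in links[c]) for c in links}


def cluster_weight_matrix(
    network: NetworkStructure,
    cluster_judgments: Mapping[str, Judgment] | None = None,
    uniform: bool = False,
    orientation: Literal["influence", "dependence"] = "influence",
) -> pd.DataFrame:
    """Cluster weight matrix: column c holds priorities over the clusters
    linked in column-cluster c of the supermatrix.

    A judgment keyed by cluster c compares exactly the linked clusters; a
    single linked cluster needs none (its entry is 1); with ``uniform=True``
    missing judgments fall back to 1/k over the k linked clusters. Entries
    are zero where no inter-cluster edge exists, and every nonzero column
    sums to one.
    """
    order = network.cluster_order
    links = _cluster_links(network, orientation)
    A = pd.DataFrame(0.0, index=list(order), columns=list(order))
    for c in order:
        linked = links[c]
        if cluster_judgments is not None and c in cluster_judgments:
            stray = set(cluster_judgments[c].elements) - set(linked)
            if stray:
                raise ValueError(
                    f"cluster judgment for {c!r} compares clusters {sorted(stray)} "
                    "that are not linked in the network"
                )
        if not linked:
            continue
        if len(linked) == 1:
            A.loc[linked[0], c] = 1.0
            continue
        if cluster_judgments is not None and c in cluster_judgments:
            judgment = cluster_judgments[c]
            if tuple(judgment.elements) != tuple(linked):
                raise ValueError(
                    f"cluster judgment for {c!r} must compare {list(linked)} "
                    f"in cluster order, got {list(judgment.elements)}"
                )
            w = priority_vector(judgment.matrix).weights
        elif uniform:
            w = np.full(len(linked), 1.0 / len(linked))
        else:
            raise ValueError(
                f"missing cluster judgment for {c!r} comparing {list(linked)}; "
                "pass uniform=True for the documented 1/k fallback"
            )
        for r, weight in zip(linked, w):
            A.loc[r, c] = weight
    return A


def apply_cluster_weights(
    W0: pd.DataFrame, clusterA: pd.DataFrame, cluster_of: Mapping[str, str]
) -> pd.DataFrame:
    """Weighted supermatrix W: scale block (r, c) of W0 by a_rc, then
    renormalize every nonzero column to sum 1 (column stochasticity)."""
    factors = list(W0.index)
    scale = np.array(
        [[float(clusterA.loc[cluster_of[i], cluster_of[j]]) for j in factors] for i in factors]
    )
    W = W0.to_numpy() * scale
    sums = W.sum(axis=0)
    if np.any(sums <= 0):
        dead = [factors[i] for i in np.nonzero(sums <= 0)[0]]
        raise ValueError(f"columns {dead} lost all mass under cluster weighting")
    W = W / sums
    return pd.DataFrame(W, index=factors, columns=factors)


@dataclass(frozen=True)
class LimitResult:
    matrix: pd.DataFrame
    method: Literal["power", "cesaro"]
    iterations: int


def limit_supermatrix(
    W,
    tol: float = 1e-10,
    max_squarings: int = 200,
    cesaro_window: int = 32,
    method: Literal["auto", "power", "cesaro"] = "auto",
) -> LimitResult:
    """Limit supermatrix W∞ of a column-stochastic W.

    Repeated squaring with a fixed-point test ``max|P·W − P| < tol``; when
    the power sequence does not converge (periodic/reducible chains) the
    Cesàro average of ``cesaro_window`` consecutive high powers is returned
    and flagged. ``method="cesaro"`` forces the average; ``method="power"``
    raises instead of falling back.
    """
    Wdf = pd.DataFrame(W)
    V = Wdf.to_numpy(dtype=float)
    sums = V.sum(axis=0)
    if np.any(V < -1e-12) or not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("limit_supermatrix requires a column-stochastic matrix")

    def _cesaro(iters: int) -> LimitResult:
        base = np.linalg.matrix_power(V, 64)
        acc = np.zeros_like(V)
        cur = base
        for _ in range(cesaro_window):
            cur = cur @ V
            acc += cur
        return LimitResult(
            matrix=pd.DataFrame(acc / cesaro_window, index=Wdf.index, columns=Wdf.columns),
            method="cesaro",
            iterations=iters,
        )

    if method == "cesaro":
        return _cesaro(0)
    P = V
    for it in range(max_squarings):
        if np.max(np.abs(P @ V - P)) < tol:
            return LimitResult(
                matrix=pd.DataFrame(P, index=Wdf.index, columns=Wdf.columns),
                method="power",
                iterations=it,
            )
        P = P @ P
        colsums = P.sum(axis=0)
        if np.any(colsums <= 0):  # numerical underflow guard
            break
        P = P / colsums
    if method == "power":
        raise ValueError(f"power sequence did not converge in {max_squarings} squarings")
    return _cesaro(max_squarings)


def global_weights(limit: LimitResult | pd.DataFrame, col_agree_tol: float = 1e-6) -> pd.DataFrame:
    """Global weight and rank of every factor from the limit supermatrix.

    When all columns agree (irreducible case) any column is the weight
    vector; otherwise the row-wise mean across columns is renormalized.
    Ranks are competition-style (ties share the smaller rank), tie order by
    factor position.
    """
    L = limit.matrix if isinstance(limit, LimitResult) else pd.DataFrame(limit)
    V = L.to_numpy(dtype=float)
    if np.max(V.max(axis=1) - V.min(axis=1)) <= col_agree_tol:
        w = V[:, 0].copy()
    else:
        w = V.mean(axis=1)
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("limit supermatrix carries no weight mass")
    w = w / total
    out = pd.DataFrame({"weight": w}, index=L.index)
    out["rank"] = out["weight"].rank(method="min", ascending=False).astype(int)
    return out


@dataclass
class AnpResult:
    """Full ANP audit: weights plus every intermediate stage."""

    weights: pd.DataFrame
    unweighted: pd.DataFrame
    weighted: pd.DataFrame
    limit: LimitResult
    consistency: dict[str, ConsistencyReport]
    cluster_consistency: dict[str, ConsistencyReport]
    cluster_matrix: pd.DataFrame
    network: NetworkStructure = field(repr=False)


def anp_pipeline(
    network: NetworkStructure,
    judgments: Mapping[str, Judgment] | Literal["uniform"],
    cluster_judgments: Mapping[str, Judgment] | None = None,
    allow_inconsistent: bool = False,
    cr_threshold: float = 0.1,
    orientation: Literal["influence", "dependence"] = "influence",
    limit_method: Literal["auto", "power", "cesaro"] = "auto",
    limit_tol: float = 1e-10,
) -> AnpResult:
    """End-to-end ANP: consistency gate → W0 → cluster weighting → limit →
    global weights. Deterministic given its inputs.

    Every supplied judgment (element-level and cluster-level) must pass
    CR < ``cr_threshold`` unless ``allow_inconsistent``; the failure message
    names every offending matrix. ``cluster_judgments=None`` uses the uniform
    1/k cluster fallback.
    """
    reports: dict[str, ConsistencyReport] = {}
    if not isinstance(judgments, str):
        for key, judgment in judgments.items():
            reports[key] = consistency(judgment.matrix, cr_threshold, extend_ri=True)
    cluster_reports: dict[str, ConsistencyReport] = {}
    for key, judgment in (cluster_judgments or {}).items():
        cluster_reports[key] = consistency(judgment.matrix, cr_threshold, extend_ri=True)
    failing = [k for k, r in {**reports, **cluster_reports}.items() if not r.passed]
    if failing and not allow_inconsistent:
        detail = ", ".join(f"{k} (CR={(reports | cluster_reports)[k].cr:.3f})" for k in failing)
        raise ValueError(
            f"judgment matrices fail the CR<{cr_threshold} gate: {detail}; "
            "pass allow_inconsistent=True to proceed anyway"
        )
    W0 = assemble_unweighted(network, judgments, orientation)
    clusterA = cluster_weight_matrix(
        network, cluster_judgments, uniform=cluster_judgments is None, orientation=orientation
    )
    W = apply_cluster_weights(W0, clusterA, network.cluster_of)
    limit = limit_supermatrix(W, tol=limit_tol, method=limit_method)
    return AnpResult(
        weights=global_weights(limit),
        unweighted=W0,
        weighted=W,
        limit=limit,
        consistency=reports,
        cluster_consistency=cluster_reports,
        cluster_matrix=clusterA,
        network=network,
    )


class AnalyticNetworkProcess(BaseEstimator):
    """ANP as an estimator: fit on a relation matrix plus judgments.

    Parameters mirror :func:`anp_pipeline`; ``clusters`` maps factor →
    cluster label and ``cluster_order`` fixes block order. ``fit(X,
    judgments=..., cluster_judgments=...)`` accepts a 0/1 relation matrix
    (adjacency or reachability) as X; judgments may be the string
    ``"uniform"``.

    Fitted attributes: ``network_``, ``weights_`` (Series), ``ranks_``,
    ``weight_table_``, ``supermatrix_``, ``weighted_supermatrix_``,
    ``limit_``, ``limit_method_``, ``consistency_``, ``cluster_matrix_``.
    """

    def __init__(
        self,
        clusters: Mapping[str, str] | None = None,
        cluster_order: Sequence[str] | None = None,
        cr_threshold: float = 0.1,
        allow_inconsistent: bool = False,
        orientation: Literal["influence", "dependence"] = "influence",
        limit_method: Literal["auto", "power", "cesaro"] = "auto",
        limit_tol: float = 1e-10,
    ):
        self.clusters = clusters
        self.cluster_order = cluster_order
        self.cr_threshold = cr_threshold
        self.allow_inconsistent = allow_inconsistent
        self.orientation = orientation
        self.limit_method = limit_method
        self.limit_tol = limit_tol

    def fit(self, X, y=None, judgments="uniform", cluster_judgments=None):
        if self.clusters is None:
            raise ValueError("AnalyticNetworkProcess requires a clusters mapping")
        network = build_network(X, self.clusters, self.cluster_order)
        result = anp_pipeline(
            network,
            judgments,
            cluster_judgments=cluster_judgments,
            allow_inconsistent=self.allow_inconsistent,
            cr_threshold=self.cr_threshold,
            orientation=self.orientation,
            limit_method=self.limit_method,
            limit_tol=self.limit_tol,
        )
        self.result_ = result
        self.network_ = network
        self.weight_table_ = result.weights
        self.weights_ = result.weights["weight"]
        self.ranks_ = result.weights["rank"]
        self.supermatrix_ = result.unweighted
        self.weighted_supermatrix_ = result.weighted
        self.limit_ = result.limit
        self.limit_method_ = result.limit.method
        self.consistency_ = {**result.consistency, **result.cluster_consistency}
        self.cluster_matrix_ = result.cluster_matrix
        self.n_features_in_ = len(network.factors)
        return self
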