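"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of their spec (seed included):

* Likert questionnaire responses with a planted common-factor loading
  structure plus noise — defaults emulate an importance-rating survey with a
  clean simple structure (loading 0.7, noise SD 0.5, 500 respondents);
* Saaty reciprocal judgment matrices derived from a ground-truth weight
  vector with controllable inconsistency (lognormal-antisymmetric noise, so
  reciprocity is exact for every noise level);
* random directed acyclic influence structures.

Likert discretization: continuous factor scores are z-scaled per item,
mapped to mean 3 / SD 1, rounded half-up and clipped to [1, 5]. Recovery
quality depends on this coarsening, which is the point — the generator
emulates what a 5-point scale does to an underlying continuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .anp import Judgment, NetworkStructure, _compared_set

__all__ = [
    "FactorModelSpec",
    "simple_structure_loadings",
    "generate_responses",
    "JudgmentSpec",
    "generate_judgment",
    "generate_random_dag",
    "uniform_judgments",
    "random_consistent_judgments",
]

#: Admissible Saaty scale values (1..9 and reciprocals) for rounding mode.
_SAATY_VALUES = np.array(
    sorted([1.0 / v for v in range(2, 10)] + [float(v) for v in range(1, 10)])
)


def simple_structure_loadings(
    n_items: int, n_factors: int, loading: float = 0.7
) -> np.ndarray:
    """Item x factor loading matrix with one nonzero loading per item,
    items split over factors as evenly as possible."""
    if not 0 < abs(loading) <= 1:
        raise ValueError("loading must be in (0, 1]")
    L = np.zeros((n_items, n_factors))
    for i in range(n_items):
        L[i, i % n_factors] = loading
    return L


@dataclass(frozen=True)
class FactorModelSpec:
    """Planted-factor-model spec for Likert response generation.

    Defaults are the package's standard recovery scenario: 15 items loading
    0.7 on one of 3 factors each, residual noise SD 0.5, 500 respondents on
    a 1-5 scale.
    """

    n_items: int = 15
    n_factors: int = 3
    loadings: np.ndarray | None = None
    noise_sd: float = 0.5
    likert_min: int = 1
    likert_max: int = 5
    n_respondents: int = 500
    seed: int = 0

    def loading_matrix(self) -> np.ndarray:
        if self.loadings is not None:
            L = np.asarray(self.loadings, dtype=float)
            if L.shape != (self.n_items, self.n_factors):
                raise ValueError("loadings shape must be (n_items, n_factors)")
            if np.any(np.abs(L) > 1):
                raise ValueError("|loadings| must not exceed 1")
            return L
        return simple_structure_loadings(self.n_items, self.n_factors)


def generate_responses(spec: FactorModelSpec) -> pd.DataFrame:
    """Simulate a respondents x items Likert response matrix.

    Latent factors are standard normal; item score = Σ λ·factor + noise,
    then z-scaled, affine-mapped to mean 3 / SD 1, rounded half-up and
    clipped into the Likert range. Deterministic per seed.
    """
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    L = spec.loading_matrix()
    dead = np.nonzero((L == 0).all(axis=1))[0]
    if spec.noise_sd == 0 and dead.size:
        raise ValueError(
            f"items {dead.tolist()} have all-zero loadings and no noise: "
            "constant items cannot be generated"
        )
    rng = np.random.default_rng(spec.seed)
    factors = rng.standard_normal((spec.n_respondents, spec.n_factors))
    raw = factors @ L.T + spec.noise_sd * rng.standard_normal(
        (spec.n_respondents, spec.n_items)
    )
    sd = raw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("generated a constant item; check loadings/noise_sd")
    z = (raw - raw.mean(axis=0)) / sd
    center = 0.5 * (spec.likert_min + spec.likert_max)
    scores = np.clip(np.floor(center + z + 0.5), spec.likert_min, spec.likert_max)
    return pd.DataFrame(
        scores.astype(int),
        columns=[f"item{i + 1}" for i in range(spec.n_items)],
    )


@dataclass(frozen=True)
class JudgmentSpec:
    """Ground-truth weights plus a perturbation level for judgment synthesis."""

    weights: tuple[float, ...]
    perturbation_sd: float = 0.0
    saaty_rounding: bool = False
    seed: int = 0

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if any(x <= 0 for x in w):
            raise ValueError("true weights must be positive")
        if self.perturbation_sd < 0:
            raise ValueError("perturbation_sd must be nonnegative")
        object.__setattr__(self, "weights", w)


def _round_saaty(value: float) -> float:
    return float(_SAATY_VALUES[np.argmin(np.abs(_SAATY_VALUES - value))])


def generate_judgment(
    spec: JudgmentSpec, elements: Sequence[str] | None = None, criterion: str = "criterion"
) -> Judgment:
    """Reciprocal judgment matrix p_ij = (w_i/w_j)·exp(ε_ij).

    ε is antisymmetric normal(0, δ²), so reciprocity is exact by
    construction for every δ. With ``saaty_rounding`` the upper triangle is
    snapped to the nearest admissible 1-9 scale value (or reciprocal) and
    the lower triangle rebuilt as exact reciprocals. δ=0 gives a perfectly
    consistent matrix whose priority vector recovers w exactly.
    """
    w = np.asarray(spec.weights)
    m = len(w)
    if elements is None:
        elements = tuple(f"e{i + 1}" for i in range(m))
    if len(elements) != m:
        raise ValueError("elements length must match the weight vector")
    rng = np.random.default_rng(spec.seed)
    P = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            eps = rng.normal(0.0, spec.perturbation_sd) if spec.perturbation_sd else 0.0
            val = (w[i] / w[j]) * np.exp(eps)
            if spec.saaty_rounding:
                val = _round_saaty(val)
            P[i, j] = val
            P[j, i] = 1.0 / val
    return Judgment(criterion=criterion, elements=tuple(elements), matrix=P)


def generate_random_dag(n: int, edge_density: float, seed: int = 0) -> pd.DataFrame:
    """Random DAG adjacency matrix on factors F1..Fn.

    A random permutation fixes a topological order; each forward pair gets
    an edge with probability ``edge_density``. Acyclic by construction and
    deterministic per seed.
    """
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rank = rng.permutation(n)
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if rank[i] < rank[j] and rng.random() < edge_density:
                A[i, j] = 1
    ids = [f"F{i + 1}" for i in range(n)]
    return pd.DataFrame(A, index=ids, columns=ids)


def uniform_judgments(network: NetworkStructure, orientation: str = "influence"):
    """All-comparisons-equal judgments for every multi-element criterion."""
    out: dict[str, Judgment] = {}
    for f in network.factors:
        compared = _compared_set(network, f, orientation)
        if len(compared) >= 2:
            out[f] = Judgment(
                criterion=f, elements=tuple(compared), matrix=np.ones((len(compared),) * 2)
            )
    return out


def random_consistent_judgments(
    network: NetworkStructure,
    seed: int = 42,
    orientation: str = "influence",
    low: float = 0.2,
) -> dict[str, Judgment]:
    """Perfectly consistent judgments from seeded random positive weights.

    For every criterion with ≥2 compared elements, draw a uniform(low, 1)
    weight vector from one seeded stream (criteria visited in factor order,
    so the full collection is a pure function of the seed) and build the
    δ=0 ratio matrix. Stands in for unpublished expert comparisons when only
    structural conclusions are of interest.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, Judgment] = {}
    for f in network.factors:
        compared = _compared_set(network, f, orientation)
        if len(compared) >= 2:
            w = rng.uniform(low, 1.0, size=len(compared))
            P = w[:, None] / w[None, :]
            out[f] = Judgment(criterion=f, elements=tuple(compared), matrix=P)
    return out
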