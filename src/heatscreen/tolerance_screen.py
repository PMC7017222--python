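"""PCA-weighted membership-function ranking of heat tolerance.

Given a cows × indexes matrix of heat-stress indicators (rectal temperature,
respiratory rate, decline in milk yield, ...), the screen ranks cows by a
composite score built in three steps:

1. PCA on the correlation (default) or covariance matrix of the indexes;
   the contribution rate of component *i* is ``P_i = λ_i / Σλ``.
2. Each retained component's scores ``X_i`` are min-max normalised to a
   membership value ``R(X_i) = (X_i − X_min) / (X_max − X_min) ∈ [0, 1]``.
3. Contribution rates of the retained components are renormalised to
   weights ``W_i = P_i / ΣP_i`` and combined into the weighted membership
   value ``RW = Σ_i R(X_i)·W_i`` per cow.

Cows are ranked by descending RW (rank 1 = most heat tolerant); the top-k
are labelled heat tolerant (HT), the bottom-k non-heat tolerant (NHT).

Sign convention
---------------
Eigenvector signs are arbitrary, so each retained component is oriented so
that the sum of its loadings on "higher-is-worse" indexes (stress burden:
RT, RR, milk-yield decline) is negative. Larger component scores — hence
larger R and RW — then consistently mean greater tolerance. Index direction
is part of the input (``directions``), defaulting to higher-is-worse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateRangeError,
    DegenerateVarianceError,
    DomainError,
    ShapeError,
)

__all__ = [
    "IndexMatrix",
    "PCAModel",
    "RWRanking",
    "pca_fit",
    "membership_normalize",
    "contribution_weights",
    "cumulative_contribution",
    "rw_score",
    "screen_herd",
]


@dataclass(frozen=True)
class IndexMatrix:
    """Cows × heat-stress-indexes matrix, each index in its native units.

    ``directions[name]`` is ``"higher_is_worse"`` (default for every index)
    or ``"higher_is_better"``; it drives the component sign convention.
    """

    cow_ids: tuple[str, ...]
    index_names: tuple[str, ...]
    values: np.ndarray  # (n_cows, n_indexes)
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cow_ids", tuple(str(c) for c in self.cow_ids))
        object.__setattr__(self, "index_names", tuple(self.index_names))
        if values.ndim != 2 or values.shape != (len(self.cow_ids), len(self.index_names)):
            raise ShapeError(
                f"values shape {values.shape} does not match "
                f"{len(self.cow_ids)} cows × {len(self.index_names)} indexes"
            )
        if len(set(self.cow_ids)) != len(self.cow_ids):
            raise DomainError("cow_ids must be unique")
        if len(self.cow_ids) < 3:
            raise DomainError("need at least 3 cows")
        if len(self.index_names) < 2:
            raise DomainError("need at least 2 indexes")
        if not np.all(np.isfinite(values)):
            raise DomainError("index matrix contains missing or non-finite cells")
        for name, d in self.directions.items():
            if name not in self.index_names:
                raise DomainError(f"direction given for unknown index {name!r}")
            if d not in ("higher_is_worse", "higher_is_better"):
                raise DomainError(f"index {name!r}: unknown direction {d!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, directions: dict[str, str] | None = None,
                   id_column: str = "cow_id") -> "IndexMatrix":
        """Build from a tidy frame with one row per cow."""
        if id_column not in df.columns:
            raise DomainError(f"index table missing required column {id_column!r}")
        index_names = [c for c in df.columns if c != id_column]
        return cls(
            cow_ids=tuple(df[id_column].astype(str)),
            index_names=tuple(index_names),
            values=df[index_names].to_numpy(dtype=float),
            directions=dict(directions or {}),
        )

    def direction_sign(self, name: str) -> int:
        """+1 if higher values mean more stress burden, −1 otherwise."""
        return -1 if self.directions.get(name) == "higher_is_better" else +1


@dataclass(frozen=True)
class PCAModel:
    """Eigendecomposition of the index correlation/covariance matrix."""

    index_names: tuple[str, ...]
    cow_ids: tuple[str, ...]
    eigenvalues: np.ndarray          # all components, descending
    loadings: np.ndarray             # (n_indexes, n_components), unit columns
    scores: np.ndarray               # (n_cows, n_components)
    contribution_rates: np.ndarray   # P_i = λ_i / Σλ over ALL components
    cumulative_contribution: np.ndarray
    scaled: bool


@dataclass(frozen=True)
class RWRanking:
    """Per-cow membership values, weights, RW score, rank and group label."""

    cow_ids: tuple[str, ...]
    membership: np.ndarray       # (n_cows, n_retained), R(X_i) in [0, 1]
    weights: np.ndarray          # W_i, sums to 1
    rw: np.ndarray               # (n_cows,)
    rank: np.ndarray             # permutation of 1..n, 1 = most tolerant
    group: np.ndarray            # "HT" | "NHT" | "unassigned"
    pca: PCAModel

    def to_frame(self) -> pd.DataFrame:
        m = len(self.weights)
        data = {"cow_id": list(self.cow_ids)}
        for i in range(m):
            data[f"pc{i + 1}_score"] = self.pca.scores[:, i]
        for i in range(m):
            data[f"pc{i + 1}_membership"] = self.membership[:, i]
        data["rw"] = self.rw
        data["rank"] = self.rank
        data["group"] = self.group
        return pd.DataFrame(data)


def pca_fit(data: IndexMatrix, n_components: int | None = None,
            scale: bool = True) -> PCAModel:
    """PCA of the index matrix via eigendecomposition.

    With ``scale`` on (default) the correlation matrix is decomposed —
    indexes carry incommensurate units (°C, breaths/min, kg), so unit
    invariance is wanted; ``scale=False`` uses the covariance matrix.

    Contribution rates are fractions of the TOTAL eigenvalue sum, over all
    components regardless of how many are retained. Retained components are
    sign-oriented so larger scores mean greater heat tolerance (see module
    docstring).
    """
    p = len(data.index_names)
    if n_components is None:
        n_components = p
    if not 1 <= n_components <= p:
        raise DomainError(f"n_components must be in [1, {p}], got {n_components}")

    X = data.values
    mean = X.mean(axis=0)
    centered = X - mean
    sd = X.std(axis=0, ddof=1)
    if scale:
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [data.index_names[j] for j in zero]
            raise DegenerateVarianceError(
                f"index column(s) {names} have zero variance; "
                "cannot standardise for correlation PCA"
            )
        Z = centered / sd
        C = (Z.T @ Z) / (len(data.cow_ids) - 1)  # correlation matrix
    else:
        Z = centered
        C = np.cov(X, rowvar=False, ddof=1)

    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    # orient: sum of loadings on stress-burden indexes must be negative
    badness = np.array([data.direction_sign(n) for n in data.index_names], float)
    for j in range(p):
        if float(badness @ eigvecs[:, j]) > 0:
            eigvecs[:, j] = -eigvecs[:, j]

    total = eigvals.sum()
    if total <= 0:
        raise DegenerateVarianceError("all eigenvalues are zero")
    rates = eigvals / total
    scores = Z @ eigvecs

    return PCAModel(
        index_names=data.index_names,
        cow_ids=data.cow_ids,
        eigenvalues=eigvals,
        loadings=eigvecs[:, :n_components],
        scores=scores[:, :n_components],
        contribution_rates=rates,
        cumulative_contribution=np.cumsum(rates),
        scaled=scale,
    )


def membership_normalize(x) -> np.ndarray:
    """Min-max normalise one component's scores to membership values.

    ``R = (x − min) / (max − min)``: the minimum maps to 0, the maximum
    to 1. Invariant under positive affine transforms of ``x``. Constant
    input is an error — a component with no spread carries no ranking
    information and silently imputing a value would corrupt RW.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DomainError("need at least 2 values to normalise")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateRangeError(
            "all component scores identical; membership value undefined"
        )
    return (x - lo) / (hi - lo)


def contribution_weights(P) -> np.ndarray:
    """Renormalise the retained components' contribution rates to weights.

    ``W_i = P_i / ΣP_i`` over the retained components only; ΣW = 1.
    """
    P = np.asarray(P, dtype=float)
    if P.size == 0:
        raise DomainError("no contribution rates supplied")
    if np.any(P <= 0) or not np.all(np.isfinite(P)):
        raise DomainError("contribution rates must be positive and finite")
    return P / P.sum()


def cumulative_contribution(P) -> np.ndarray:
    """Running sum of contribution rates (same scale as the input)."""
    P = np.asarray(P, dtype=float)
    if P.size == 0:
        raise DomainError("no contribution rates supplied")
    if np.any(P < 0):
        raise DomainError("contribution rates must be non-negative")
    return np.cumsum(P)


def rw_score(R, W) -> np.ndarray:
    """Weighted membership value ``RW = Σ_i R(x_i)·W_i`` per cow."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    W = np.asarray(W, dtype=float)
    if R.shape[1] != W.shape[0]:
        raise ShapeError(
            f"membership matrix has {R.shape[1]} components but "
            f"{W.shape[0]} weights were given"
        )
    if np.any((R < 0) | (R > 1)):
        raise DomainError("membership values must lie in [0, 1]")
    if abs(W.sum() - 1.0) > 1e-9 or np.any(W < 0):
        raise DomainError("weights must be non-negative and sum to 1")
    return R @ W


def screen_herd(data: IndexMatrix, n_retain: int = 2, k: int = 3,
                scale: bool = True) -> RWRanking:
    """Rank cows by RW and label the top-k HT and bottom-k NHT.

    Composes :func:`pca_fit` → :func:`membership_normalize` per retained
    component → :func:`contribution_weights` → :func:`rw_score`. Ties are
    broken deterministically by lexicographic cow id.

    Parameters
    ----------
    n_retain
        Number of leading principal components combined into RW (default 2).
    k
        Number of cows labelled at each extreme; requires ``2k ≤ n``.
    """
    n = len(data.cow_ids)
    if k < 1:
        raise DomainError("k must be at least 1")
    if 2 * k > n:
        raise DomainError(f"2k = {2 * k} exceeds herd size {n}")
    if n_retain < 1:
        raise DomainError("must retain at least 1 component")

    model = pca_fit(data, n_components=n_retain, scale=scale)
    R = np.column_stack(
        [membership_normalize(model.scores[:, i]) for i in range(n_retain)]
    )
    W = contribution_weights(model.contribution_rates[:n_retain])
    rw = rw_score(R, W)

    # descending RW; stable with cow_id as the final lexicographic key
    order = sorted(range(n), key=lambda i: (-rw[i], data.cow_ids[i]))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    group = np.full(n, "unassigned", dtype=object)
    group[rank <= k] = "HT"
    group[rank > n - k] = "NHT"

    return RWRanking(
        cow_ids=data.cow_ids,
        membership=R,
        weights=W,
        rw=rw,
        rank=rank,
        group=group,
        pca=model,
    )
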