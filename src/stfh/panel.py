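"""Core data containers: the balanced area x time panel and the proximity matrix.

Stacking convention
-------------------
All vectors and matrices over panel cells are ordered *area-major,
time-minor*: row index ``(i * T) + t`` for area ``i`` (0-based position in
``area_ids``) and time ``t`` (0-based position in ``time_ids``).  Every
module in the package follows this single ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = ["AreaPanel", "ProximityMatrix", "row_standardize"]


@dataclass(frozen=True)
class AreaPanel:
    """Balanced panel of direct estimates with known sampling variances.

    Parameters
    ----------
    area_ids : list of str
        Unique area identifiers, length ``m``.
    time_ids : list of str
        Strictly increasing time labels, length ``T``.  Labels are opaque;
        the model treats periods as equally spaced integers ``1..T``.
    y : (m, T) ndarray
        Direct estimates per cell.
    D : (m, T) ndarray
        Known sampling variances per cell; strictly positive.
    X : (m*T, p) ndarray
        Covariates stacked area-major, time-minor.  An intercept column is
        allowed (and usual).
    """

    area_ids: list[str]
    time_ids: list[str]
    y: np.ndarray
    D: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "area_ids", [str(a) for a in self.area_ids])
        object.__setattr__(self, "time_ids", [str(t) for t in self.time_ids])
        y = np.asarray(self.y, dtype=float)
        D = np.asarray(self.D, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "X", X)
        self._validate()

    def _validate(self) -> None:
        m, T = len(self.area_ids), len(self.time_ids)
        if m == 0 or T == 0:
            raise ValidationError("panel must have at least one area and one time")
        if len(set(self.area_ids)) != m:
            raise ValidationError("area_ids are not unique")
        if len(set(self.time_ids)) != T:
            raise ValidationError("time_ids are not unique")
        if sorted(self.time_ids) != list(self.time_ids):
            raise ValidationError("time_ids must be strictly increasing")
        if self.y.shape != (m, T):
            raise ValidationError(f"y has shape {self.y.shape}, expected {(m, T)}")
        if self.D.shape != (m, T):
            raise ValidationError(f"D has shape {self.D.shape}, expected {(m, T)}")
        if not np.all(np.isfinite(self.y)):
            raise ValidationError("y contains non-finite values")
        if not np.all(np.isfinite(self.D)) or np.any(self.D <= 0):
            bad = np.argwhere(~(np.isfinite(self.D) & (self.D > 0)))
            cells = [(self.area_ids[i], self.time_ids[t]) for i, t in bad[:5]]
            raise ValidationError(
                f"sampling variances must be finite and > 0; offending cells: {cells}"
            )
        n = m * T
        if self.X.shape[0] != n:
            raise ValidationError(
                f"X has {self.X.shape[0]} rows, expected m*T = {n}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("X contains non-finite values")
        p = self.X.shape[1]
        if p >= n:
            raise ValidationError(f"p = {p} must be < m*T = {n}")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValidationError("X is rank deficient")

    @property
    def m(self) -> int:
        return len(self.area_ids)

    @property
    def T(self) -> int:
        return len(self.time_ids)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n(self) -> int:
        return self.m * self.T

    @property
    def y_stacked(self) -> np.ndarray:
        """Direct estimates as an n-vector in stacking order."""
        return self.y.reshape(-1)

    @property
    def D_stacked(self) -> np.ndarray:
        """Sampling variances as an n-vector in stacking order."""
        return self.D.reshape(-1)

    def at_time(self, t: int | str) -> "AreaPanel":
        """Cross-sectional sub-panel at one time point (T becomes 1)."""
        if isinstance(t, str):
            t = self.time_ids.index(t)
        rows = np.arange(self.m) * self.T + t
        return AreaPanel(
            area_ids=list(self.area_ids),
            time_ids=[self.time_ids[t]],
            y=self.y[:, [t]],
            D=self.D[:, [t]],
            X=self.X[rows],
        )


def row_standardize(A: np.ndarray) -> np.ndarray:
    """Divide each row of a nonnegative matrix by its sum."""
    A = np.asarray(A, dtype=float)
    sums = A.sum(axis=1)
    if np.any(sums <= 0):
        bad = np.where(sums <= 0)[0].tolist()
        raise ValidationError(f"isolated areas (zero adjacency rows) at indices {bad}")
    return A / sums[:, None]


@dataclass(frozen=True)
class ProximityMatrix:
    """Row-standardized contiguity weights aligned with a panel's areas.

    Construct via :meth:`from_adjacency` from a symmetric 0/1 (or weighted)
    adjacency matrix; the constructor validates that ``W`` is already
    row-standardized with zero diagonal.
    """

    area_ids: list[str]
    W: np.ndarray
    adjacency: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "area_ids", [str(a) for a in self.area_ids])
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        m = len(self.area_ids)
        if W.shape != (m, m):
            raise ValidationError(f"W has shape {W.shape}, expected {(m, m)}")
        if np.any(W < 0):
            raise ValidationError("W must be nonnegative")
        if np.any(np.diag(W) != 0):
            raise ValidationError("W must have a zero diagonal")
        if not np.allclose(W.sum(axis=1), 1.0, atol=1e-10):
            raise ValidationError("W rows must sum to 1 (row-standardized)")
        adj = self.adjacency
        if adj is None:
            adj = (W > 0).astype(float)
        adj = np.asarray(adj, dtype=float)
        if not np.allclose(adj, adj.T):
            raise ValidationError("underlying adjacency must be symmetric")
        object.__setattr__(self, "adjacency", adj)

    @classmethod
    def from_adjacency(
        cls, adjacency: np.ndarray, area_ids: list[str]
    ) -> "ProximityMatrix":
        """Build from a symmetric nonnegative adjacency; row-standardizes."""
        A = np.asarray(adjacency, dtype=float)
        if not np.allclose(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            A = A.copy()
            np.fill_diagonal(A, 0.0)
        return cls(area_ids=list(area_ids), W=row_standardize(A), adjacency=A)

    @property
    def m(self) -> int:
        return len(self.area_ids)

    def reorder(self, area_ids: list[str]) -> "ProximityMatrix":
        """Permute to match the given area ordering."""
        idx = [self.area_ids.index(str(a)) for a in area_ids]
        if len(idx) != self.m:
            raise ValidationError("area id sets do not match")
        P = np.ix_(idx, idx)
        return ProximityMatrix(
            area_ids=[str(a) for a in area_ids],
            W=self.W[P],
            adjacency=self.adjacency[P],
        )
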