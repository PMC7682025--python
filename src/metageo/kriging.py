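"""Ordinary kriging of city probabilities on the biological map.

Given per-city anchor values p_i (a sample's predicted probabilities on
the sampled cities, placed at those cities' biological coordinates),
the probability at an unsampled target location is the best linear
unbiased predictor

    p_hat_o = sum_i lambda_{o,i} p_i

whose weights minimize the expected squared prediction error subject to
the unbiasedness constraint sum_i lambda_{o,i} = 1.  Under second-order
stationarity the weights solve the augmented linear system

    [Gamma  1] [lambda]   [gamma(d(target, i))]
    [1^T    0] [mu    ] = [1                  ]

where Gamma_ij = gamma(d_ij) is the semivariogram evaluated at the
anchor-pair distances and mu is the Lagrange multiplier.  The
semivariogram is estimated empirically and fit by weighted least
squares over a small family of classical models; with the handful of
anchors typical here the parametric fit can be fragile, so a linear
model is the documented fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "VariogramModel",
    "KrigingSystem",
    "empirical_semivariogram",
    "fit_variogram",
    "solve_kriging_weights",
    "krige_probability",
]

FAMILIES = ("gaussian", "exponential", "spherical", "linear")


@dataclass
class VariogramModel:
    """Semivariogram gamma(d) with nugget/sill/range parameterization.

    ``gamma(0) = nugget``; for the parametric families gamma rises from
    the nugget to the sill over a distance set by ``range_``.  For the
    linear family ``range_`` is the slope and there is no sill (``sill``
    stores nugget + slope for validity only).
    """

    family: str
    nugget: float
    sill: float
    range_: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or not np.isfinite(self.nugget):
            raise ValueError("nugget must be finite and >= 0")
        if self.family != "linear" and (self.sill < self.nugget or self.sill <= 0):
            raise ValueError("sill must be positive and >= nugget")
        if self.range_ < 0:
            raise ValueError("range must be >= 0")

    def to_dict(self) -> dict:
        return {"family": self.family, "nugget": self.nugget,
                "sill": self.sill, "range": self.range_,
                "degenerate": self.degenerate}

    @classmethod
    def from_dict(cls, payload: dict) -> "VariogramModel":
        return cls(family=payload["family"], nugget=payload["nugget"],
                   sill=payload["sill"], range_=payload["range"],
                   degenerate=payload.get("degenerate", False))

    def __call__(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        psill = self.sill - self.nugget
        r = max(self.range_, np.finfo(float).tiny)
        if self.family == "gaussian":
            struct = psill * (1.0 - np.exp(-((d / r) ** 2)))
        elif self.family == "exponential":
            struct = psill * (1.0 - np.exp(-d / r))
        elif self.family == "spherical":
            h = np.clip(d / r, 0.0, 1.0)
            struct = psill * (1.5 * h - 0.5 * h**3)
        else:  # linear: range_ is the slope
            struct = self.range_ * d
        return self.nugget + struct


@dataclass
class KrigingSystem:
    """A solved ordinary-kriging system for one target location."""

    anchor_points: np.ndarray  # (n, 2)
    anchor_values: np.ndarray  # (n,)
    target: np.ndarray  # (2,)
    weights: np.ndarray  # (n,)
    multiplier: float

    @property
    def prediction(self) -> float:
        return float(self.weights @ self.anchor_values)

    def to_dict(self) -> dict:
        return {"anchor_points": self.anchor_points.tolist(),
                "anchor_values": self.anchor_values.tolist(),
                "target": self.target.tolist(),
                "weights": self.weights.tolist(),
                "multiplier": self.multiplier}


def empirical_semivariogram(
    points: np.ndarray, values: np.ndarray, n_bins: int = 6
) -> list[tuple[float, float, int]]:
    """Binned empirical semivariogram.

    Pairs are grouped into ``n_bins`` equal-width distance bins up to
    the maximum pairwise distance; each bin reports its mean pair
    distance, the mean of 0.5 * (v_i - v_j)^2, and the pair count.
    Empty bins are omitted.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need >= 2 points")
    dists = pdist(points)
    if dists.max() == 0:
        raise ValueError("all points coincident; no semivariogram")
    gammas = pdist(values[:, None], metric="sqeuclidean") / 2.0
    edges = np.linspace(0.0, dists.max(), n_bins + 1)
    which = np.minimum(np.digitize(dists, edges[1:], right=True), n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            out.append((float(dists[mask].mean()), float(gammas[mask].mean()),
                        int(mask.sum())))
    return out


def _fit_linear(lags, gammas, counts) -> VariogramModel:
    # weighted least squares of gamma = nugget + slope * d, clipped nonneg
    w = np.sqrt(counts)
    A = np.column_stack([np.ones_like(lags), lags]) * w[:, None]
    coef, _, _, _ = np.linalg.lstsq(A, gammas * w, rcond=None)
    nugget = max(float(coef[0]), 0.0)
    slope = max(float(coef[1]), 0.0)
    # a flat (near-constant) field gives slope ~ 0, which would make the
    # kriging system singular; predictions are invariant to scaling of
    # gamma, so a unit slope is a safe canonical choice there
    scale = max(abs(gammas).max(), 1.0)
    degenerate = slope <= 1e-12 * scale / max(lags.max(), 1.0)
    if degenerate:
        slope = 1.0
    return VariogramModel("linear", nugget=nugget, sill=nugget + slope,
                          range_=slope, degenerate=degenerate)


def fit_variogram(
    empirical: list[tuple[float, float, int]], family: str = "gaussian"
) -> VariogramModel:
    """Weighted least-squares fit of a variogram model to binned data.

    Weights are the per-bin pair counts; nugget, partial sill and range
    are bounded nonnegative.  Fewer than 3 bins, a failed fit, or a
    fitted range beyond 10x the largest lag fall back to the linear
    family with a warning.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    lags = np.array([e[0] for e in empirical], dtype=float)
    gammas = np.array([e[1] for e in empirical], dtype=float)
    counts = np.array([e[2] for e in empirical], dtype=float)
    if family == "linear":
        return _fit_linear(lags, gammas, counts)
    if len(empirical) < 3:
        warnings.warn("fewer than 3 semivariogram bins; falling back to linear")
        return _fit_linear(lags, gammas, counts)

    max_lag = lags.max()
    scale = max(gammas.max(), np.finfo(float).tiny)
    w = np.sqrt(counts)

    def residual(p):
        nugget, psill, rng = p
        model = VariogramModel(family, nugget=nugget, sill=nugget + psill + 1e-300,
                               range_=rng)
        return w * (model(lags) - gammas)

    best = None
    for r0 in (max_lag / 3, max_lag, max_lag / 10):
        try:
            sol = least_squares(
                residual,
                x0=[max(gammas.min(), 0.0), max(scale - gammas.min(), scale * 0.1), r0],
                bounds=([0.0, 1e-12 * scale, 1e-12 * max_lag],
                        [scale * 10, scale * 10, max_lag * 100]),
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        warnings.warn("variogram fit failed to converge; falling back to linear")
        return _fit_linear(lags, gammas, counts)
    nugget, psill, rng = best.x
    if rng > 10 * max_lag:
        warnings.warn("fitted range exceeds 10x the maximum lag; "
                      "falling back to linear")
        return _fit_linear(lags, gammas, counts)
    degenerate = psill < 1e-6 * scale  # flat curve: nugget ~ sill
    return VariogramModel(family, nugget=float(nugget),
                          sill=float(nugget + psill), range_=float(rng),
                          degenerate=degenerate)


def solve_kriging_weights(
    anchors: np.ndarray, target: np.ndarray, model: VariogramModel
) -> tuple[np.ndarray, float]:
    """Solve the augmented ordinary-kriging system for one target.

    Returns the weight vector (summing to 1 by construction) and the
    Lagrange multiplier.  Duplicate anchors or a pathological variogram
    make the system singular; the error reports the condition number.
    """
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    target = np.asarray(target, dtype=float).ravel()
    n = anchors.shape[0]
    if n < 2:
        raise ValueError("need >= 2 anchors")
    d = squareform(pdist(anchors))
    if np.any(d[np.triu_indices(n, 1)] == 0):
        raise ValueError("anchor positions must be pairwise distinct")

    gamma = model(d)
    np.fill_diagonal(gamma, model.nugget)  # gamma(0) = nugget
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = model(cdist(anchors, target[None, :])).ravel()
    b[n] = 1.0
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"kriging system is singular or ill-conditioned (cond={cond:.3e})"
        )
    solution = np.linalg.solve(A, b)
    return solution[:n], float(solution[n])


def krige_probability(
    anchors: np.ndarray,
    values: np.ndarray,
    target: np.ndarray,
    model: VariogramModel,
) -> tuple[float, bool]:
    """Interpolate a probability at the target; clamp into [0, 1].

    Kriging does not preserve the [0, 1] range, so the weighted sum is
    clamped and the clamping is flagged in the second return value.
    """
    values = np.asarray(values, dtype=float)
    weights, _ = solve_kriging_weights(anchors, target, model)
    raw = float(weights @ values)
    clamped = not 0.0 <= raw <= 1.0
    return min(max(raw, 0.0), 1.0), clamped
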