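"""Spectrum-wise preprocessing: airPLS baseline correction, Savitzky-Golay
smoothing/differentiation, and min-max scaling.

The baseline corrector follows the adaptive iteratively reweighted penalized
least squares (airPLS) scheme: a Whittaker smoother — solving
``(W + lambda * D'D) z = W x`` with a sparse order-d difference penalty —
is re-fit with weights that progressively exclude points sitting above the
current baseline, so only sub-baseline points (assumed baseline + negative
noise) anchor the next fit.  Defaults: lambda 1e10, difference order 2,
at most 20 iterations, convergence when the negative-residual l1 mass drops
below 0.001 of the signal's l1 norm.  The first/last 5% of points keep a
weight floor of 0.5 to anchor the endpoints (an endpoint-asymmetry reading
of start/end weight handling; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Sequence

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import splu

from .spectra_core import ABSORBANCE, SpectraSet, SpectraError, convert_mode


@dataclass(frozen=True)
class AirPLSConfig:
    lam: float = 1e10
    diff_order: int = 2
    max_iter: int = 20
    convergence_ratio: float = 1e-3
    edge_protect_fraction: float = 0.05
    edge_asymmetry: float = 0.5

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.diff_order not in (1, 2, 3):
            raise ValueError("diff_order must be 1, 2 or 3")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0.0 <= self.edge_protect_fraction <= 0.5):
            raise ValueError("edge_protect_fraction must be in [0, 0.5]")
        if not (0.0 <= self.edge_asymmetry <= 1.0):
            raise ValueError("edge_asymmetry must be in [0, 1]")


@dataclass(frozen=True)
class BaselineResult:
    """airPLS output; ``corrected + baseline`` equals the input exactly."""

    baseline: np.ndarray
    corrected: np.ndarray
    iterations_used: int
    converged: bool


def _difference_matrix(p: int, order: int) -> sparse.csc_matrix:
    D = sparse.eye(p, format="csc")
    for _ in range(order):
        D = D[1:] - D[:-1]
    return D


def whittaker_smooth(
    x: np.ndarray, weights: np.ndarray, lam: float, diff_order: int = 2
) -> np.ndarray:
    """Weighted Whittaker smoother: minimise
    ``sum_i w_i (x_i - z_i)^2 + lam * sum (diff^d z)^2``.

    Solves the sparse SPD system ``(W + lam D'D) z = W x``; suitable for
    axes with ~1e4 points.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    p = x.size
    if w.shape != x.shape:
        raise ValueError("weights and signal must have the same length")
    if p < diff_order + 1:
        raise ValueError("signal too short for the requested difference order")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("weights must not be all zero")
    D = _difference_matrix(p, diff_order)
    A = (sparse.diags(w, format="csc") + lam * (D.T @ D)).tocsc()
    # Solve for the correction delta = z - x:  A delta = -lam * D'(D x).
    # The RHS vanishes when x lies in the penalty null space (polynomials of
    # degree < d), so such signals are reproduced to rounding error even at
    # lam ~ 1e12 where the direct system (cond ~ lam) loses ~12 digits.
    rhs = -lam * (D.T @ np.diff(x, diff_order))
    delta = splu(A).solve(rhs)
    return x + delta


def airpls(x: np.ndarray, config: AirPLSConfig | None = None) -> BaselineResult:
    """Adaptive iteratively reweighted penalized least squares baseline fit.

    Iteration t: fit ``z`` by the Whittaker smoother under current weights;
    residual ``d = x - z``; stop when ``|d^-|_1 < ratio * |x|_1`` or at
    ``max_iter``; otherwise set ``w_i = 0`` where ``d_i >= 0`` and
    ``w_i = exp(t * |d_i| / |d^-|_1)`` where ``d_i < 0``.  Edge-protected
    points keep ``w >= edge_asymmetry``.
    """
    if config is None:
        config = AirPLSConfig()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("airpls input must be finite")
    p = x.size
    n_edge = int(np.ceil(config.edge_protect_fraction * p))
    w = np.ones(p)
    abs_x_l1 = np.abs(x).sum()
    z = x.copy()
    converged = False
    t = 0
    for t in range(1, config.max_iter + 1):
        z = whittaker_smooth(x, w, config.lam, config.diff_order)
        d = x - z
        neg = d < 0
        d_neg_l1 = float(-d[neg].sum())
        if d_neg_l1 < config.convergence_ratio * abs_x_l1:
            converged = True
            break
        if t == config.max_iter:
            break
        w = np.zeros(p)
        w[neg] = np.exp(t * np.abs(d[neg]) / d_neg_l1)
        if n_edge > 0 and config.edge_asymmetry > 0:
            w[:n_edge] = np.maximum(w[:n_edge], config.edge_asymmetry)
            w[-n_edge:] = np.maximum(w[-n_edge:], config.edge_asymmetry)
    # corrected is x - baseline by this exact subtraction, so recomputing
    # x - baseline reproduces corrected bit-identically (no information
    # beyond the baseline estimate is introduced)
    return BaselineResult(
        baseline=z,
        corrected=x - z,
        iterations_used=t,
        converged=converged,
    )


def savitzky_golay(
    x: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay local polynomial smoothing / differentiation.

    ``delta`` is the (absolute) axis spacing used to scale derivatives; it
    is ignored for ``deriv=0``.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > x.size:
        raise ValueError("window longer than the signal")
    if not (window > polyorder >= deriv >= 0):
        raise ValueError("need window > polyorder >= deriv >= 0")
    return savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv, delta=abs(delta)
    )


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale one spectrum to [0, 1]; degenerate (constant) input errors."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("constant spectrum cannot be min-max normalized")
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

_STEP_NAMES = ("to_absorbance", "airpls", "sg", "minmax")


def _normalize_recipe(
    recipe: Sequence[Any],
) -> list[tuple[str, dict[str, Any]]]:
    steps: list[tuple[str, dict[str, Any]]] = []
    for item in recipe:
        if isinstance(item, str):
            name, params = item, {}
        elif isinstance(item, dict):
            d = dict(item)
            name = d.pop("step")
            params = d
        else:
            name, params = item[0], dict(item[1]) if len(item) > 1 else {}
        if name not in _STEP_NAMES:
            raise ValueError(
                f"unknown preprocessing step {name!r}; expected one of {_STEP_NAMES}"
            )
        steps.append((name, params))
    return steps


def apply_recipe(sset: SpectraSet, recipe: Sequence[Any]) -> SpectraSet:
    """Apply an ordered preprocessing recipe per spectrum.

    Steps: ``to_absorbance``, ``airpls`` (params of :class:`AirPLSConfig`),
    ``sg`` (window/polyorder/deriv), ``minmax``.  Provenance is recorded in
    the output metadata.  An empty recipe returns the input unchanged.
    """
    steps = _normalize_recipe(recipe)
    if not steps:
        return sset
    out = sset
    spacing = float(np.abs(np.diff(out.axis.values)).mean())
    for name, params in steps:
        if name == "to_absorbance":
            out = convert_mode(out, ABSORBANCE)
            continue
        X = np.array(out.X, dtype=float, copy=True)
        if name == "airpls":
            cfg = AirPLSConfig(**params)
            for i in range(X.shape[0]):
                X[i] = airpls(X[i], cfg).corrected
        elif name == "sg":
            p = {"window": 11, "polyorder": 2, "deriv": 0}
            p.update(params)
            for i in range(X.shape[0]):
                X[i] = savitzky_golay(X[i], delta=spacing, **p)
        elif name == "minmax":
            for i in range(X.shape[0]):
                X[i] = minmax_normalize(X[i])
        out = replace(out, X=X)
    described = ";".join(
        name + ("" if not params else str(dict(sorted(params.items()))))
        for name, params in steps
    )
    return out.with_metadata(preprocessing_recipe=described)


def recipe_label(recipe: Sequence[Any]) -> str:
    steps = _normalize_recipe(recipe)
    names = [n for n, _ in steps if n != "to_absorbance"]
    return "-".join(names) if names else "without"
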