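"""Wavelength selection: competitive adaptive reweighted sampling (CARS)
and fixed chemistry-motivated peak lists (functional groups & moieties).

CARS shrinks the candidate wavelength set over N Monte-Carlo runs.  Each
run fits a PLS model on a random row subset of the calibration data,
weights every retained wavelength by its standardized absolute regression
coefficient (|b_j| * sd(x_j), the magnitude of the wavelength's term in
the prediction sum — invariant to per-channel scale), records the
repeated K-fold RMSECV of the current set at its CV-chosen component
count, then forms the next set by an enforced reduction to the
exponentially-decreasing-function (EDF) quota followed by weighted
adaptive reweighted sampling (ARS) with ceil(r * p0) draws.  Run 1
evaluates the full spectrum (the EDF ratio starts at 1).

The winning subset is the smallest retained set whose RMSECV is within
one cross-validation standard error of the trace minimum and no worse
than the full-spectrum run — the package-wide smallest-model tie rule
applied to a Monte-Carlo trace whose near-minimum is flat; a strict
argmin there is decided by fold noise rather than by the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .regression import kfold_indices, plsr_fit, plsr_predict
from .spectra_core import WavenumberAxis


@dataclass(frozen=True)
class CARSConfig:
    n_runs: int = 50
    mc_row_fraction: float = 0.8
    cv_folds: int = 5
    cv_repeats: int = 3
    pls_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not (0.0 < self.mc_row_fraction < 1.0):
            raise ValueError("mc_row_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if self.pls_components < 1:
            raise ValueError("pls_components must be >= 1")


@dataclass(frozen=True)
class CARSRun:
    indices: np.ndarray  # retained wavelength set evaluated this run
    ratio: float  # EDF quota ratio r_i
    rmsecv: float
    rmsecv_se: float = float("nan")
    n_components: int = 0  # CV-chosen internal component count


@dataclass(frozen=True)
class CARSResult:
    runs: tuple[CARSRun, ...]
    winner: int
    selected: np.ndarray

    @property
    def rmsecv_trace(self) -> np.ndarray:
        return np.array([r.rmsecv for r in self.runs])

    @property
    def size_trace(self) -> np.ndarray:
        return np.array([r.indices.size for r in self.runs])


def edf_schedule(p0: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retention ratios ``r_i = a exp(-k i)``.

    Calibrated so ``r_1 = 1`` (keep all ``p0`` variables) and
    ``r_N = 2/p0`` (keep two): ``a = (p0/2)^{1/(N-1)}``,
    ``k = ln(p0/2)/(N-1)``.
    """
    if p0 <= 2:
        raise ValueError("p0 must exceed 2")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    a = (p0 / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(p0 / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def ars_sample(
    weights: np.ndarray, draw_count: int, rng: np.random.Generator
) -> np.ndarray:
    """Adaptive reweighted sampling: ``draw_count`` weighted draws with
    replacement; returns the sorted unique positions drawn.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    if draw_count < 1:
        raise ValueError("draw_count must be >= 1")
    drawn = rng.choice(w.size, size=draw_count, replace=True, p=w / total)
    return np.unique(drawn)


def _repeated_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    foldsets: Sequence[Sequence[np.ndarray]],
    max_components: int,
) -> tuple[float, float, int]:
    """Repeated K-fold RMSECV of a wavelength subset.

    One PLS fit per fold at the component cap; per-component predictions
    come from sequential score projection, so the whole 1..cap curve costs
    a single fit per fold.  Returns ``(rmsecv, se, a_best)``: the pooled
    RMSECV at the CV-chosen component count, the standard error of that
    value across the individual folds, and the chosen count.
    """
    n = X.shape[0]
    cap = min(
        max_components,
        min(n - f.size for folds in foldsets for f in folds) - 1,
        X.shape[1],
    )
    per_fold = []  # rows: one fold; cols: rmse at component count a+1
    weights = []  # fold sizes, for pooling
    for folds in foldsets:
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            model = plsr_fit(X[train], y[train], cap)
            E = X[fold] - model.x_mean
            yhat = np.full(fold.size, model.y_mean)
            row = np.empty(cap)
            for a in range(cap):
                w = model.weights[:, a]
                if np.any(w):
                    t = E @ w
                    yhat = yhat + model.y_loadings[a] * t
                    E = E - np.outer(t, model.loadings[:, a])
                row[a] = float(np.mean((y[fold] - yhat) ** 2))
            per_fold.append(row)
            weights.append(fold.size)
    mse = np.asarray(per_fold)
    wts = np.asarray(weights, dtype=float)
    pooled = np.sqrt((mse * wts[:, None]).sum(axis=0) / wts.sum())
    a_best = int(np.argmin(pooled))
    fold_rmse = np.sqrt(mse[:, a_best])
    se = float(fold_rmse.std(ddof=1) / np.sqrt(fold_rmse.size)) if fold_rmse.size > 1 else 0.0
    return float(pooled[a_best]), se, a_best + 1


def cars_select(
    X: np.ndarray, y: np.ndarray, config: CARSConfig | None = None
) -> CARSResult:
    """Run CARS on calibration data and return the full per-run trace.

    Deterministic given ``config.seed``; retained-set sizes are
    non-increasing across runs.  The winner is the smallest retained set
    whose RMSECV is within one CV standard error of the trace minimum and
    not above the full-spectrum run's RMSECV (earliest run on ties), so
    the winning RMSECV never exceeds run 1's.
    """
    if config is None:
        config = CARSConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p0 = X.shape
    if p0 < 3:
        raise ValueError("need at least 3 candidate wavelengths")
    if n < config.cv_folds:
        raise ValueError("fewer samples than CV folds")
    if np.ptp(y) == 0:
        raise ValueError("reference values are constant; nothing to calibrate")
    rng = np.random.default_rng(config.seed)
    foldsets = [
        kfold_indices(n, config.cv_folds, int(rng.integers(2**31)))
        for _ in range(config.cv_repeats)
    ]
    ratios = edf_schedule(p0, config.n_runs)
    n_mc = math.ceil(config.mc_row_fraction * n)
    current = np.arange(p0)
    runs: list[CARSRun] = []
    for i in range(config.n_runs):
        rows = np.sort(rng.choice(n, size=n_mc, replace=False))
        # component count chosen by RMSECV on the current set (capped by
        # config and data); a fixed large count would let late components
        # overfit noise wavelengths and corrupt the coefficient weights
        rmsecv, se, a_best = _repeated_rmsecv(
            X[:, current], y, foldsets, config.pls_components
        )
        a = min(a_best, n_mc - 1, current.size)
        model = plsr_fit(X[np.ix_(rows, current)], y[rows], a)
        # standardized coefficient magnitude |b_j| * sd(x_j): the size of
        # the wavelength's term in the prediction, independent of channel
        # scale (raw |b| would inflate near-constant noise channels)
        w = np.abs(model.coef) * X[np.ix_(rows, current)].std(axis=0)
        runs.append(
            CARSRun(
                indices=current.copy(),
                ratio=float(ratios[i]),
                rmsecv=rmsecv,
                rmsecv_se=se,
                n_components=a_best,
            )
        )
        if i + 1 == config.n_runs:
            break
        # enforced reduction to the next EDF quota (floor of 2), then ARS
        # with ceil(r*p0) draws (with replacement, so draws may exceed the
        # candidate count; the unique survivors stay within the current set)
        quota = max(2, math.ceil(ratios[i + 1] * p0))
        order = np.lexsort((np.arange(current.size), -w))  # weight desc, index asc
        kept = order[: min(quota, current.size)]
        kept_w = w[kept]
        if kept_w.sum() <= 0:
            kept_w = np.ones_like(kept_w)  # degenerate fit: uniform resampling
        drawn = ars_sample(kept_w, quota, rng)
        current = np.sort(current[kept[drawn]])
    trace = np.array([r.rmsecv for r in runs])
    imin = int(np.argmin(trace))
    # smallest near-optimal subset: within 1 SE of the minimum, never worse
    # than the full-spectrum run
    threshold = min(trace[imin] + runs[imin].rmsecv_se, trace[0])
    candidates = [i for i in range(len(runs)) if trace[i] <= threshold]
    winner = min(candidates, key=lambda i: (runs[i].indices.size, i))
    return CARSResult(runs=tuple(runs), winner=winner, selected=runs[winner].indices)


# ---------------------------------------------------------------------------
# Fixed-peak (functional groups & moieties) selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakList:
    """Chemistry-motivated wavenumber centres with a matching tolerance."""

    centers: tuple[float, ...]
    tolerance: float = 2.0
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.labels and len(self.labels) != len(self.centers):
            raise ValueError("labels must match centers")


#: Default fixed-peak list (20 centres): the eleven strong absorption peaks
#: of an alfalfa mid-IR spectrum, the CARS-overlap peaks near the protein
#: amide/COOH region, three water-avoiding N-H shoulder positions flanking
#: the broad 3400 cm^-1 moisture band, and two high-importance neighbour
#: peaks flagged by forest importance analysis.
DEFAULT_FGM_CENTERS: tuple[float, ...] = (
    593.0, 600.0, 665.0, 1053.0, 1102.0, 1246.0, 1381.0, 1417.0,
    1630.0, 2915.0, 3394.0,
    1633.0, 1512.0, 1420.0, 1242.0,
    3368.0, 3445.0, 3477.0,
    1426.07, 1051.69,
)


def default_fgm_peaks(tolerance: float = 2.0) -> PeakList:
    return PeakList(centers=DEFAULT_FGM_CENTERS, tolerance=tolerance)


def fgm_select(
    axis: WavenumberAxis,
    peaks: PeakList | None = None,
    mean_spectrum: np.ndarray | None = None,
) -> np.ndarray:
    """Map peak centres to axis indices (nearest grid point, deduplicated).

    When the mean calibration spectrum is supplied, local extrema within
    ``tolerance`` of each centre are added as well — peak maxima drift a few
    cm^-1 between sample populations.  Indices come back sorted.
    """
    if peaks is None:
        peaks = default_fgm_peaks()
    wn = axis.values
    lo, hi = float(wn.min()), float(wn.max())
    if mean_spectrum is not None:
        mean_spectrum = np.asarray(mean_spectrum, dtype=float)
        if mean_spectrum.shape != wn.shape:
            raise ValueError("mean_spectrum length must match the axis")
        interior = np.zeros(wn.size, dtype=bool)
        interior[1:-1] = (
            (mean_spectrum[1:-1] > mean_spectrum[:-2])
            & (mean_spectrum[1:-1] > mean_spectrum[2:])
        ) | (
            (mean_spectrum[1:-1] < mean_spectrum[:-2])
            & (mean_spectrum[1:-1] < mean_spectrum[2:])
        )
    selected: set[int] = set()
    for c in peaks.centers:
        if not (lo <= c <= hi):
            raise ValueError(f"peak center {c} cm^-1 outside axis range [{lo}, {hi}]")
        selected.add(int(np.argmin(np.abs(wn - c))))
        if mean_spectrum is not None:
            near = np.flatnonzero(np.abs(wn - c) <= peaks.tolerance)
            selected.update(int(j) for j in near[interior[near]])
    return np.array(sorted(selected), dtype=int)
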