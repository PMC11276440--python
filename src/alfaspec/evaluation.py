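"""Dataset splitting, calibration/prediction statistics, and execution of
the pretreatment x selector x model combination matrix.

The headline statistics are the calibration-set coefficient of
determination and RMSE (Rc^2, RMSEC) and their prediction-set counterparts
(Rp^2, RMSEP):

    R^2   = 1 - sum (C_i - C_i_hat)^2 / sum (C_i - C_bar)^2
    RMSE  = sqrt( sum (C_i - C_i_hat)^2 / count )

with ``C_bar`` the mean measured value of the subset being scored (an
optional ``reference_mean`` lets callers substitute the predicted-value
mean).  Samples are split calibration/validation/prediction by a seeded
shuffle at a 7:1.5:1.5 ratio (floor/floor/remainder, so 90 samples give
63/13/14); hyperparameter searches run K-fold within the calibration set
only, and the prediction subset stays untouched until final scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_selection import (
    CARSConfig,
    CARSResult,
    PeakList,
    cars_select,
    default_fgm_peaks,
    fgm_select,
)
from .preprocessing import apply_recipe, recipe_label
from .regression import (
    DEFAULT_RFR_GRID,
    PLSRModel,
    RFRHyperparams,
    RFRModel,
    plsr_fit,
    plsr_predict,
    rfr_fit,
    rfr_grid_search,
    rfr_predict,
    select_components_kfold,
)
from .spectra_core import SpectraSet

DEFAULT_SPLIT_RATIO = (7.0, 1.5, 1.5)


@dataclass(frozen=True)
class SplitPlan:
    calibration: np.ndarray
    validation: np.ndarray
    prediction: np.ndarray
    ratio: tuple[float, float, float]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (self.calibration.size, self.validation.size, self.prediction.size)


def split_dataset(
    n: int,
    ratio: Sequence[float] = DEFAULT_SPLIT_RATIO,
    seed: int = 0,
) -> SplitPlan:
    """Seeded-random partition into calibration/validation/prediction.

    Counts are ``floor(r_cal*n)`` and ``floor(r_val*n)`` with the remainder
    going to prediction (normalised ratios), so 90 samples at 7:1.5:1.5
    give 63/13/14.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    r = np.asarray(ratio, dtype=float)
    if r.shape != (3,) or np.any(r <= 0):
        raise ValueError("ratio must be a positive triple")
    r = r / r.sum()
    # tiny epsilon so exact fractions (0.7 * 90 = 63) survive float rounding
    n_cal = int(np.floor(r[0] * n + 1e-9))
    n_val = int(np.floor(r[1] * n + 1e-9))
    n_pred = n - n_cal - n_val
    if min(n_cal, n_val, n_pred) < 1:
        raise ValueError(f"split of n={n} at ratio {tuple(ratio)} leaves an empty subset")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitPlan(
        calibration=np.sort(perm[:n_cal]),
        validation=np.sort(perm[n_cal : n_cal + n_val]),
        prediction=np.sort(perm[n_cal + n_val :]),
        ratio=(float(ratio[0]), float(ratio[1]), float(ratio[2])),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("observed/predicted must be equal-length with >= 2 values")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def r2_score(
    observed: np.ndarray,
    predicted: np.ndarray,
    reference_mean: float | None = None,
) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the observed mean unless ``reference_mean``
    overrides it (e.g. the predicted-value mean variant).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("observed/predicted must be equal-length with >= 2 values")
    if np.ptp(observed) == 0:
        raise ValueError("R^2 is undefined for constant observed values")
    center = float(np.mean(observed)) if reference_mean is None else float(reference_mean)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - center) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Combination runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedPipeline:
    """Selection + model fitted on calibration rows only."""

    selected: np.ndarray
    model: PLSRModel | RFRModel
    model_kind: str
    n_components: int | None = None
    rmsecv_curve: np.ndarray | None = None
    cars: CARSResult | None = None
    hyperparams: RFRHyperparams | None = None
    cv_table: tuple | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = X[:, self.selected]
        if self.model_kind == "plsr":
            return plsr_predict(self.model, Xs)
        return rfr_predict(self.model, Xs)


@dataclass(frozen=True)
class EvaluationReport:
    label: str
    pretreatment: str
    selector: str
    model_kind: str
    cv: bool
    n_features: int
    rmsec: float
    rc2: float
    rmsep: float
    rp2: float
    mae_prediction: float
    rmsev: float
    rv2: float
    pairs: Mapping[str, tuple[np.ndarray, np.ndarray]]
    selected_wavenumbers: np.ndarray
    seed: int
    rp2_literal: float = float("nan")
    details: Mapping[str, Any] = field(default_factory=dict)

    def recompute(self) -> dict[str, float]:
        """Re-derive the headline metrics from the stored (obs, pred) pairs."""
        cal_o, cal_p = self.pairs["calibration"]
        pre_o, pre_p = self.pairs["prediction"]
        return {
            "rmsec": rmse(cal_o, cal_p),
            "rc2": r2_score(cal_o, cal_p),
            "rmsep": rmse(pre_o, pre_p),
            "rp2": r2_score(pre_o, pre_p),
            "mae_prediction": float(np.mean(np.abs(pre_o - pre_p))),
        }


def derive_seeds(seed: int) -> dict[str, int]:
    """Named sub-seeds for every stochastic stage, all below 2^31."""
    state = np.random.SeedSequence(seed).generate_state(4, dtype=np.uint64)
    names = ("split", "cars", "cv", "rfr")
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def select_features(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    sset: SpectraSet,
    selector: str = "none",
    seeds: Mapping[str, int] | None = None,
    cars_config: CARSConfig | None = None,
    fgm_peaks: PeakList | None = None,
) -> tuple[np.ndarray, CARSResult | None]:
    """Run the configured wavelength selector on calibration rows only."""
    if seeds is None:
        seeds = derive_seeds(0)
    p = X_cal.shape[1]
    if selector == "none":
        return np.arange(p), None
    if selector == "cars":
        cfg = cars_config or CARSConfig()
        cfg = CARSConfig(
            n_runs=cfg.n_runs,
            mc_row_fraction=cfg.mc_row_fraction,
            cv_folds=cfg.cv_folds,
            pls_components=cfg.pls_components,
            seed=seeds["cars"],
        )
        result = cars_select(X_cal, y_cal, cfg)
        return result.selected, result
    if selector == "fgm":
        # axis-only mapping of the fixed peak list (20 indices on the
        # default axis); extremum augmentation stays opt-in via fgm_select
        return fgm_select(sset.axis, fgm_peaks or default_fgm_peaks()), None
    raise ValueError(f"unknown selector {selector!r}")


def fit_calibration(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    sset: SpectraSet,
    selector: str = "none",
    model_kind: str = "plsr",
    cv: bool = False,
    seeds: Mapping[str, int] | None = None,
    cars_config: CARSConfig | None = None,
    fgm_peaks: PeakList | None = None,
    **model_kwargs: Any,
) -> FittedPipeline:
    """Select wavelengths and fit the calibration model from calibration
    rows alone (the no-leakage contract of the pipeline)."""
    if seeds is None:
        seeds = derive_seeds(0)
    selected, cars_result = select_features(
        X_cal, y_cal, sset, selector, seeds, cars_config, fgm_peaks
    )
    return _refit_with_selection(
        X_cal, y_cal, selected, cars_result, model_kind, cv, seeds, **model_kwargs
    )


def run_combination(
    sset: SpectraSet,
    recipe: Sequence[Any] = (),
    selector: str = "none",
    model_kind: str = "plsr",
    cv: bool = False,
    seed: int = 0,
    ratio: Sequence[float] = DEFAULT_SPLIT_RATIO,
    split: SplitPlan | None = None,
    preprocessed: SpectraSet | None = None,
    fitted: FittedPipeline | None = None,
    **fit_kwargs: Any,
) -> EvaluationReport:
    """Execute preprocess -> split -> select -> (CV) -> fit -> evaluate.

    Selection and hyperparameter search see calibration rows only; the
    prediction subset enters only at final scoring.  ``split``,
    ``preprocessed`` and ``fitted`` allow callers to reuse stages across
    combinations without changing results.
    """
    if sset.y is None:
        raise ValueError("dataset has no reference values attached")
    pre = preprocessed if preprocessed is not None else apply_recipe(sset, recipe)
    n = pre.n_samples
    seeds = derive_seeds(seed)
    plan = split if split is not None else split_dataset(n, ratio, seeds["split"])
    cal, val, prd = plan.calibration, plan.validation, plan.prediction
    pipe = fitted if fitted is not None else fit_calibration(
        pre.X[cal], pre.y[cal], pre, selector, model_kind, cv, seeds, **fit_kwargs
    )
    # leakage guard: subsets disjoint; the model saw calibration rows only
    # (structural: fit_calibration receives pre.X[cal] and nothing else)
    if set(prd.tolist()) & (set(cal.tolist()) | set(val.tolist())):
        raise AssertionError("prediction rows leaked into calibration/validation")

    pairs = {}
    for name, idx in (("calibration", cal), ("validation", val), ("prediction", prd)):
        pairs[name] = (pre.y[idx].copy(), pipe.predict(pre.X[idx]))
    cal_o, cal_p = pairs["calibration"]
    val_o, val_p = pairs["validation"]
    pre_o, pre_p = pairs["prediction"]

    label_bits = [recipe_label(recipe)]
    if selector != "none":
        label_bits.append(selector.upper() if selector == "cars" else "FG&M")
    label_bits.append(model_kind.upper())
    if cv:
        label_bits.append("CV")
    return EvaluationReport(
        label="-".join(label_bits),
        pretreatment=recipe_label(recipe),
        selector=selector,
        model_kind=model_kind,
        cv=cv,
        n_features=int(pipe.selected.size),
        rmsec=rmse(cal_o, cal_p),
        rc2=r2_score(cal_o, cal_p),
        rmsep=rmse(pre_o, pre_p),
        rp2=r2_score(pre_o, pre_p),
        mae_prediction=float(np.mean(np.abs(pre_o - pre_p))),
        rmsev=rmse(val_o, val_p),
        rv2=r2_score(val_o, val_p),
        pairs=pairs,
        selected_wavenumbers=pre.axis.values[pipe.selected].copy(),
        seed=seed,
        rp2_literal=r2_score(pre_o, pre_p, reference_mean=float(np.mean(pre_p))),
        details={
            "n_components": pipe.n_components,
            "hyperparams": pipe.hyperparams,
            "split_sizes": plan.sizes,
        },
    )


#: The study's model-combination matrix: pretreatment comparison rows (the
#: "without" row models the instrument-native raw spectra directly) plus
#: the selector x model (x CV) grid on baseline-corrected absorbance.
_AIRPLS = ("to_absorbance", "airpls")
DEFAULT_MATRIX: tuple[dict[str, Any], ...] = (
    {"recipe": (), "selector": "none", "model_kind": "plsr", "cv": False},
    {"recipe": _AIRPLS, "selector": "none", "model_kind": "plsr", "cv": False},
    {"recipe": ("to_absorbance", "sg"), "selector": "none", "model_kind": "plsr", "cv": False},
    {"recipe": _AIRPLS, "selector": "cars", "model_kind": "plsr", "cv": False},
    {"recipe": _AIRPLS, "selector": "fgm", "model_kind": "plsr", "cv": False},
    {"recipe": _AIRPLS, "selector": "cars", "model_kind": "rfr", "cv": False},
    {"recipe": _AIRPLS, "selector": "fgm", "model_kind": "rfr", "cv": False},
    {"recipe": _AIRPLS, "selector": "cars", "model_kind": "plsr", "cv": True},
    {"recipe": _AIRPLS, "selector": "fgm", "model_kind": "plsr", "cv": True},
    {"recipe": _AIRPLS, "selector": "cars", "model_kind": "rfr", "cv": True},
    {"recipe": _AIRPLS, "selector": "fgm", "model_kind": "rfr", "cv": True},
)


def run_matrix(
    sset: SpectraSet,
    combos: Sequence[Mapping[str, Any]] = DEFAULT_MATRIX,
    seed: int = 0,
    **fit_kwargs: Any,
) -> list[EvaluationReport]:
    """Run a list of combinations, reusing preprocessing and wavelength
    selection across combinations that share them (results unchanged)."""
    seeds = derive_seeds(seed)
    plan = split_dataset(sset.n_samples, DEFAULT_SPLIT_RATIO, seeds["split"])
    pre_cache: dict[tuple, SpectraSet] = {}
    sel_cache: dict[tuple, tuple[np.ndarray, CARSResult | None]] = {}
    cars_config = fit_kwargs.pop("cars_config", None)
    fgm_peaks = fit_kwargs.pop("fgm_peaks", None)
    reports = []
    for combo in combos:
        recipe = tuple(combo.get("recipe", ()))
        selector = combo.get("selector", "none")
        if recipe not in pre_cache:
            pre_cache[recipe] = apply_recipe(sset, recipe)
        pre = pre_cache[recipe]
        cal = plan.calibration
        skey = (recipe, selector)
        if skey not in sel_cache:
            sel_cache[skey] = select_features(
                pre.X[cal], pre.y[cal], pre, selector, seeds, cars_config, fgm_peaks
            )
        selected, cars_result = sel_cache[skey]
        fitted = _refit_with_selection(
            pre.X[cal],
            pre.y[cal],
            selected,
            cars_result,
            combo.get("model_kind", "plsr"),
            combo.get("cv", False),
            seeds,
            **fit_kwargs,
        )
        reports.append(
            run_combination(
                sset,
                recipe=recipe,
                selector=selector,
                model_kind=combo.get("model_kind", "plsr"),
                cv=combo.get("cv", False),
                seed=seed,
                split=plan,
                preprocessed=pre,
                fitted=fitted,
            )
        )
    return reports


def _refit_with_selection(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    selected: np.ndarray,
    cars_result: CARSResult | None,
    model_kind: str,
    cv: bool,
    seeds: Mapping[str, int],
    n_components: int = 10,
    rfr_hyperparams: RFRHyperparams | None = None,
    rfr_grid: Mapping[str, Sequence[Any]] | None = None,
    cv_folds: int = 5,
    max_components: int = 15,
    **_: Any,
) -> FittedPipeline:
    if model_kind not in ("plsr", "rfr"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    Xs = X_cal[:, selected]
    if model_kind == "plsr":
        curve = None
        if cv:
            a_star, curve = select_components_kfold(
                Xs, y_cal, k=cv_folds, a_max=max_components, seed=seeds["cv"]
            )
        else:
            a_star = min(n_components, X_cal.shape[0] - 1, selected.size)
        model = plsr_fit(Xs, y_cal, a_star)
        return FittedPipeline(
            selected=selected, model=model, model_kind="plsr",
            n_components=a_star, rmsecv_curve=curve, cars=cars_result,
        )
    if cv:
        hp, table = rfr_grid_search(Xs, y_cal, grid=rfr_grid, k=cv_folds, seed=seeds["rfr"])
        cv_table = tuple(tuple(sorted(row.items())) for row in table)
    else:
        hp = rfr_hyperparams or RFRHyperparams(seed=seeds["rfr"])
        hp = RFRHyperparams(
            n_trees=hp.n_trees, max_depth=hp.max_depth,
            min_split=hp.min_split, min_leaf=hp.min_leaf, seed=seeds["rfr"],
        )
        cv_table = None
    model = rfr_fit(Xs, y_cal, hp)
    return FittedPipeline(
        selected=selected, model=model, model_kind="rfr",
        cars=cars_result, hyperparams=hp, cv_table=cv_table,
    )


def compare_models(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Rank combinations by prediction accuracy (Rp^2 desc, RMSEP asc)."""
    if not reports:
        raise ValueError("need at least one report")
    df = pd.DataFrame(
        {
            "Model": [r.label for r in reports],
            "Pretreatment": [r.pretreatment for r in reports],
            "Number": [r.n_features for r in reports],
            "RMSEC": [r.rmsec for r in reports],
            "Rc2": [r.rc2 for r in reports],
            "RMSEP": [r.rmsep for r in reports],
            "Rp2": [r.rp2 for r in reports],
        }
    )
    df = df.sort_values(["Rp2", "RMSEP"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def comparison_text(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.4f}")
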