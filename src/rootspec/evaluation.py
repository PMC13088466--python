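"""Accuracy metrics, train/test splitting, the area-based baseline model,
and paired comparison of prediction errors.

The baseline predicts segment dry weight from the percentage of the segment
covered by root pixels — cheap and intuitive, but it saturates once
coverage approaches 100% while biomass keeps accumulating through root
overlap; the spectral model exists precisely to beat it there.  Models are
compared with a two-sided paired t-test on absolute prediction errors over
a shared test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import substream
from .errors import InvalidInputError

__all__ = [
    "AreaModel",
    "EvaluationReport",
    "r_squared",
    "rmse",
    "mae",
    "split_train_test",
    "fit_area_model",
    "predict_area",
    "paired_abs_error_ttest",
    "evaluate_predictions",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise InvalidInputError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size == 0:
        raise InvalidInputError("empty input")
    return y, yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise InvalidInputError("need n >= 2 for R^2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidInputError("constant observations: R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def mae(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_train_test(
    table: pd.DataFrame,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform random split; train size ceil(train_frac * n).

    Rows are sampled without replacement, so the two parts are disjoint and
    exhaustive; the same seed always reproduces the same split.
    """
    if not 0.0 < train_frac < 1.0:
        raise InvalidInputError("train_frac must be in (0, 1)")
    n = len(table)
    if n < 5:
        raise InvalidInputError(f"need n >= 5 rows to split, got {n}")
    n_train = int(np.ceil(train_frac * n))
    perm = substream(seed, "split").permutation(n)
    return table.iloc[np.sort(perm[:n_train])], table.iloc[np.sort(perm[n_train:])]


# ---------------------------------------------------------------------------
# area-based baseline
# ---------------------------------------------------------------------------

@dataclass
class AreaModel:
    """Regression of dry weight on percent root coverage.

    ``power``: y = a * (x/100)**b,  ``saturating_exp``: y = a * (1 - exp(-b x)),
    ``linear``: y = a * x + c (clipped at 0).  Power and saturating forms are
    monotone non-decreasing and non-negative on coverage in [0, 100] by
    construction (a, b > 0).
    """

    form: str
    params: np.ndarray
    fit_rmse: float


def _area_forms():
    return {
        "power": lambda x, a, b: a * (x / 100.0) ** b,
        "saturating_exp": lambda x, a, b: a * (1.0 - np.exp(-b * x)),
        "linear": lambda x, a, c: a * x + c,
    }


def fit_area_model(coverage, dry_weight, form: str = "power") -> AreaModel:
    """Least-squares fit on sqrt-weight (same variance stabilisation as the
    spectral model) of dry weight vs percent coverage."""
    x = np.asarray(coverage, dtype=float).ravel()
    y = np.asarray(dry_weight, dtype=float).ravel()
    if x.size != y.size or x.size < 10:
        raise InvalidInputError("need >= 10 (coverage, weight) pairs")
    if np.any((x < 0) | (x > 100)):
        raise InvalidInputError("coverage must be in [0, 100]")
    if not np.any(x > 0):
        raise InvalidInputError("all-zero coverage: nothing to fit")
    forms = _area_forms()
    if form not in forms:
        raise InvalidInputError(f"unknown form {form!r}")
    f = forms[form]
    sqrt_y = np.sqrt(np.clip(y, 0, None))

    if form == "linear":
        params, _ = np.polyfit(x, y, 1), None
        params = np.array([params[0], params[1]])
        pred = np.clip(f(x, *params), 0, None)
        return AreaModel(form=form, params=params, fit_rmse=rmse(y, pred))

    def g(x_, a, b):  # fit in sqrt space
        return np.sqrt(np.clip(f(x_, a, b), 0, None))

    a0 = max(float(y.max()), 1e-6)
    b0 = 1.0 if form == "power" else 0.05
    params, _ = optimize.curve_fit(
        g, x, sqrt_y, p0=(a0, b0),
        bounds=([1e-12, 1e-6], [np.inf, np.inf]), maxfev=20000,
    )
    pred = np.clip(f(x, *params), 0, None)
    return AreaModel(form=form, params=np.asarray(params), fit_rmse=rmse(y, pred))


def predict_area(model: AreaModel, coverage) -> np.ndarray:
    """Predicted dry weight (g) at the given percent coverages, clipped at 0."""
    x = np.asarray(coverage, dtype=float)
    f = _area_forms()[model.form]
    return np.clip(f(x, *model.params), 0.0, None)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def paired_abs_error_ttest(err_a, err_b) -> tuple[float, int, float]:
    """Two-sided paired t-test on |err_a| - |err_b|; returns (t, df, p)."""
    a = np.abs(np.asarray(err_a, dtype=float).ravel())
    b = np.abs(np.asarray(err_b, dtype=float).ravel())
    if a.size != b.size:
        raise InvalidInputError("error vectors must have equal length")
    n = a.size
    if n < 3:
        raise InvalidInputError("need n >= 3 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise InvalidInputError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)


@dataclass
class EvaluationReport:
    """Per-model accuracy plus pairwise error comparisons."""

    metrics: dict  # model name -> {r2, rmse, mae, n}
    comparisons: dict = field(default_factory=dict)  # (a, b) -> {t, df, p}
    units: str = "g/segment"

    def to_dict(self) -> dict:
        return {
            "units": self.units,
            "metrics": self.metrics,
            "comparisons": {
                f"{a}_vs_{b}": v for (a, b), v in self.comparisons.items()
            },
        }

    def __str__(self) -> str:
        lines = [f"{'model':<14}{'R2':>8}{'RMSE':>10}{'MAE':>10}{'n':>6}  ({self.units})"]
        for name, m in self.metrics.items():
            lines.append(
                f"{name:<14}{m['r2']:>8.3f}{m['rmse']:>10.4f}{m['mae']:>10.4f}{m['n']:>6d}"
            )
        for (a, b), c in self.comparisons.items():
            lines.append(
                f"paired t-test |err {a}| vs |err {b}|: "
                f"t = {c['t']:.3f}, df = {c['df']}, p = {c['p']:.4g}"
            )
        return "\n".join(lines)


def evaluate_predictions(y_true, predictions: dict, units: str = "g/segment") -> EvaluationReport:
    """Build an :class:`EvaluationReport` for several models on one test set."""
    y = np.asarray(y_true, dtype=float).ravel()
    metrics = {}
    for name, yhat in predictions.items():
        metrics[name] = {
            "r2": r_squared(y, yhat),
            "rmse": rmse(y, yhat),
            "mae": mae(y, yhat),
            "n": int(y.size),
        }
    comparisons = {}
    names = list(predictions)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            try:
                t, df, p = paired_abs_error_ttest(
                    np.asarray(predictions[a]) - y, np.asarray(predictions[b]) - y
                )
                comparisons[(a, b)] = {"t": t, "df": df, "p": p}
            except InvalidInputError:
                pass
    return EvaluationReport(metrics=metrics, comparisons=comparisons, units=units)
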