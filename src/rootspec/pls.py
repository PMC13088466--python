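"""Orthogonal-scores PLS1 regression with VIP scores and LOOCV model selection.

Partial least squares regression projects the (mean-centred, unscaled)
spectra onto a small number of latent variables (LVs) chosen to maximise
covariance with the response, which makes it robust to the severe
band-to-band collinearity of hyperspectral data.  The classical
orthogonal-scores (NIPALS) algorithm is used: for each component

    w_a = X_a' y_a / ||X_a' y_a||      (weights)
    t_a = X_a w_a                      (orthogonal scores)
    p_a = X_a' t_a / (t_a' t_a)        (x-loadings)
    q_a = y_a' t_a / (t_a' t_a)        (y-loading)
    X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a

and the equivalent linear coefficients are b_A = W (P'W)^{-1} q, accumulated
per component so predictions at every LV count come from one fit.

The LV count is selected by leave-one-out cross-validation (smallest RMSECV,
ties to the fewest LVs, at most 16).  Variable importance in projection
(VIP) scores summarise each wavelength's contribution; their squares average
to 1, so VIP > 1 marks influential bands.

The dry-weight target is square-root transformed before fitting (weights are
right-skewed); predictions are clipped at zero in sqrt space and squared
back to grams.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .preprocessing import PreprocSpec, SpectrumTable, apply_spec, enumerate_grid

__all__ = [
    "PLSRModel",
    "CVResult",
    "fit_pls",
    "loocv_select",
    "vip_scores",
    "predict",
    "grid_search",
    "save_model",
    "load_model",
]

MAX_LV_DEFAULT = 16


@dataclass
class CVResult:
    """Leave-one-out RMSECV per candidate LV count and the selected count."""

    rmsecv_by_lv: np.ndarray
    selected_lv: int

    @property
    def min_rmsecv(self) -> float:
        return float(self.rmsecv_by_lv[self.selected_lv - 1])


@dataclass
class PLSRModel:
    """A fitted orthogonal-scores PLS1 model plus its frozen preprocessing."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # B x A
    x_loadings: np.ndarray  # B x A
    y_loadings: np.ndarray  # A
    score_norms: np.ndarray  # A, t_a' t_a
    coefficients: np.ndarray  # B, at n_lv components
    n_lv: int
    vip: np.ndarray | None = None
    y_transform: str = "identity"  # "identity" | "sqrt"
    preproc: PreprocSpec | None = None
    wavelengths_nm: np.ndarray | None = None
    cv: CVResult | None = None

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)

    def linear_predict(self, X: np.ndarray) -> np.ndarray:
        """Prediction in (transformed-) y units from preprocessed spectra."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.intercept


def _center(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    return X - x_mean, y - y_mean, x_mean, y_mean


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Extract up to ``n_lv`` components; returns (W, P, q, tt, coefs_by_lv).

    ``coefs_by_lv[a]`` is the coefficient vector using components 1..a+1.
    Extraction stops early (without error) when the residual covariance or
    score norm underflows, i.e. at the effective rank.
    """
    n, B = Xc.shape
    tol = 1e-12 * max(1.0, float(np.abs(Xc).max()) ** 2 * float(np.abs(yc).max() + 1.0))
    Xr = Xc.copy()
    yr = yc.copy()
    W, P, q, tt, R = [], [], [], [], []
    coefs = []
    b = np.zeros(B)
    for _ in range(n_lv):
        w = Xr.T @ yr
        nw = float(np.linalg.norm(w))
        if nw <= tol:
            break
        w /= nw
        t = Xr @ w
        t2 = float(t @ t)
        if t2 <= tol:
            break
        p = Xr.T @ t / t2
        qa = float(yr @ t) / t2
        Xr -= np.outer(t, p)
        yr = yr - qa * t
        r = w.copy()
        for pj, rj in zip(P, R):
            r -= (pj @ w) * rj
        b = b + qa * r
        W.append(w)
        P.append(p)
        q.append(qa)
        tt.append(t2)
        R.append(r)
        coefs.append(b.copy())
    return W, P, np.array(q), np.array(tt), coefs


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    y_transform: str = "identity",
    preproc: PreprocSpec | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> PLSRModel:
    """Fit orthogonal-scores PLS1 on (already preprocessed) X and y.

    ``y`` is in the (possibly transformed) regression scale.  If fewer than
    ``n_lv`` components can be extracted (rank deficiency, or a constant
    y), the model is fitted with the reduced count and a warning is issued;
    a fully degenerate fit predicts the mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InvalidInputError("X must be n x B with len(y) = n")
    if n_lv < 1:
        raise InvalidInputError("n_lv must be >= 1")
    if X.shape[0] < n_lv + 1:
        raise InvalidInputError(f"need at least n_lv+1={n_lv + 1} samples")
    Xc, yc, x_mean, y_mean = _center(X, y)
    W, P, q, tt, coefs = _nipals(Xc, yc, n_lv)
    a = len(W)
    if a < n_lv:
        warnings.warn(
            f"rank deficiency: extracted {a} of {n_lv} requested components",
            stacklevel=2,
        )
    B = X.shape[1]
    model = PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=np.column_stack(W) if a else np.zeros((B, 0)),
        x_loadings=np.column_stack(P) if a else np.zeros((B, 0)),
        y_loadings=q,
        score_norms=tt,
        coefficients=coefs[-1] if a else np.zeros(B),
        n_lv=max(a, 1) if a else 1,
        y_transform=y_transform,
        preproc=preproc,
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm, dtype=float),
    )
    if a:
        model.n_lv = a
        model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSRModel) -> np.ndarray:
    """Variable importance in projection for each band.

    VIP_j = sqrt( B * sum_a SSY_a * w_ja^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 t_a't_a the y-variance captured by component a and w_a the
    unit-norm weight vectors.  The mean of VIP^2 over bands is identically 1.
    """
    W = model.weights
    if W.shape[1] == 0:
        raise InvalidInputError("model has no components")
    ssy = model.y_loadings**2 * model.score_norms
    total = float(ssy.sum())
    if total <= 0:
        raise InvalidInputError("zero explained variance: VIP undefined")
    B = W.shape[0]
    wnorm2 = W**2 / np.maximum((W**2).sum(axis=0), 1e-300)
    return np.sqrt(B * (wnorm2 @ ssy) / total)


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predict dry weight (g) from raw spectra matching the model's bands.

    Applies the model's frozen preprocessing, the linear fit in the
    (possibly sqrt-) transformed scale, then back-transforms; negative
    sqrt-scale predictions are clipped to zero before squaring.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.preproc is not None:
        if model.wavelengths_nm is None:
            raise InvalidInputError("model with preprocessing must carry wavelengths")
        if X.shape[1] != model.wavelengths_nm.size:
            raise InvalidInputError(
                f"band mismatch: {X.shape[1]} columns vs {model.wavelengths_nm.size} model bands"
            )
        _, table = apply_spec(
            model.preproc,
            SpectrumTable(X=X, wavelengths_nm=model.wavelengths_nm),
            training=False,
        )
        X = table.X
    elif model.x_mean.size != X.shape[1]:
        raise InvalidInputError(
            f"band mismatch: {X.shape[1]} columns vs {model.x_mean.size} model bands"
        )
    yhat = model.linear_predict(X)
    if model.y_transform == "sqrt":
        yhat = np.clip(yhat, 0.0, None) ** 2
    return yhat


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _loocv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    spec: PreprocSpec | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> np.ndarray:
    """(n, A_max) held-out predictions; column a uses a+1 components.

    If ``spec`` is given, preprocessing is re-fitted inside every fold
    (only MSC has fitted state; stateless layers are applied once up
    front).  When a fold extracts fewer components than requested, its
    remaining columns repeat the last available prediction.
    """
    n, B = X.shape
    a_max = min(max_lv, n - 2, B)
    if a_max < 1:
        raise InvalidInputError("too few samples for cross-validation")
    msc = spec is not None and spec.layer3 == "msc"
    if spec is not None:
        from dataclasses import replace

        stateless = replace(spec, layer3="none") if msc else spec
        _, t = apply_spec(stateless, SpectrumTable(X=X, wavelengths_nm=wavelengths_nm), training=True)
        Z = t.X
    else:
        Z = X
    preds = np.empty((n, a_max))
    idx = np.arange(n)
    from .preprocessing import msc_apply

    for i in range(n):
        tr = idx != i
        Ztr, zte = Z[tr], Z[i]
        if msc:
            ref = Ztr.mean(axis=0)
            Ztr = msc_apply(Ztr, ref)
            zte = msc_apply(zte, ref)
        Xc, yc, x_mean, y_mean = _center(Ztr, y[tr])
        _, _, _, _, coefs = _nipals(Xc, yc, a_max)
        xc = zte - x_mean
        if coefs:
            vals = np.array([y_mean + xc @ b for b in coefs])
            preds[i, : len(vals)] = vals
            preds[i, len(vals):] = vals[-1]
        else:
            preds[i, :] = y_mean
    return preds


def loocv_select(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = MAX_LV_DEFAULT,
    spec: PreprocSpec | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> CVResult:
    """Choose the LV count minimising leave-one-out RMSECV (ties: fewest LVs)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size or y.size < 3:
        raise InvalidInputError("need n >= 3 samples for LOOCV")
    preds = _loocv_predictions(X, y, max_lv, spec=spec, wavelengths_nm=wavelengths_nm)
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return CVResult(rmsecv_by_lv=rmsecv, selected_lv=int(np.argmin(rmsecv)) + 1)


# ---------------------------------------------------------------------------
# preprocessing grid search
# ---------------------------------------------------------------------------

def grid_search(
    train_table: SpectrumTable,
    specs: list[PreprocSpec] | None = None,
    max_lv: int = MAX_LV_DEFAULT,
    y_transform: str = "sqrt",
) -> tuple[PLSRModel, CVResult, pd.DataFrame]:
    """Evaluate every preprocessing spec by LOOCV and refit the winner.

    For each spec the LV count is chosen by leave-one-out RMSECV on the
    training table (in sqrt-weight units when ``y_transform='sqrt'``); the
    spec with the smallest minimum RMSECV wins, ties resolving to the
    earlier spec in grid order.  Returns the refitted model, its CV result,
    and the full ranking table.
    """
    if train_table.y is None:
        raise InvalidInputError("training table must carry dry weights")
    if specs is None:
        specs = enumerate_grid()
    n = train_table.X.shape[0]
    if n < 20:
        raise InvalidInputError(f"need at least ~20 training rows, got {n}")
    y = np.sqrt(train_table.y) if y_transform == "sqrt" else train_table.y

    rows = []
    results: list[CVResult | None] = []
    failures: list[str] = []
    for k, spec in enumerate(specs):
        try:
            cv = loocv_select(
                train_table.X, y, max_lv=max_lv, spec=spec,
                wavelengths_nm=train_table.wavelengths_nm,
            )
            results.append(cv)
            rows.append(
                {
                    "rank_order": k,
                    "layer1": spec.layer1,
                    "layer2": spec.layer2,
                    "layer3": spec.layer3,
                    "selected_lv": cv.selected_lv,
                    "rmsecv": cv.min_rmsecv,
                }
            )
        except InvalidInputError as e:
            results.append(None)
            failures.append(f"{spec.name}: {e}")
            rows.append(
                {
                    "rank_order": k,
                    "layer1": spec.layer1,
                    "layer2": spec.layer2,
                    "layer3": spec.layer3,
                    "selected_lv": 0,
                    "rmsecv": np.inf,
                }
            )
    ranking = pd.DataFrame(rows)
    if all(r is None for r in results):
        raise InvalidInputError("all preprocessing specs failed:\n" + "\n".join(failures))
    best_idx = int(ranking["rmsecv"].idxmin())  # idxmin takes the first minimum
    best_cv = results[best_idx]
    fitted_spec, table = apply_spec(specs[best_idx], train_table, training=True)
    model = fit_pls(
        table.X,
        y,
        n_lv=best_cv.selected_lv,
        y_transform=y_transform,
        preproc=fitted_spec,
        wavelengths_nm=train_table.wavelengths_nm,
    )
    model.cv = best_cv
    return model, best_cv, ranking


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: PLSRModel, path: str) -> None:
    d = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "score_norms": model.score_norms.tolist(),
        "coefficients": model.coefficients.tolist(),
        "n_lv": model.n_lv,
        "vip": None if model.vip is None else model.vip.tolist(),
        "y_transform": model.y_transform,
        "preproc": None if model.preproc is None else json.loads(model.preproc.to_json()),
        "wavelengths_nm": None
        if model.wavelengths_nm is None
        else model.wavelengths_nm.tolist(),
    }
    with open(path, "w") as f:
        json.dump(d, f)


def load_model(path: str) -> PLSRModel:
    with open(path) as f:
        d = json.load(f)
    pre = d["preproc"]
    return PLSRModel(
        x_mean=np.array(d["x_mean"]),
        y_mean=d["y_mean"],
        weights=np.array(d["weights"]),
        x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]),
        score_norms=np.array(d["score_norms"]),
        coefficients=np.array(d["coefficients"]),
        n_lv=d["n_lv"],
        vip=None if d["vip"] is None else np.array(d["vip"]),
        y_transform=d["y_transform"],
        preproc=None if pre is None else PreprocSpec.from_json(json.dumps(pre)),
        wavelengths_nm=None
        if d["wavelengths_nm"] is None
        else np.array(d["wavelengths_nm"]),
    )
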