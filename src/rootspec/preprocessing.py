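"""Chemometric spectral preprocessing: a three-layer combination grid.

Spectra are conditioned before regression by choosing one method from each
of three layers and applying them in order:

    layer 1: none | normalization (unit L2 norm) | log (absorbance log10(1/R))
    layer 2: none | Savitzky-Golay smoothing | 1st derivative | 2nd derivative
    layer 3: none | SNV | MSC

giving 3 x 4 x 3 = 36 combinations.  SNV standardises each spectrum to mean
0 / sd 1; MSC regresses each spectrum on a reference (the training-set mean)
and inverts the fitted affine distortion; both target the multiplicative
scatter artifacts that plague diffuse-reflectance imaging.  Derivatives are
computed by Savitzky-Golay convolution (window 11, polyorder 2 by default)
and scaled per nm of band spacing.

Only MSC has fitted state (its reference spectrum).  ``apply_spec`` with
``training=True`` fits that reference and freezes it into the returned spec
so test spectra and pixel spectra are corrected against the training
reference, never their own.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import InvalidInputError

__all__ = [
    "PreprocSpec",
    "SpectrumTable",
    "LAYER1_OPTIONS",
    "LAYER2_OPTIONS",
    "LAYER3_OPTIONS",
    "enumerate_grid",
    "normalize_spectrum",
    "log_transform",
    "savgol",
    "snv",
    "msc_fit",
    "msc_apply",
    "apply_spec",
]

LAYER1_OPTIONS = ("none", "normalization", "log")
LAYER2_OPTIONS = ("none", "savgol", "deriv1", "deriv2")
LAYER3_OPTIONS = ("none", "snv", "msc")

LOG_FLOOR = 1e-6
MSC_MIN_SLOPE = 1e-8


@dataclass
class PreprocSpec:
    """One cell of the preprocessing grid, optionally carrying fitted state."""

    layer1: str = "none"
    layer2: str = "none"
    layer3: str = "none"
    savgol_window: int = 11
    savgol_polyorder: int = 2
    msc_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.layer1 not in LAYER1_OPTIONS:
            raise InvalidInputError(f"unknown layer1 {self.layer1!r}")
        if self.layer2 not in LAYER2_OPTIONS:
            raise InvalidInputError(f"unknown layer2 {self.layer2!r}")
        if self.layer3 not in LAYER3_OPTIONS:
            raise InvalidInputError(f"unknown layer3 {self.layer3!r}")
        if self.savgol_window % 2 == 0 or self.savgol_window < 5:
            raise InvalidInputError("savgol_window must be odd and >= 5")
        if not self.savgol_window > self.savgol_polyorder:
            raise InvalidInputError("savgol_window must exceed savgol_polyorder")

    @property
    def name(self) -> str:
        return f"{self.layer1}/{self.layer2}/{self.layer3}"

    @property
    def is_fitted(self) -> bool:
        return self.layer3 != "msc" or self.msc_reference is not None

    def to_json(self) -> str:
        d = {
            "layer1": self.layer1,
            "layer2": self.layer2,
            "layer3": self.layer3,
            "savgol_window": self.savgol_window,
            "savgol_polyorder": self.savgol_polyorder,
        }
        if self.msc_reference is not None:
            d["msc_reference"] = np.asarray(self.msc_reference).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "PreprocSpec":
        d = json.loads(text)
        ref = d.pop("msc_reference", None)
        return cls(msc_reference=None if ref is None else np.asarray(ref, dtype=float), **d)


@dataclass
class SpectrumTable:
    """n spectra (rows) with wavelengths and optional dry-weight targets."""

    X: np.ndarray
    wavelengths_nm: np.ndarray
    y: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.wavelengths_nm.size:
            raise InvalidInputError("X must be n x B with B = len(wavelengths)")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.X.shape[0],):
                raise InvalidInputError("y length must match X rows")
            if np.any(self.y < 0):
                raise InvalidInputError("dry weights must be non-negative")

    @property
    def band_spacing_nm(self) -> float:
        return float(np.mean(np.diff(self.wavelengths_nm)))


def enumerate_grid(savgol_window: int = 11, savgol_polyorder: int = 2) -> list[PreprocSpec]:
    """All 36 layer combinations, in grid order (layer 3 varies fastest)."""
    return [
        PreprocSpec(l1, l2, l3, savgol_window=savgol_window, savgol_polyorder=savgol_polyorder)
        for l1, l2, l3 in itertools.product(LAYER1_OPTIONS, LAYER2_OPTIONS, LAYER3_OPTIONS)
    ]


# ---------------------------------------------------------------------------
# primitives (row-wise; each accepts a 1-D spectrum or an n x B matrix)
# ---------------------------------------------------------------------------

def _as2d(x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim == 2:
        return x, False
    raise InvalidInputError("spectra must be 1-D or 2-D")


def normalize_spectrum(x: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm."""
    X, squeeze = _as2d(x)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise InvalidInputError("cannot normalize a zero spectrum")
    out = X / norms
    return out[0] if squeeze else out


def log_transform(x: np.ndarray) -> np.ndarray:
    """Absorbance transform log10(1/R), flooring R at 1e-6."""
    X, squeeze = _as2d(x)
    out = np.log10(1.0 / np.maximum(X, LOG_FLOOR))
    return out[0] if squeeze else out


def savgol(
    x: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
    deriv_order: int = 0,
    band_spacing_nm: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing or derivative along the band axis.

    Derivatives are per nm (``delta=band_spacing_nm``); edges use the
    polynomial fitted to the end windows.
    """
    if deriv_order not in (0, 1, 2):
        raise InvalidInputError("deriv_order must be 0, 1 or 2")
    if window % 2 == 0 or not window > polyorder or polyorder < deriv_order:
        raise InvalidInputError(
            "require odd window > polyorder >= deriv_order "
            f"(got window={window}, polyorder={polyorder}, deriv={deriv_order})"
        )
    X, squeeze = _as2d(x)
    if X.shape[1] < window:
        raise InvalidInputError("spectrum shorter than the filter window")
    out = savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv_order,
        delta=band_spacing_nm, axis=1, mode="interp",
    )
    return out[0] if squeeze else out


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum (sd, n-1)."""
    X, squeeze = _as2d(x)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise InvalidInputError("SNV undefined for a constant spectrum")
    out = (X - mu) / sd
    return out[0] if squeeze else out


def msc_fit(X_train: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the band-wise mean of the training spectra."""
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("MSC needs at least 2 training spectra")
    return X.mean(axis=0)


def msc_apply(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Correct spectra by inverting their affine fit to the reference.

    Each spectrum is regressed as ``x ~ a + b * reference`` (least squares)
    and returned as ``(x - a) / b``.
    """
    X, squeeze = _as2d(x)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise InvalidInputError("reference length must match band count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise InvalidInputError("constant MSC reference")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < MSC_MIN_SLOPE):
        raise InvalidInputError("MSC slope ~ 0: spectrum unrelated to reference")
    a = X.mean(axis=1) - b * ref.mean()
    out = (X - a[:, None]) / b[:, None]
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def apply_spec(
    spec: PreprocSpec,
    table: SpectrumTable,
    training: bool = True,
) -> tuple[PreprocSpec, SpectrumTable]:
    """Apply the three layers in order to every row of ``table``.

    With ``training=True`` the MSC reference (if any) is fitted on the
    layer-1/2 output of this table and stored in the returned spec; with
    ``training=False`` the spec must already carry its fitted reference.
    Returns ``(fitted_spec, transformed_table)``.
    """
    X = table.X
    try:
        if spec.layer1 == "normalization":
            X = normalize_spectrum(X)
        elif spec.layer1 == "log":
            X = log_transform(X)
        if spec.layer2 != "none":
            deriv = {"savgol": 0, "deriv1": 1, "deriv2": 2}[spec.layer2]
            X = savgol(
                X, spec.savgol_window, spec.savgol_polyorder, deriv,
                band_spacing_nm=table.band_spacing_nm,
            )
        fitted = spec
        if spec.layer3 == "snv":
            X = snv(X)
        elif spec.layer3 == "msc":
            if training:
                fitted = replace(spec, msc_reference=msc_fit(X))
            elif spec.msc_reference is None:
                raise InvalidInputError(
                    f"spec {spec.name} not fitted: MSC reference missing"
                )
            else:
                fitted = spec
            X = msc_apply(X, fitted.msc_reference)
    except InvalidInputError as e:
        raise InvalidInputError(f"preprocessing {spec.name} failed: {e}") from e
    return fitted, SpectrumTable(X=X, wavelengths_nm=table.wavelengths_nm, y=table.y, ids=table.ids)
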