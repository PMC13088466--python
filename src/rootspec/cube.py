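"""Hyperspectral cube container, ENVI-style I/O, radiometric calibration.

A :class:`SpectralCube` holds a calibrated reflectance image ``R(x, lambda)``
with one wavelength (nm) per band.  Cubes are stored on disk as a plain-text
ENVI header (``.hdr``) next to a band-sequential float32 binary, the format
understood by most hyperspectral software; an HDF5 single-file container is
offered as an alternative.

Radiometric calibration converts raw digital numbers to reflectance with the
standard white-reference / dark-frame normalisation

    R = (DN - dark) / (white - dark)

per band, which cancels the spectral shape of the illuminant and the sensor
gain.  Reflectance is clipped to [0, 1.5]: values slightly above 1 occur on
specular highlights and are retained, while gross outliers are bounded.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, FormatError, InvalidInputError

__all__ = [
    "SpectralCube",
    "RGBImage",
    "calibrate",
    "trim_bands",
    "rgb_composite",
    "read_cube",
    "write_cube",
    "read_cube_hdf5",
    "write_cube_hdf5",
    "nearest_band",
]

REFLECTANCE_CLIP = 1.5


@dataclass
class SpectralCube:
    """Calibrated reflectance image with per-band wavelengths.

    Attributes
    ----------
    reflectance : (H, W, B) float array, dimensionless, clipped to [0, 1.5].
    wavelengths_nm : (B,) strictly increasing band centres in nm.
    pixel_size_cm : ground sampling distance of one pixel.
    provenance : free-text processing history.
    """

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_size_cm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.reflectance.ndim != 3:
            raise InvalidInputError("reflectance must be H x W x B")
        if self.reflectance.shape[2] != self.wavelengths_nm.size:
            raise InvalidInputError(
                f"band count {self.reflectance.shape[2]} != "
                f"{self.wavelengths_nm.size} wavelengths"
            )
        if self.wavelengths_nm.size >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if not self.pixel_size_cm > 0:
            raise InvalidInputError("pixel_size_cm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    def band_nearest(self, wavelength_nm: float) -> int:
        """Index of the band whose centre is closest to ``wavelength_nm``."""
        return nearest_band(self.wavelengths_nm, wavelength_nm)


@dataclass
class RGBImage:
    """False-RGB composite with the three source wavelengths recorded."""

    rgb: np.ndarray
    band_wavelengths_nm: tuple[float, float, float] = field(default=(650.0, 550.0, 450.0))

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise InvalidInputError("rgb must be H x W x 3")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise InvalidInputError("rgb values must lie in [0, 1]")


def nearest_band(wavelengths_nm: np.ndarray, target_nm: float) -> int:
    return int(np.argmin(np.abs(np.asarray(wavelengths_nm, dtype=float) - target_nm)))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(raw, pixel_size_cm: float | None = None) -> SpectralCube:
    """White/dark radiometric calibration of a raw digital-number scene.

    Parameters
    ----------
    raw : RawScene
        Object with ``dn_cube`` (H, W, B), ``white_frame`` and ``dark_frame``
        (B,) and ``optics.wavelengths_nm``.
    pixel_size_cm : override for the pixel pitch; defaults to ``raw.pixel_size_cm``.

    Returns the reflectance cube ``(DN - dark) / (white - dark)`` clipped to
    [0, 1.5].  Any band with ``white <= dark`` cannot be normalised and raises
    :class:`CalibrationError` naming the first offending band.
    """
    dn = np.asarray(raw.dn_cube, dtype=np.float32)
    white = np.asarray(raw.white_frame, dtype=np.float64)
    dark = np.asarray(raw.dark_frame, dtype=np.float64)
    denom = white - dark
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise CalibrationError(
            f"white <= dark in band {bad[0]} "
            f"({raw.optics.wavelengths_nm[bad[0]]:.1f} nm)"
        )
    refl = (dn - dark.astype(np.float32)) / denom.astype(np.float32)
    np.clip(refl, 0.0, REFLECTANCE_CLIP, out=refl)
    if pixel_size_cm is None:
        pixel_size_cm = getattr(raw, "pixel_size_cm", 25.0 / 512.0)
    return SpectralCube(
        reflectance=refl,
        wavelengths_nm=np.asarray(raw.optics.wavelengths_nm, dtype=float),
        pixel_size_cm=float(pixel_size_cm),
        provenance="calibrated:(DN-dark)/(white-dark)",
    )


def trim_bands(cube: SpectralCube, lo_nm: float = 450.0, hi_nm: float = 950.0) -> SpectralCube:
    """Keep bands with ``lo_nm <= lambda <= hi_nm`` (inclusive both ends).

    The spectral edges of push-broom sensors are noisy; trimming to the
    analysis range is done once after calibration.
    """
    if not lo_nm < hi_nm:
        raise InvalidInputError("lo_nm must be < hi_nm")
    keep = (cube.wavelengths_nm >= lo_nm) & (cube.wavelengths_nm <= hi_nm)
    if not keep.any():
        raise InvalidInputError(f"no bands in [{lo_nm}, {hi_nm}] nm")
    return SpectralCube(
        reflectance=cube.reflectance[:, :, keep],
        wavelengths_nm=cube.wavelengths_nm[keep],
        pixel_size_cm=cube.pixel_size_cm,
        provenance=cube.provenance + f"|trim[{lo_nm:g},{hi_nm:g}]",
    )


def rgb_composite(cube: SpectralCube) -> RGBImage:
    """Min-max scaled composite from the bands nearest 650/550/450 nm.

    A flat channel (max == min) maps to all zeros rather than erroring, so
    batch pipelines survive empty scenes.
    """
    wl = cube.wavelengths_nm
    if wl.min() > 450.0 or wl.max() < 700.0:
        raise InvalidInputError("cube must span at least 450-700 nm for an RGB composite")
    targets = (650.0, 550.0, 450.0)
    chans = []
    used = []
    for t in targets:
        b = cube.band_nearest(t)
        used.append(float(wl[b]))
        sl = cube.reflectance[:, :, b].astype(float)
        lo, hi = float(sl.min()), float(sl.max())
        chans.append(np.zeros_like(sl) if hi <= lo else (sl - lo) / (hi - lo))
    return RGBImage(rgb=np.stack(chans, axis=-1), band_wavelengths_nm=tuple(used))


# ---------------------------------------------------------------------------
# ENVI-style I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32}


def write_cube(cube: SpectralCube, path: str) -> None:
    """Write ``path``(.hdr) + raw band-sequential float32 binary."""
    base = _strip_hdr(path)
    data = np.ascontiguousarray(
        np.transpose(cube.reflectance.astype(np.float32), (2, 0, 1))
    )  # BSQ: band, row, col
    h, w, b = cube.shape
    wl = ", ".join(f"{v:.6f}" for v in cube.wavelengths_nm)
    hdr = (
        "ENVI\n"
        f"description = {{{cube.provenance or 'rootspec cube'}}}\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\ninterleave = bsq\nbyte order = 0\n"
        "wavelength units = nm\n"
        f"pixel size cm = {cube.pixel_size_cm!r}\n"
        f"wavelength = {{{wl}}}\n"
    )
    with open(base + ".hdr", "w") as f:
        f.write(hdr)
    data.tofile(base + ".img")


def _strip_hdr(path: str) -> str:
    for ext in (".hdr", ".img"):
        if path.endswith(ext):
            return path[: -len(ext)]
    return path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # collapse brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_cube(path: str) -> SpectralCube:
    """Read an ENVI header + binary pair written by :func:`write_cube`.

    Wavelengths declared in micrometres (``wavelength units``) are converted
    to nm on read.
    """
    base = _strip_hdr(path)
    hdr_path = base + ".hdr"
    if not os.path.exists(hdr_path):
        raise FormatError(f"missing header {hdr_path}")
    with open(hdr_path) as f:
        fields = _parse_envi_header(f.read())
    try:
        h = int(fields["lines"])
        w = int(fields["samples"])
        b = int(fields["bands"])
    except KeyError as e:  # pragma: no cover - malformed external file
        raise FormatError(f"header missing {e}") from e
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if "wavelength" not in fields:
        raise FormatError("header has no wavelength metadata")
    wl = np.array(
        [float(v) for v in fields["wavelength"].strip("{} ").split(",") if v.strip()]
    )
    if wl.size != b:
        raise FormatError(f"header declares {b} bands but {wl.size} wavelengths")
    units = fields.get("wavelength units", "nm").lower()
    if units in ("micrometers", "micrometres", "um"):
        wl = wl * 1000.0
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise FormatError(f"unsupported interleave {interleave!r}")
    data = np.fromfile(base + ".img", dtype=_ENVI_DTYPES[dtype_code])
    if data.size != h * w * b:
        raise FormatError(
            f"binary holds {data.size} values, header implies {h * w * b}"
        )
    refl = np.transpose(data.reshape(b, h, w), (1, 2, 0))
    px = float(fields.get("pixel size cm", 25.0 / 512.0))
    return SpectralCube(
        reflectance=refl,
        wavelengths_nm=wl,
        pixel_size_cm=px,
        provenance=fields.get("description", "").strip("{} "),
    )


def write_cube_hdf5(cube: SpectralCube, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.reflectance.astype(np.float32))
        f.create_dataset("wavelengths_nm", data=cube.wavelengths_nm)
        f.create_dataset("pixel_size_cm", data=cube.pixel_size_cm)
        f.attrs["provenance"] = cube.provenance


def read_cube_hdf5(path: str) -> SpectralCube:
    import h5py

    with h5py.File(path, "r") as f:
        return SpectralCube(
            reflectance=f["reflectance"][()],
            wavelengths_nm=f["wavelengths_nm"][()],
            pixel_size_cm=float(f["pixel_size_cm"][()]),
            provenance=str(f.attrs.get("provenance", "")),
        )
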