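"""Hyperspectral cube I/O, radiometric conversion, and noisy-band removal.

Cubes are stored on disk in the ENVI convention: a flat binary raster
(BIL, BIP, or BSQ interleave) next to a plain-text ``.hdr`` file that
carries the spatial/spectral dimensions and the band-center wavelengths.
Only the small, portable subset of the header needed for push-broom
reflectance work is supported; vendor-specific calibration files are out
of scope (DN -> radiance is a per-band linear gain/offset).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpectralCube",
    "BandFilter",
    "read_cube",
    "write_cube",
    "to_reflectance",
    "remove_noisy_bands",
    "DEFAULT_EDGE_TRIM",
    "DEFAULT_REMOVAL_WINDOWS",
]

#: Bands dropped at each spectral end by default (high sensor noise).
DEFAULT_EDGE_TRIM = 5

#: Default removal windows (nm): O2 absorption near 760 nm and H2O near 820 nm.
DEFAULT_REMOVAL_WINDOWS = ((753.0, 766.0), (813.0, 827.0))

_STATES = ("dn", "radiance", "reflectance")

# ENVI data-type codes <-> numpy dtypes (little-endian; byte order 0)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectralCube:
    """A calibrated hyperspectral data cube.

    Parameters
    ----------
    values : ndarray, shape (rows, cols, bands)
        Pixel values. Unitless reflectance, radiance in W m-2 sr-1 nm-1,
        or raw digital numbers depending on ``state``.
    band_centers : ndarray, shape (bands,)
        Band-center wavelengths in nm, strictly increasing.
    state : {"dn", "radiance", "reflectance"}
        Radiometric state of ``values``. Reflectance values above 1 are
        permitted (specular pixels exist) but must be non-negative.
    """

    values: np.ndarray
    band_centers: np.ndarray
    state: str = "reflectance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if self.band_centers.ndim != 1 or len(self.band_centers) != self.values.shape[2]:
            raise ValueError("band_centers length must equal the band axis")
        if len(self.band_centers) > 1 and not np.all(np.diff(self.band_centers) > 0):
            raise ValueError("band_centers must be strictly increasing")
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}, got {self.state!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")
        if self.state == "reflectance" and np.any(self.values < 0):
            raise ValueError("reflectance values must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest to ``wavelength_nm``.

        Wavelengths outside the covered spectral range are rejected.
        """
        lo, hi = self.band_centers[0], self.band_centers[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside spectral range [{lo}, {hi}] nm"
            )
        return int(np.argmin(np.abs(self.band_centers - wavelength_nm)))


@dataclass
class BandFilter:
    """Record of a band-removal step, reusable and idempotent.

    ``kept_indices`` index into the original band list; a kept band center
    never lies inside any removal window (windows are closed nm intervals).
    """

    kept_indices: np.ndarray
    kept_centers: np.ndarray
    removal_windows: tuple = ()
    edge_trim: int = 0

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        self.kept_centers = np.asarray(self.kept_centers, dtype=float)
        if len(self.kept_indices) and not np.all(np.diff(self.kept_indices) > 0):
            raise ValueError("kept_indices must be strictly increasing")

    def apply(self, cube: SpectralCube) -> SpectralCube:
        """Apply the same band selection to ``cube`` (by band center, so a
        second application to an already-filtered cube is the identity)."""
        keep = np.isin(cube.band_centers, self.kept_centers)
        if not keep.any():
            raise ValueError("filter keeps no band of this cube")
        return SpectralCube(cube.values[:, :, keep], cube.band_centers[keep],
                            cube.state)


def _header_path(path: Path) -> Path:
    hdr = path.with_suffix(path.suffix + ".hdr")
    if hdr.exists():
        return hdr
    alt = path.with_suffix(".hdr")
    if alt.exists():
        return alt
    return hdr


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in body.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(path: str | Path, state: str | None = None) -> SpectralCube:
    """Read an ENVI-style raster plus header into a :class:`SpectralCube`.

    The header must list band wavelengths in a ``wavelength`` field. The
    radiometric state is taken from a nonstandard ``state`` header tag
    when present, overridable by the ``state`` argument; reflectance is
    assumed otherwise.
    """
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise FileNotFoundError(f"ENVI header not found for {path}")
    fields = _parse_envi_header(hdr.read_text())

    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength list")
    wl_text = fields["wavelength"].strip().strip("{}")
    band_centers = np.array(
        [float(tok) for tok in wl_text.replace(",", " ").split()], dtype=float
    )
    if len(band_centers) != bands:
        raise ValueError("wavelength list length does not match band count")
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("only little-endian (byte order 0) rasters supported")
    offset = int(fields.get("header offset", "0"))

    raw = np.fromfile(path, dtype=_ENVI_DTYPES[dtype_code], offset=offset)
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"data size {raw.size} does not match header "
            f"{rows}x{cols}x{bands} = {rows * cols * bands}"
        )
    if interleave == "bip":  # (rows, cols, bands)
        values = raw.reshape(rows, cols, bands)
    elif interleave == "bil":  # (rows, bands, cols)
        values = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":  # (bands, rows, cols)
        values = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    resolved = state or fields.get("state", "reflectance")
    return SpectralCube(np.ascontiguousarray(values, dtype=np.float64),
                        band_centers, resolved)


def write_cube(cube: SpectralCube, path: str | Path, interleave: str = "bil",
               dtype=np.float32) -> Path:
    """Write ``cube`` as an ENVI raster + ``.hdr``; returns the data path."""
    path = Path(path)
    interleave = interleave.lower()
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    values = cube.values.astype(dtype)
    if interleave == "bip":
        flat = values
    elif interleave == "bil":
        flat = values.transpose(0, 2, 1)
    elif interleave == "bsq":
        flat = values.transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    flat.tofile(path)

    wl = ", ".join(f"{w:.4f}" for w in cube.band_centers)
    hdr_text = (
        "ENVI\n"
        f"samples = {cube.n_cols}\n"
        f"lines = {cube.n_rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"state = {cube.state}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr_text)
    return path


def to_reflectance(
    cube: SpectralCube,
    panel_region: tuple[int, int, int, int],
    panel_reflectance: float = 0.997,
    gain: float | np.ndarray | None = None,
    offset: float | np.ndarray | None = None,
) -> SpectralCube:
    """Convert radiance (or DN) to reflectance via a white-reference panel.

    Per band, ``reflectance = radiance / mean(panel radiance) * panel_reflectance``
    where the panel mean is taken over ``panel_region`` (half-open rectangle
    ``(r0, c0, r1, c1)``). A Spectralon panel reflects ~99.7% of incident
    light, hence the default ``panel_reflectance``.

    A DN cube must be accompanied by per-band linear ``gain``/``offset``
    (``radiance = dn * gain + offset``).
    """
    if cube.state == "reflectance":
        raise ValueError("cube is already in reflectance state")
    values = cube.values
    if cube.state == "dn":
        if gain is None or offset is None:
            raise ValueError("DN cube requires gain and offset for conversion")
        values = values * np.asarray(gain, dtype=float) + np.asarray(offset, dtype=float)
    r0, c0, r1, c1 = panel_region
    if r1 <= r0 or c1 <= c0:
        raise ValueError("panel_region must be a nonempty half-open rectangle")
    panel = values[r0:r1, c0:c1, :].reshape(-1, cube.n_bands)
    panel_mean = panel.mean(axis=0)
    if np.any(panel_mean == 0):
        bad = np.nonzero(panel_mean == 0)[0]
        raise ValueError(f"zero mean panel radiance in band(s) {bad.tolist()}")
    reflectance = values / panel_mean * panel_reflectance
    return SpectralCube(reflectance, cube.band_centers.copy(), "reflectance")


def remove_noisy_bands(
    cube: SpectralCube,
    edge_trim: int = DEFAULT_EDGE_TRIM,
    windows: Sequence[tuple[float, float]] = DEFAULT_REMOVAL_WINDOWS,
) -> tuple[SpectralCube, BandFilter]:
    """Drop noisy bands: first/last ``edge_trim`` bands, then every band whose
    center lies inside any closed ``(low_nm, high_nm)`` window.

    The defaults remove five bands at each spectral end plus the oxygen
    (753-766 nm) and water-vapor (813-827 nm) absorption windows.
    """
    if edge_trim < 0:
        raise ValueError("edge_trim must be >= 0")
    n = cube.n_bands
    keep = np.ones(n, dtype=bool)
    if edge_trim:
        keep[:edge_trim] = False
        keep[n - edge_trim:] = False
    for low, high in windows:
        if low > high:
            raise ValueError(f"invalid window ({low}, {high})")
        keep &= ~((cube.band_centers >= low) & (cube.band_centers <= high))
    if not keep.any():
        raise ValueError("band removal would discard every band")
    kept = np.nonzero(keep)[0]
    filtered = SpectralCube(
        cube.values[:, :, kept], cube.band_centers[kept], cube.state
    )
    return filtered, BandFilter(kept, cube.band_centers[kept],
                                tuple(tuple(w) for w in windows), edge_trim)
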