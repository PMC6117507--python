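"""Synthetic hyperspectral scenes with known ground truth.

Every downstream stage (masking, endmember extraction, similarity,
ranking) is testable against scenes rendered here, where the true
endmember spectra, per-pixel abundances, and class labels are known.

A scene holds two vegetation plots on a dark background: a control plot
in the top half of the image and a salt-treated plot in the bottom half.
Each vegetation pixel is a convex mixture of a healthy (control) and a
stressed (salt) endmember spectrum,

    pixel = illum * [(1 - a) * w_control + a * w_salt] + noise,

where the salt abundance ``a`` follows a Beta distribution whose mean is
``base_abundance`` for control pixels and ``base_abundance + shift`` for
salt pixels. ``shift`` is the single knob that moves the salt class
toward the salt endmember; downstream ranking statistics must increase
with it. The multiplicative ``illum`` factor (log-normal, unit median)
is a surrogate for leaf-angle/illumination geometry; additive Gaussian
noise models the sensor. One pure control pixel (a=0) and one pure salt
pixel (a=1) are planted at the plot centers with unit illumination so
that noise-free scenes contain the exact endmembers. A 1-pixel ring of
50/50 vegetation/background mixtures at each plot border exercises the
mixed-pixel filter.

Draw order (single generator seeded from ``SceneSpec.seed``):
abundances for control-labeled pixels in row-major order, then salt
abundances, then the full illumination field, then the full noise cube.
Identical specs therefore render bit-identical cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cube_io import SpectralCube, write_cube

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "make_vegetation_spectra",
    "default_band_centers",
    "render_scene",
    "write_truth",
]

LABEL_BACKGROUND = 0
LABEL_CONTROL = 1
LABEL_SALT = 2


def default_band_centers(n_bands: int = 50, low: float = 400.0,
                         high: float = 900.0) -> np.ndarray:
    """Evenly spaced band centers over the visible/NIR range (nm)."""
    return np.linspace(low, high, n_bands)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_vegetation_spectra(band_centers, seed: int = 0):
    """Build a healthy and a salt-stressed vegetation reflectance spectrum.

    Both spectra have the canonical green-leaf shape: low blue/red
    reflectance, a green bump near 550 nm, a sharp red edge near 700 nm,
    and a high NIR plateau. The stressed spectrum is a deterministic,
    seed-reproducible perturbation of the healthy one reproducing the
    classic symptoms of salt stress: chlorosis raises visible
    reflectance (pigment degradation absorbs less light), the NIR
    plateau drops (collapsing mesophyll structure), and the red edge
    shifts toward longer wavelengths. Because the visible rises while
    the NIR falls, the stress direction in feature space is far from
    collinear with an overall brightness change, as in real canopies.

    Returns
    -------
    (w_control, w_salt) : ndarray pair, values in [0, 1].
    """
    wl = np.asarray(band_centers, dtype=float)
    if wl.ndim != 1 or len(wl) < 10:
        raise ValueError("need at least 10 band centers")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("band_centers must be strictly increasing")

    rng = np.random.default_rng(seed)

    def leaf(base, green_amp, green_center, nir_amp, edge_center, edge_width,
             chlorosis=0.0):
        # chlorosis raises the red shoulder (600-690 nm) only
        vis_gain = chlorosis * _sigmoid((wl - 600.0) / 25.0) \
            * (1.0 - _sigmoid((wl - 690.0) / 15.0))
        return (
            base
            + vis_gain
            + green_amp * np.exp(-((wl - green_center) / 35.0) ** 2)
            + nir_amp * _sigmoid((wl - edge_center) / edge_width)
        )

    w_control = leaf(0.05, 0.12, 550.0, 0.42, 712.0, 16.0)

    # stress perturbation: parameters drawn once from the seeded generator
    nir_loss = rng.uniform(0.25, 0.35)       # fraction of NIR plateau lost
    edge_shift = rng.uniform(4.0, 10.0)      # red edge moves to longer nm
    green_loss = rng.uniform(0.10, 0.25)     # green bump weakens
    chlorosis = rng.uniform(0.010, 0.020)    # red-shoulder reflectance gain
    w_salt = leaf(
        0.05,
        0.12 * (1.0 - green_loss),
        552.0,
        0.42 * (1.0 - nir_loss),
        712.0 + edge_shift,
        17.0,
        chlorosis=chlorosis,
    )

    w_control = np.clip(w_control, 0.0, 1.0)
    w_salt = np.clip(w_salt, 0.0, 1.0)
    return w_control, w_salt


@dataclass
class SceneSpec:
    """Full parameterization of a synthetic scene; see module docstring.

    ``shift`` is the mean salt-abundance increase of the salt class over
    the control class (unitless, in [0, 1]). ``illum_sd`` is the standard
    deviation of log illumination (log-normal factor with unit median);
    ``noise_sd`` the additive sensor-noise standard deviation in
    reflectance units.
    """

    n_rows: int = 120
    n_cols: int = 120
    band_centers: np.ndarray = field(default_factory=default_band_centers)
    w_control: np.ndarray | None = None
    w_salt: np.ndarray | None = None
    shift: float = 0.2
    base_abundance: float = 0.35
    abundance_concentration: float = 16.0
    illum_sd: float = 0.03
    noise_sd: float = 0.005
    background_spectrum: np.ndarray | None = None
    edge_mix_width: int = 1
    plot_margin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if not np.all(np.diff(self.band_centers) > 0):
            raise ValueError("band_centers must be strictly increasing")
        if self.w_control is None or self.w_salt is None:
            self.w_control, self.w_salt = make_vegetation_spectra(
                self.band_centers, seed=self.seed
            )
        self.w_control = np.asarray(self.w_control, dtype=float)
        self.w_salt = np.asarray(self.w_salt, dtype=float)
        if self.background_spectrum is None:
            # dark, spectrally flat surface (tank/soil stand-in)
            self.background_spectrum = np.full(len(self.band_centers), 0.02)
        self.background_spectrum = np.asarray(self.background_spectrum, dtype=float)
        for name in ("w_control", "w_salt", "background_spectrum"):
            spec = getattr(self, name)
            if spec.shape != self.band_centers.shape:
                raise ValueError(f"{name} length must match band_centers")
            if np.any(spec < 0) or np.any(spec > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.shift <= 1.0):
            raise ValueError("shift must be in [0, 1]")
        if self.noise_sd < 0 or self.illum_sd < 0:
            raise ValueError("noise_sd and illum_sd must be >= 0")
        if self.base_abundance + self.shift >= 1.0 and self.shift > 0:
            raise ValueError("shift pushes mean salt abundance to 1 or above")
        if self.base_abundance + self.shift > 1.0:
            raise ValueError("shift pushes mean salt abundance above 1")

    # half-open rectangles (r0, c0, r1, c1)
    @property
    def control_region(self) -> tuple[int, int, int, int]:
        return (0, 0, self.n_rows // 2, self.n_cols)

    @property
    def salt_region(self) -> tuple[int, int, int, int]:
        return (self.n_rows // 2, 0, self.n_rows, self.n_cols)

    def _plot_rect(self, region):
        r0, c0, r1, c1 = region
        m = self.plot_margin
        if r1 - r0 <= 2 * m or c1 - c0 <= 2 * m:
            raise ValueError("scene too small for the configured plot margin")
        return (r0 + m, c0 + m, r1 - m, c1 - m)

    @property
    def control_plot(self) -> tuple[int, int, int, int]:
        return self._plot_rect(self.control_region)

    @property
    def salt_plot(self) -> tuple[int, int, int, int]:
        return self._plot_rect(self.salt_region)


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene.

    ``abundance_map`` holds the true salt-endmember fraction per pixel
    (NaN on background); ``label_map`` the class per pixel (0 background,
    1 control, 2 salt); ``edge_map`` marks planted mixed border pixels;
    ``endmember_locations`` the planted pure control/salt pixel coords.
    """

    abundance_map: np.ndarray
    label_map: np.ndarray
    edge_map: np.ndarray
    endmember_locations: dict
    control_region: tuple[int, int, int, int]
    salt_region: tuple[int, int, int, int]


def _beta_draw(rng, mean, concentration, size):
    """Beta draw with given mean and concentration; degenerate at 0/1."""
    if mean <= 0.0:
        return np.zeros(size)
    if mean >= 1.0:
        return np.ones(size)
    return rng.beta(mean * concentration, (1.0 - mean) * concentration, size)


def render_scene(spec: SceneSpec) -> tuple[SpectralCube, SceneTruth]:
    """Render ``spec`` into a reflectance cube plus its ground truth."""
    rows, cols, d = spec.n_rows, spec.n_cols, len(spec.band_centers)
    rng = np.random.default_rng(spec.seed)

    label = np.full((rows, cols), LABEL_BACKGROUND, dtype=np.int8)
    edge = np.zeros((rows, cols), dtype=bool)
    for rect, lab in ((spec.control_plot, LABEL_CONTROL),
                      (spec.salt_plot, LABEL_SALT)):
        r0, c0, r1, c1 = rect
        label[r0:r1, c0:c1] = lab
        w = spec.edge_mix_width
        if w > 0:
            inner = np.zeros((rows, cols), dtype=bool)
            inner[r0 + w:r1 - w, c0 + w:c1 - w] = True
            plot = np.zeros((rows, cols), dtype=bool)
            plot[r0:r1, c0:c1] = True
            edge |= plot & ~inner

    # --- documented draw order ---
    abundance = np.full((rows, cols), np.nan)
    ctrl_px = label == LABEL_CONTROL
    salt_px = label == LABEL_SALT
    abundance[ctrl_px] = _beta_draw(
        rng, spec.base_abundance, spec.abundance_concentration, int(ctrl_px.sum())
    )
    abundance[salt_px] = _beta_draw(
        rng, spec.base_abundance + spec.shift, spec.abundance_concentration,
        int(salt_px.sum()),
    )
    if spec.illum_sd > 0:
        illum = np.exp(rng.normal(0.0, spec.illum_sd, (rows, cols)))
    else:
        illum = np.ones((rows, cols))
    noise = (rng.normal(0.0, spec.noise_sd, (rows, cols, d))
             if spec.noise_sd > 0 else np.zeros((rows, cols, d)))

    # plant pure endmember pixels at plot centers (unit illumination)
    def center(rect):
        r0, c0, r1, c1 = rect
        return ((r0 + r1) // 2, (c0 + c1) // 2)

    loc_c = center(spec.control_plot)
    loc_s = center(spec.salt_plot)
    abundance[loc_c] = 0.0
    abundance[loc_s] = 1.0
    illum[loc_c] = 1.0
    illum[loc_s] = 1.0

    a = np.nan_to_num(abundance)[:, :, None]
    veg_signal = (1.0 - a) * spec.w_control + a * spec.w_salt
    signal = np.broadcast_to(spec.background_spectrum, (rows, cols, d)).copy()
    veg_mask = ctrl_px | salt_px
    signal[veg_mask] = veg_signal[veg_mask]
    signal[edge] = 0.5 * veg_signal[edge] + 0.5 * spec.background_spectrum
    values = np.where(veg_mask[:, :, None], illum[:, :, None] * signal, signal) + noise
    values = np.clip(values, 0.0, None)  # reflectance is non-negative

    cube = SpectralCube(values, spec.band_centers.copy(), "reflectance")
    truth = SceneTruth(
        abundance_map=abundance,
        label_map=label,
        edge_map=edge,
        endmember_locations={"control": loc_c, "salt": loc_s},
        control_region=spec.control_region,
        salt_region=spec.salt_region,
    )
    return cube, truth


def write_truth(truth: SceneTruth, directory: str | Path) -> None:
    """Write truth maps as plain-text sidecars next to a rendered cube."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "abundance_map.csv", truth.abundance_map,
               delimiter=",", fmt="%.6f")
    np.savetxt(directory / "label_map.csv", truth.label_map,
               delimiter=",", fmt="%d")
    np.savetxt(directory / "edge_map.csv", truth.edge_map.astype(int),
               delimiter=",", fmt="%d")
    with open(directory / "endmember_locations.csv", "w") as fh:
        fh.write("class,row,col\n")
        for name, (r, c) in truth.endmember_locations.items():
            fh.write(f"{name},{r},{c}\n")
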