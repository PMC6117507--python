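"""End-to-end orchestration: cube -> mask -> endmembers -> similarity -> ranking.

The pipeline analyses each plant line independently — its salt-treated
pixels are always compared with its own control pixels, so inherent
spectral differences between lines (leaf wax, color) do not masquerade
as stress response — and then ranks the lines by each of the three
statistics. A run is configured by a :class:`RunConfig` (YAML on disk),
either pointing at real ENVI cubes or requesting synthetic scenes with
known ground truth (fixture mode).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import cube_io, mask as mask_mod, ranking as rk
from .cube_io import SpectralCube
from .endmembers import EndmemberPair, extract_pair
from .mask import CONTROL, SALT, PixelMatrix
from .ranking import BayesTable, ClassHistogram, NRDCurve
from .similarity import SimilarityField, similarity_image, vsm
from .synthetic import SceneSpec, render_scene

__all__ = [
    "LineConfig",
    "RunConfig",
    "LineResult",
    "ExperimentResult",
    "analyze_pixel_matrix",
    "analyze_scene",
    "make_line_scene",
    "run_line",
    "run_experiment",
    "load_config",
]

log = logging.getLogger("saltrank")


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


Rect = tuple[int, int, int, int]


class LineConfig(BaseModel):
    """One plant line: a cube on disk or a synthetic scene request."""

    name: str
    cube: Optional[str] = None          # ENVI data path; None => synthetic
    state: str = "reflectance"
    control_region: Optional[Rect] = None
    salt_region: Optional[Rect] = None
    shift: float = 0.2                  # synthetic mode only

    @model_validator(mode="after")
    def _check(self):
        if self.cube is not None and (self.control_region is None
                                      or self.salt_region is None):
            raise ValueError(f"line {self.name}: cube runs need treatment regions")
        return self


class RunConfig(BaseModel):
    """Validated configuration for a full experiment run."""

    lines: list[LineConfig] = Field(min_length=1)
    out_dir: str = "saltrank_out"
    seed: int = 0
    # radiometric / band removal
    panel_region: Optional[Rect] = None
    panel_reflectance: float = 0.997
    edge_trim: int = 5
    removal_windows: list[tuple[float, float]] = Field(
        default_factory=lambda: [(753.0, 766.0), (813.0, 827.0)])
    apply_band_removal: bool = True
    # mask
    t_ndvi: float = 0.5
    t_egi: float = 0.05
    blue_nm: float = 470.0
    green_nm: float = 550.0
    red_nm: float = 670.0
    nir_nm: float = 800.0
    # statistics
    bins: int = 100
    split: float = 0.5
    posterior_bins: int = 10
    endmember_method: str = "auto"
    plots: bool = False


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-check a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


@dataclass
class LineResult:
    """All statistics for a single line."""

    name: str
    pair: EndmemberPair
    field: SimilarityField
    nrd: NRDCurve
    auc: float
    hist_control: ClassHistogram
    hist_salt: ClassHistogram
    mdpa: float
    bayes: BayesTable
    posterior_bins: np.ndarray
    counts: dict

    def summary(self) -> dict:
        row = self.bayes.as_percent()
        return {
            "line": self.name,
            "auc_J": self.auc,
            "mdpa": self.mdpa,
            **{f"bayes_{k}_pct": v for k, v in row.items()},
            **self.counts,
        }


@dataclass
class ExperimentResult:
    """Per-line results plus the three rankings and their concordance."""

    lines: dict
    rankings: dict
    concordant: bool

    def concordance_note(self) -> str:
        orders = {s: tuple(r.order) for s, r in self.rankings.items()}
        if self.concordant:
            return ("All three statistics rank the lines identically: "
                    + " > ".join(orders["posterior"])
                    + " (most tolerant first).")
        return "Rankings disagree: " + "; ".join(
            f"{s}: {' > '.join(o)}" for s, o in orders.items())


def _balanced_field(hc: ClassHistogram, hs: ClassHistogram) -> SimilarityField:
    """Assemble a balanced similarity field from two equal-size histograms."""
    s = np.concatenate([hc.values, hs.values])
    labels = np.concatenate([
        np.full(hc.n, CONTROL, dtype=np.int8),
        np.full(hs.n, SALT, dtype=np.int8),
    ])
    coords = np.column_stack([np.zeros(len(s), dtype=int), np.arange(len(s))])
    return SimilarityField(s, labels, coords)


def analyze_pixel_matrix(pm: PixelMatrix, *, bins: int = 100, split: float = 0.5,
                         posterior_bins: int = 10, endmember_method: str = "auto",
                         seed: int = 0, name: str = "line") -> LineResult:
    """Compute endmembers, similarity, and all three ranking statistics.

    NRD/AUC uses every masked pixel; MDPA and the Bayesian posterior use
    classes balanced by stratified subsampling of the larger class
    (seeded), as equal class sizes are required by both the pair
    assignment distance and the equal-prior simplification.
    """
    if pm.n_control == 0 or pm.n_salt == 0:
        raise StageError("ranking", "both treatment classes must be nonempty")
    pair = extract_pair(pm, method=endmember_method)
    field = vsm(pm, pair)

    curve = rk.nrd_curve(pm.class_matrix(CONTROL), pm.class_matrix(SALT),
                         pm.band_centers)
    auc = rk.auc_energy(curve)

    hc, hs = rk.class_histograms(field, b=bins)
    rng = np.random.default_rng(seed)
    hc_bal, hs_bal = rk.balance_classes(hc, hs, rng)
    dist = rk.mdpa(hc_bal, hs_bal)

    balanced = _balanced_field(hc_bal, hs_bal)
    bayes = rk.bayes_table(balanced, split=split)
    post_bins = rk.binned_posterior(balanced, nbins=posterior_bins)

    counts = {
        "n_control": pm.n_control,
        "n_salt": pm.n_salt,
        "n_balanced_per_class": hc_bal.n,
    }
    return LineResult(name, pair, field, curve, auc, hc_bal, hs_bal, dist,
                      bayes, post_bins, counts)


def make_line_scene(shift: float, seed: int, **spec_kwargs):
    """Render one synthetic line scene; returns (cube, truth, spec)."""
    spec = SceneSpec(shift=shift, seed=seed, **spec_kwargs)
    cube, truth = render_scene(spec)
    return cube, truth, spec


def analyze_scene(cube: SpectralCube, control_region: Rect, salt_region: Rect,
                  cfg: RunConfig | None = None, *, seed: int | None = None,
                  name: str = "line") -> LineResult:
    """Mask a reflectance cube, label treatments, and compute statistics."""
    cfg = cfg or RunConfig(lines=[LineConfig(name=name)])
    try:
        vmask = mask_mod.build_mask(cube, cfg.t_ndvi, cfg.t_egi,
                                    cfg.blue_nm, cfg.green_nm,
                                    cfg.red_nm, cfg.nir_nm)
    except ValueError as exc:
        raise StageError("vegetation_mask", str(exc)) from exc
    labels, dropped = mask_mod.assign_treatment(vmask.final, control_region,
                                                salt_region)
    pm = mask_mod.flatten(cube, labels)
    # stage accounting: every primary pixel is eroded, dropped, or kept
    assert pm.n == vmask.counts["primary"] - vmask.counts["eroded"] - dropped
    log.info("%s: primary=%d eroded=%d dropped=%d kept=%d", name,
             vmask.counts["primary"], vmask.counts["eroded"], dropped, pm.n)
    result = analyze_pixel_matrix(
        pm, bins=cfg.bins, split=cfg.split, posterior_bins=cfg.posterior_bins,
        endmember_method=cfg.endmember_method,
        seed=cfg.seed if seed is None else seed, name=name)
    result.counts.update({"n_primary": vmask.counts["primary"],
                          "n_eroded": vmask.counts["eroded"],
                          "n_dropped_unlabeled": dropped})
    return result


def _load_line_cube(cfg: RunConfig, line: LineConfig):
    """cube_io stage: read, convert to reflectance, drop noisy bands."""
    try:
        cube = cube_io.read_cube(line.cube, state=line.state)
        if cube.state != "reflectance":
            if cfg.panel_region is None:
                raise ValueError("panel_region required for non-reflectance cubes")
            cube = cube_io.to_reflectance(cube, cfg.panel_region,
                                          cfg.panel_reflectance)
        if cfg.apply_band_removal:
            cube, _ = cube_io.remove_noisy_bands(cube, cfg.edge_trim,
                                                 cfg.removal_windows)
    except (ValueError, FileNotFoundError) as exc:
        raise StageError("cube_io", f"line {line.name}: {exc}") from exc
    return cube


def _write_line_artifacts(result: LineResult, shape, out_dir: Path,
                          plots: bool) -> None:
    import tifffile
    from PIL import Image

    out_dir.mkdir(parents=True, exist_ok=True)
    grid = similarity_image(result.field, shape)
    tifffile.imwrite(out_dir / "similarity.tiff", grid.astype(np.float32))
    Image.fromarray(np.round(grid * 255).astype(np.uint8)).save(
        out_dir / "similarity.png")
    with open(out_dir / "similarity.csv", "w") as fh:
        fh.write("row,col,label,s\n")
        lab_name = {CONTROL: "control", SALT: "salt"}
        for (r, c), lab, s in zip(result.field.coords, result.field.labels,
                                  result.field.s):
            fh.write(f"{r},{c},{lab_name.get(int(lab), 'unknown')},{s:.6f}\n")
    with open(out_dir / "nrd.csv", "w") as fh:
        fh.write("wavelength_nm,nrd\n")
        for wl, v in zip(result.nrd.band_centers, result.nrd.nrd):
            fh.write(f"{wl:.4f},{v:.8f}\n")
    with open(out_dir / "endmembers.csv", "w") as fh:
        fh.write("wavelength_nm,control,salt\n")
        # band grid matches the analyzed pixel matrix
        for wl, a, b in zip(result.nrd.band_centers, result.pair.w1,
                            result.pair.w2):
            fh.write(f"{wl:.4f},{a:.8f},{b:.8f}\n")
    report = {
        **result.summary(),
        "posterior_bins": [None if np.isnan(p) else round(float(p), 6)
                           for p in result.posterior_bins],
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    if plots:
        from . import plots as plots_mod
        plots_mod.plot_line_result(result, out_dir)


def run_line(cfg: RunConfig, line_name: str,
             write_artifacts: bool = True) -> LineResult:
    """Run the full pipeline for one configured line."""
    line = next((ln for ln in cfg.lines if ln.name == line_name), None)
    if line is None:
        raise KeyError(f"no line named {line_name!r} in config")
    if line.cube is None:
        cube, truth, _ = make_line_scene(line.shift, cfg.seed)
        control_region = line.control_region or truth.control_region
        salt_region = line.salt_region or truth.salt_region
    else:
        cube = _load_line_cube(cfg, line)
        control_region, salt_region = line.control_region, line.salt_region
    result = analyze_scene(cube, control_region, salt_region, cfg,
                           name=line.name)
    if write_artifacts:
        _write_line_artifacts(result, cube.values.shape[:2],
                              Path(cfg.out_dir) / line.name, cfg.plots)
    return result


def run_experiment(cfg: RunConfig,
                   write_artifacts: bool = True) -> ExperimentResult:
    """Run every line and rank them by AUC, MDPA, and posterior."""
    if len(cfg.lines) < 2:
        raise ValueError("an experiment needs at least two lines to rank")
    results = {ln.name: run_line(cfg, ln.name, write_artifacts)
               for ln in cfg.lines}
    rankings = {
        "auc": rk.rank_lines({n: r.auc for n, r in results.items()}, "auc"),
        "mdpa": rk.rank_lines({n: r.mdpa for n, r in results.items()}, "mdpa"),
        "posterior": rk.rank_lines(
            {n: r.bayes.posterior for n, r in results.items()}, "posterior"),
    }
    orders = {tuple(r.order) for r in rankings.values()}
    experiment = ExperimentResult(results, rankings, len(orders) == 1)
    if write_artifacts:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary = {
            "lines": {n: r.summary() for n, r in results.items()},
            "rankings": {s: r.order for s, r in rankings.items()},
            "concordance": experiment.concordance_note(),
        }
        (out / "experiment.json").write_text(json.dumps(summary, indent=2))
        _write_bayes_table(results, out / "bayes_table.csv")
    return experiment


def _write_bayes_table(results: dict, path: Path) -> None:
    """Bayes-rule components per line, as percentages (report layout)."""
    with open(path, "w") as fh:
        fh.write("line,prior_pct,class_conditional_pct,evidence_pct,posterior_pct\n")
        for name, r in results.items():
            row = r.bayes.as_percent()
            fh.write(f"{name},{row['prior']:.2f},{row['class_conditional']:.2f},"
                     f"{row['evidence']:.2f},{row['posterior']:.2f}\n")
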