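"""Ranking statistics: NRD curve with energy-domain AUC, MDPA histogram
distance on balanced classes, and Bayesian posteriors at a similarity split.

Three complementary statistics quantify how far a line's salt-treated
pixels have moved away from its control pixels; for all three, smaller
means more salt-tolerant.

* **NRD / AUC** — the normalized reflectance difference per band,
  ``NRD_i = (mean control_i - mean salt_i) / mean control_i``, summarized
  by the area under the curve after converting the wavelength axis to
  photon energy ``E = h c / lambda`` (so the area carries units of
  joules).
* **MDPA** — the minimum difference of pair assignments between the
  control and salt similarity histograms: the minimal number of one-bin
  moves that turns one histogram into the other (the 1-D earth-mover
  distance for ordinal histograms), computed as the sum of absolute
  prefix-sum differences and normalized per pixel. Requires equal class
  sizes, enforced by stratified subsampling of the larger class.
* **Bayesian posterior** — ``P(salt | s > 0.5)`` under equal priors,
  from the class-conditional exceedance fractions at the split point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mask import CONTROL, SALT
from .similarity import SimilarityField

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "NRDCurve",
    "ClassHistogram",
    "BayesTable",
    "RankResult",
    "nrd_curve",
    "auc_energy",
    "wavelength_to_energy",
    "class_histograms",
    "stratified_subsample",
    "balance_classes",
    "mdpa",
    "bayes_table",
    "binned_posterior",
    "rank_lines",
]

PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m / s


def wavelength_to_energy(wavelength_nm) -> np.ndarray:
    """Photon energy (J) at a wavelength given in nm: E = h c / lambda."""
    return PLANCK_H * SPEED_OF_LIGHT / (np.asarray(wavelength_nm, dtype=float) * 1e-9)


# ---------------------------------------------------------------------------
# NRD curve and energy-domain AUC

@dataclass
class NRDCurve:
    """Per-band normalized reflectance difference between class means.

    Bands where the control mean is zero have an undefined ratio; they
    are stored as NaN, flagged in ``defined``, and excluded from the AUC.
    """

    nrd: np.ndarray
    band_centers: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.nrd) == len(self.band_centers) == len(self.defined)):
            raise ValueError("nrd, band_centers and defined must align")


def nrd_curve(C: np.ndarray, S: np.ndarray, band_centers) -> NRDCurve:
    """NRD_i = (mean(C_i) - mean(S_i)) / mean(C_i) per band.

    ``C`` and ``S`` are d x n_c and d x n_s matrices of control and salt
    pixel spectra (rows are bands).
    """
    C = np.asarray(C, dtype=float)
    S = np.asarray(S, dtype=float)
    if C.size == 0 or S.size == 0:
        raise ValueError("both classes must be nonempty")
    if C.shape[0] != S.shape[0]:
        raise ValueError("class matrices must share the band axis")
    band_centers = np.asarray(band_centers, dtype=float)
    if len(band_centers) != C.shape[0]:
        raise ValueError("band_centers must match the band axis")
    mc = C.mean(axis=1)
    ms = S.mean(axis=1)
    defined = mc != 0
    nrd = np.full(C.shape[0], np.nan)
    nrd[defined] = (mc[defined] - ms[defined]) / mc[defined]
    return NRDCurve(nrd, band_centers, defined)


def auc_energy(curve: NRDCurve) -> float:
    """Area under the NRD curve on the photon-energy axis (joules).

    Bands are taken in wavelength order; the area is the sum of
    trapezoids between successive defined bands, with the energy
    increment taken in absolute value (energy decreases with
    wavelength). The integrand keeps its sign, so negative NRD regions
    subtract from the area.
    """
    nrd = curve.nrd[curve.defined]
    wl = curve.band_centers[curve.defined]
    if len(nrd) < 2:
        raise ValueError("need at least two defined bands for an area")
    x = wavelength_to_energy(wl)
    return float(np.sum(0.5 * (nrd[:-1] + nrd[1:]) * np.abs(np.diff(x))))


# ---------------------------------------------------------------------------
# Class histograms, stratified subsampling, MDPA

@dataclass
class ClassHistogram:
    """Occupancy of b equal bins tiling [0, 1] for one class's similarities.

    Bins are half-open ``[k/b, (k+1)/b)`` with the last bin closed at 1,
    the only tiling that keeps the salt endmember itself (s = 1)
    in-range. ``values`` retains the raw similarity values (the bin
    members), so the histogram can be subsampled; mean and sd are
    computed from the raw values, not bin centers.
    """

    counts: np.ndarray
    b: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.counts) != self.b:
            raise ValueError("counts length must equal bin count")
        if int(self.counts.sum()) != len(self.values):
            raise ValueError("counts must sum to the number of values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def bin_width(self) -> float:
        return 1.0 / self.b

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0


def _bin_index(values: np.ndarray, b: int) -> np.ndarray:
    return np.minimum((values * b).astype(int), b - 1)


def _histogram(values: np.ndarray, b: int) -> ClassHistogram:
    counts = np.bincount(_bin_index(values, b), minlength=b)
    return ClassHistogram(counts, b, values)


def class_histograms(field: SimilarityField, b: int = 100):
    """Histogram the similarity values of each treatment class.

    Returns ``(control_histogram, salt_histogram)`` over ``b`` bins.
    """
    if b < 2:
        raise ValueError("need at least 2 bins")
    hc_vals = field.class_values(CONTROL)
    hs_vals = field.class_values(SALT)
    if len(hc_vals) == 0 or len(hs_vals) == 0:
        raise ValueError("both classes must be nonempty")
    return _histogram(hc_vals, b), _histogram(hs_vals, b)


def stratified_subsample(hist: ClassHistogram, target_n: int,
                         seed: int | np.random.Generator = 0) -> ClassHistogram:
    """Subsample a histogram to ``target_n`` members, bin by bin.

    Each bin contributes in proportion to its occupancy (quota
    ``count * target_n / n``); fractional quotas are resolved by a
    deterministic largest-remainder rule so the total is exactly
    ``target_n``, and members within a bin are chosen uniformly at
    random under ``seed``. The subsampled histogram therefore preserves
    the shape of the original distribution.
    """
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    if target_n > hist.n:
        raise ValueError("target_n exceeds histogram size")
    if target_n == hist.n:
        return ClassHistogram(hist.counts.copy(), hist.b, hist.values.copy())
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    quota = hist.counts * (target_n / hist.n)
    take = np.floor(quota).astype(int)
    remainder = quota - take
    short = target_n - int(take.sum())
    if short > 0:
        # largest remainders first; ties broken by lower bin index
        order = np.lexsort((np.arange(hist.b), -remainder))
        take[order[:short]] += 1
    bins = _bin_index(hist.values, hist.b)
    chosen = []
    for k in np.nonzero(take)[0]:
        members = np.nonzero(bins == k)[0]
        pick = rng.choice(members, size=take[k], replace=False)
        chosen.append(np.sort(pick))
    idx = np.concatenate(chosen) if chosen else np.array([], dtype=int)
    return _histogram(hist.values[idx], hist.b)


def balance_classes(hc: ClassHistogram, hs: ClassHistogram,
                    seed: int | np.random.Generator = 0):
    """Subsample the larger class so both histograms have equal totals."""
    target = min(hc.n, hs.n)
    return (stratified_subsample(hc, target, seed),
            stratified_subsample(hs, target, seed))


def mdpa(hc: ClassHistogram, hs: ClassHistogram,
         normalized: bool = True) -> float:
    """Minimum difference of pair assignments between two histograms.

    D = sum_i | sum_{j<=i} (Hc_j - Hs_j) | — the minimal number of
    one-bin sample moves equalizing the histograms, valid only for equal
    totals (subsample first; see :func:`balance_classes`). With
    ``normalized`` the raw distance is divided by the per-class pixel
    count, giving bin-index units per pixel, comparable across lines.
    """
    if hc.b != hs.b:
        raise ValueError("histograms must share a bin count")
    if hc.n != hs.n:
        raise ValueError("histograms must have equal totals; subsample first")
    raw = float(np.abs(np.cumsum(hc.counts.astype(np.int64)
                                 - hs.counts.astype(np.int64))).sum())
    return raw / hc.n if normalized else raw


# ---------------------------------------------------------------------------
# Bayesian posterior

@dataclass
class BayesTable:
    """Components of Bayes' rule at the similarity split point.

    All fields are fractions: ``prior`` P(salt); ``cc_salt``
    P(s>split | salt); ``cc_control`` P(s>split | control); ``evidence``
    P(s>split); ``posterior`` P(salt | s>split). ``posterior`` is NaN
    (flagged undefined) when no pixel exceeds the split.
    """

    prior: float
    cc_salt: float
    cc_control: float
    evidence: float
    posterior: float
    split: float = 0.5

    @classmethod
    def from_conditionals(cls, cc_salt: float, cc_control: float,
                          prior: float = 0.5, split: float = 0.5) -> "BayesTable":
        evidence = prior * cc_salt + (1.0 - prior) * cc_control
        if cc_salt + cc_control == 0.0:
            posterior = math.nan
        else:
            posterior = prior * cc_salt / evidence
        return cls(prior, cc_salt, cc_control, evidence, posterior, split)

    @classmethod
    def from_evidence(cls, cc_salt: float, evidence: float,
                      prior: float = 0.5, split: float = 0.5) -> "BayesTable":
        """Build from the class-conditional and the evidence.

        Under equal priors the control conditional is recoverable as
        ``2 * evidence - cc_salt``; useful when only the salt
        conditional and the evidence are reported.
        """
        if prior != 0.5:
            raise ValueError("evidence-based construction assumes equal priors")
        return cls.from_conditionals(cc_salt, 2.0 * evidence - cc_salt,
                                     prior, split)

    def as_percent(self) -> dict:
        """Report-layer view: fields as percentages, two decimals."""
        return {
            "prior": round(self.prior * 100, 2),
            "class_conditional": round(self.cc_salt * 100, 2),
            "evidence": round(self.evidence * 100, 2),
            "posterior": round(self.posterior * 100, 2),
        }


def bayes_table(field: SimilarityField, split: float = 0.5) -> BayesTable:
    """Posterior P(salt | s > split) from balanced classes, equal priors.

    The classes must have equal sizes (balance first) so the prior is
    exactly 0.5 and cancels; the split rule is the strict inequality
    ``s > split``.
    """
    if not (0.0 < split < 1.0):
        raise ValueError("split must be in (0, 1)")
    s_salt = field.class_values(SALT)
    s_ctrl = field.class_values(CONTROL)
    if len(s_salt) == 0 or len(s_ctrl) == 0:
        raise ValueError("both classes must be nonempty")
    if len(s_salt) != len(s_ctrl):
        raise ValueError("classes must be balanced (equal sizes) for equal priors")
    cc_salt = float(np.mean(s_salt > split))
    cc_control = float(np.mean(s_ctrl > split))
    return BayesTable.from_conditionals(cc_salt, cc_control, prior=0.5, split=split)


def binned_posterior(field: SimilarityField, nbins: int = 10) -> np.ndarray:
    """P(salt | s in bin_j) over nbins similarity bins (balanced classes).

    Empty bins are NaN (undefined); the control curve is the complement
    1 - posterior in every nonempty bin.
    """
    if nbins < 2:
        raise ValueError("need at least 2 bins")
    bins = _bin_index(field.s, nbins)
    salt = field.labels == SALT
    out = np.full(nbins, np.nan)
    for j in range(nbins):
        members = bins == j
        total = int(members.sum())
        if total:
            out[j] = float(np.sum(members & salt)) / total
    return out


# ---------------------------------------------------------------------------
# Line-level ranking

@dataclass
class RankResult:
    """Ordering of lines by one statistic, most tolerant first."""

    statistic: str
    order: list
    values: dict
    ties: list = field(default_factory=list)


def rank_lines(values: dict, statistic: str = "posterior") -> RankResult:
    """Rank lines ascending by a statistic (smaller = more tolerant).

    ``values`` maps line name to its statistic (AUC in J, normalized
    MDPA, or posterior fraction). Ties are broken by line-name order and
    reported in ``ties``.
    """
    if statistic not in ("auc", "mdpa", "posterior"):
        raise ValueError("statistic must be one of auc, mdpa, posterior")
    if len(values) < 2:
        raise ValueError("ranking needs at least two lines")
    order = sorted(values, key=lambda name: (values[name], name))
    ties = []
    names = list(values)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if values[a] == values[b]:
                ties.append((a, b))
    return RankResult(statistic, order, dict(values), ties)
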