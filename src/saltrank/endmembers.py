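"""Two-endmember extraction: the farthest-apart pixel pair in feature space.

Following the simplex-volume view of endmember search, the two purest
pixels of a two-class scene are the vertices of the maximum-length
1-simplex — the pair of pixels at maximum Euclidean distance in the
d-dimensional spectral feature space. Two search strategies are
provided: an exact O(n^2) scan and a farthest-point alternation
heuristic (start from the pixel farthest from the centroid, then
alternately move each end to the pixel farthest from the other until a
fixed point). The heuristic is the default above ``EXACT_LIMIT`` pixels.

Orientation: ``w1`` is the control endmember, chosen by treatment label
when the two extreme pixels carry different labels, else by proximity to
the control-class centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask import CONTROL, PixelMatrix

__all__ = ["EndmemberPair", "extract_pair", "project_pca3", "EXACT_LIMIT"]

#: Largest n for which the exact O(n^2) search is used by default.
EXACT_LIMIT = 5000


@dataclass
class EndmemberPair:
    """The control (w1) and salt (w2) endmember spectra.

    ``idx1``/``idx2`` are the source column indices in the pixel matrix;
    ``separation`` is the Euclidean distance between the endmembers.
    """

    w1: np.ndarray
    w2: np.ndarray
    idx1: int
    idx2: int
    separation: float

    def __post_init__(self) -> None:
        if self.idx1 == self.idx2:
            raise ValueError("endmembers must be distinct columns")
        if self.separation <= 0:
            raise ValueError("endmember separation must be positive")

    @property
    def axis(self) -> np.ndarray:
        """The line direction w2 - w1 along which similarity is measured."""
        return self.w2 - self.w1


def _sq_dists_to(X: np.ndarray, j: int, sq_norms: np.ndarray) -> np.ndarray:
    return sq_norms + sq_norms[j] - 2.0 * (X.T @ X[:, j])


def _exact_pair(X: np.ndarray) -> tuple[int, int]:
    """Full O(n^2) max-distance pair; ties broken lexicographically."""
    n = X.shape[1]
    sq = np.einsum("ij,ij->j", X, X)
    gram = X.T @ X
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    iu = np.triu_indices(n, k=1)
    vals = d2[iu]
    # argmax returns the first maximum; triu_indices order is lexicographic
    best = int(np.argmax(np.round(vals, 12)))
    return int(iu[0][best]), int(iu[1][best])


def _farthest_point_pair(X: np.ndarray) -> tuple[int, int]:
    """Certified farthest-pair search without the O(n^2) distance matrix.

    An alternating farthest-point pass (start at the pixel farthest from
    the centroid, alternately move each end to the pixel farthest from
    the other until a fixed point) gives a lower bound on the diameter;
    a subsequent sweep over pixels in decreasing centroid radius, pruned
    by the triangle-inequality bound d(i, j) <= r_i + r_j on centroid
    radii, certifies or improves it. The result always equals the exact
    maximum-distance pair, but only pivot rows of the distance matrix
    are ever formed, so memory stays O(n) and the sweep terminates early
    whenever the data have genuinely extreme pixels.
    """
    sq = np.einsum("ij,ij->j", X, X)
    centroid = X.mean(axis=1, keepdims=True)
    radius = np.sqrt(np.einsum("ij,ij->j", X - centroid, X - centroid))

    # alternation pass -> initial lower bound
    a = int(np.argmax(radius))
    b = int(np.argmax(_sq_dists_to(X, a, sq)))
    seen = set()
    while (min(a, b), max(a, b)) not in seen:
        seen.add((min(a, b), max(a, b)))
        a = int(np.argmax(_sq_dists_to(X, b, sq)))
        b = int(np.argmax(_sq_dists_to(X, a, sq)))
    best_sq = float(_sq_dists_to(X, a, sq)[b])
    best = (min(a, b), max(a, b))

    # certification sweep with norm-bound pruning
    order = np.argsort(-radius, kind="stable")
    for pos, i in enumerate(order):
        if 2.0 * radius[i] <= np.sqrt(best_sq):
            break  # no remaining pair can beat the incumbent
        d2 = _sq_dists_to(X, int(i), sq)
        # only partners that could beat the bound matter
        d2[radius < np.sqrt(best_sq) - radius[i]] = -np.inf
        j = int(np.argmax(d2))
        if d2[j] > best_sq * (1.0 + 1e-15):
            best_sq = float(d2[j])
            best = (min(int(i), j), max(int(i), j))
    return best


def extract_pair(pixels: PixelMatrix | np.ndarray, labels=None,
                 method: str = "auto") -> EndmemberPair:
    """Extract the two most separated pixels as control/salt endmembers.

    Parameters
    ----------
    pixels : PixelMatrix or (d, n) ndarray
    labels : optional per-column treatment labels (taken from the
        PixelMatrix when omitted); used only to orient the pair.
    method : {"auto", "exact", "farthest_point"}
        ``exact`` scans all pairs; ``farthest_point`` iterates the
        alternation heuristic; ``auto`` picks exact for n <= EXACT_LIMIT.
    """
    if isinstance(pixels, PixelMatrix):
        X = pixels.X
        if labels is None:
            labels = pixels.labels
    else:
        X = np.asarray(pixels, dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least two pixels")
    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "farthest_point"
    if method == "exact":
        i, j = _exact_pair(X)
    elif method == "farthest_point":
        i, j = _farthest_point_pair(X)
    else:
        raise ValueError(f"unknown method {method!r}")

    separation = float(np.linalg.norm(X[:, i] - X[:, j]))
    if separation == 0.0:
        raise ValueError("all pixels identical: endmember separation is zero")

    # orient: w1 = control endmember. The orientation uses every labeled
    # pixel, not just the two extremes: project the class centroids onto
    # the endmember axis and pick as w1 the end the control centroid lies
    # toward. With overlapping treatment classes the label of a single
    # extreme pixel is unreliable; the centroid rule agrees with the
    # extremes' own labels whenever the classes are well separated.
    idx1, idx2 = i, j
    if labels is not None:
        labels = np.asarray(labels)
        ctrl = X[:, labels == CONTROL]
        salt = X[:, labels != CONTROL]
        if ctrl.shape[1] and salt.shape[1]:
            axis = X[:, j] - X[:, i]
            if (ctrl.mean(axis=1) - salt.mean(axis=1)) @ axis > 0:
                idx1, idx2 = j, i
        elif ctrl.shape[1]:
            cen = ctrl.mean(axis=1)
            if np.linalg.norm(X[:, j] - cen) < np.linalg.norm(X[:, i] - cen):
                idx1, idx2 = j, i
    return EndmemberPair(
        w1=X[:, idx1].copy(), w2=X[:, idx2].copy(),
        idx1=idx1, idx2=idx2, separation=separation,
    )


def project_pca3(pixels: PixelMatrix | np.ndarray) -> np.ndarray:
    """Mean-centered projection onto the top three principal axes.

    Returns a (3, n) array of scores for visualization; with rank-2 data
    the third row is identically zero.
    """
    X = pixels.X if isinstance(pixels, PixelMatrix) else np.asarray(pixels, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least three pixels for a 3-D projection")
    centered = X - X.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(3, len(s))
    scores = np.zeros((3, X.shape[1]))
    scores[:k] = (s[:k, None] * vt[:k])
    return scores
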