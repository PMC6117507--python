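"""Vector-wise similarity measurement (VSM) and its quadratic-programming oracle.

VSM reduces each d-dimensional pixel spectrum to a single number: the
pixel is projected onto the line through the control endmember ``w1``
and the salt endmember ``w2``, and its normalized position along that
line is its similarity to the salt endmember,

    t = <r - w1, w2 - w1> / ||w2 - w1||^2,     s = clip(t, 0, 1).

Similarity to the control endmember is 1 - s, so the two similarities
sum to one. The clip enforces the convex-combination box constraints for
pixels projecting outside the segment, which makes ``s`` identical to
the salt coefficient of the fully constrained two-endmember unmixing QP

    min_h ||x - W h||^2   s.t.  h1 + h2 = 1,  0 <= h <= 1,

solved here per pixel by an iterative SQP solver purely as a
correctness oracle (``qp_unmix``). VSM itself is a single matrix
product over all pixels — no per-pixel solver loop — which is what
makes it usable at phenotyping scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .endmembers import EndmemberPair
from .mask import PixelMatrix

__all__ = ["SimilarityField", "vsm", "qp_unmix", "similarity_image"]


@dataclass
class SimilarityField:
    """Per-pixel similarity to the salt endmember, in [0, 1].

    Carries the treatment labels and source coordinates of the pixel
    matrix it was computed from, so it can be mapped back to an image.
    """

    s: np.ndarray
    labels: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s < 0) or np.any(self.s > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        if len(self.labels) != len(self.s) or len(self.coords) != len(self.s):
            raise ValueError("labels/coords must match similarity length")

    @property
    def n(self) -> int:
        return len(self.s)

    def class_values(self, label: int) -> np.ndarray:
        return self.s[self.labels == label]


def vsm(pixels: PixelMatrix | np.ndarray, pair: EndmemberPair) -> SimilarityField:
    """Similarity of every pixel to the salt endmember via projection.

    Accepts a PixelMatrix (labels/coords are carried through) or a raw
    (d, n) array (labels/coords filled with placeholders).
    """
    if pair.separation <= 0:
        raise ValueError("endmember separation must be positive")
    if isinstance(pixels, PixelMatrix):
        X, labels, coords = pixels.X, pixels.labels, pixels.coords
    else:
        X = np.asarray(pixels, dtype=float)
        labels = np.zeros(X.shape[1], dtype=np.int8)
        coords = np.column_stack([np.zeros(X.shape[1], dtype=int),
                                  np.arange(X.shape[1])])
    axis = pair.axis  # w2 - w1
    t = (X - pair.w1[:, None]).T @ axis / (pair.separation ** 2)
    return SimilarityField(np.clip(t, 0.0, 1.0), labels, coords)


def qp_unmix(pixels: PixelMatrix | np.ndarray, pair: EndmemberPair,
             ftol: float = 1e-14) -> tuple[np.ndarray, np.ndarray]:
    """Fully constrained two-endmember unmixing, one QP per pixel.

    Minimizes ``0.5 h^T Q h + c^T h`` with ``Q = 2 W^T W`` and
    ``c = -2 W^T x`` subject to the coefficients summing to one and
    lying in [0, 1], using SLSQP per column. Quadratic in cost per
    pixel count; intended as the slow reference for :func:`vsm`.

    Returns
    -------
    H : (2, n) ndarray — rows are (control, salt) coefficients.
    converged : (n,) bool ndarray — per-column solver success.
    """
    X = pixels.X if isinstance(pixels, PixelMatrix) else np.asarray(pixels, dtype=float)
    W = np.column_stack([pair.w1, pair.w2])
    Q = 2.0 * W.T @ W
    n = X.shape[1]
    H = np.empty((2, n))
    converged = np.zeros(n, dtype=bool)
    constraints = {"type": "eq", "fun": lambda h: h.sum() - 1.0,
                   "jac": lambda h: np.ones(2)}
    bounds = [(0.0, 1.0), (0.0, 1.0)]
    for j in range(n):
        c = -2.0 * W.T @ X[:, j]
        res = minimize(
            lambda h: 0.5 * h @ Q @ h + c @ h,
            x0=np.array([0.5, 0.5]),
            jac=lambda h: Q @ h + c,
            method="SLSQP", bounds=bounds, constraints=constraints,
            options={"ftol": ftol, "maxiter": 200},
        )
        H[:, j] = np.clip(res.x, 0.0, 1.0)
        converged[j] = bool(res.success)
    return H, converged


def similarity_image(field: SimilarityField, shape: tuple[int, int]) -> np.ndarray:
    """Scatter a similarity field to a 2-D grid; background is exactly 0.

    The mapping is lossless for the masked pixels: re-reading the grid at
    ``field.coords`` returns ``field.s``. A pixel whose similarity is
    exactly 0 is distinguished from background by the coordinate list,
    not by the grid value.
    """
    rows, cols = field.coords[:, 0], field.coords[:, 1]
    if np.any(rows < 0) or np.any(rows >= shape[0]) or \
       np.any(cols < 0) or np.any(cols >= shape[1]):
        raise ValueError("coordinates outside the target shape")
    flat = rows.astype(np.int64) * shape[1] + cols.astype(np.int64)
    if len(np.unique(flat)) != len(flat):
        raise ValueError("coordinate collision: duplicate pixel locations")
    grid = np.zeros(shape)
    grid[rows, cols] = field.s
    return grid
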