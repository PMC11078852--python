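"""Shape-context descriptors and one-to-one border point correspondence.

Endoscopic mucosa is texture-poor, so keypoint descriptors fail; the two
segmented borders of the same polyp are instead matched purely on shape.
Each border point gets a log-polar histogram of the relative positions of
all other points (5 radial x 12 angular bins by default).  Radii are
normalised by the shape's mean pairwise distance, making descriptors scale
and translation invariant.  Angles are measured in the image frame (x-axis
= 0, counter-clockwise positive) — deliberately *not* rotation invariant:
usable view pairs are constrained to < 30 degrees relative rotation, and
the absolute orientation disambiguates near-symmetric borders.

Histograms are compared with the chi-squared distance and a globally
optimal one-to-one assignment is solved with the Hungarian algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .contours import BorderContour, resample_contour
from .exceptions import ShapeContextError


@dataclass(frozen=True)
class ShapeContextParams:
    """Binning geometry of the log-polar histogram.

    ``r_inner``/``r_outer`` bound the radial range as fractions of the
    shape's mean pairwise distance; points outside are dropped, not
    clamped.
    """

    n_r: int = 5
    n_theta: int = 12
    r_inner: float = 0.125
    r_outer: float = 2.0

    def __post_init__(self) -> None:
        if self.n_r < 1 or self.n_theta < 2:
            raise ShapeContextError("need n_r >= 1 and n_theta >= 2")
        if not (0 < self.r_inner < self.r_outer):
            raise ShapeContextError("need 0 < r_inner < r_outer")

    @property
    def radial_edges(self) -> np.ndarray:
        return np.logspace(np.log10(self.r_inner), np.log10(self.r_outer), self.n_r + 1)


@dataclass
class ShapeContextDescriptor:
    """Log-polar histogram of a shape around one reference point."""

    histogram: np.ndarray
    ref_index: int
    params: ShapeContextParams = field(default_factory=ShapeContextParams)

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=float)
        if self.histogram.shape != (self.params.n_r, self.params.n_theta):
            raise ShapeContextError(
                f"histogram shape {self.histogram.shape} != "
                f"({self.params.n_r}, {self.params.n_theta})"
            )
        if np.any(self.histogram < 0):
            raise ShapeContextError("negative histogram counts")


@dataclass
class CorrespondenceSet:
    """One-to-one point correspondences between borders P and Q."""

    pairs: list[tuple[int, int]]
    total_cost: float
    per_pair_cost: np.ndarray
    points_p: np.ndarray
    points_q: np.ndarray


def mean_pairwise_distance(points: np.ndarray) -> float:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    n = len(points)
    return float(d.sum() / (n * (n - 1)))


def compute_descriptors(
    points: np.ndarray, params: ShapeContextParams = ShapeContextParams()
) -> np.ndarray:
    """Histograms for every point of a shape, shape (n, n_r, n_theta).

    Vectorised over reference points: relative radii are normalised by the
    mean pairwise distance of the full set, binned logarithmically between
    ``r_inner`` and ``r_outer``; angles uniformly over [0, 2*pi).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        raise ShapeContextError(f"need >= 2 points, got {n}")
    diff = pts[None, :, :] - pts[:, None, :]  # [ref, other, xy]
    r = np.linalg.norm(diff, axis=-1)
    r_norm = r / mean_pairwise_distance(pts)
    theta = np.mod(np.arctan2(diff[..., 1], diff[..., 0]), 2 * np.pi)
    theta[theta >= 2 * np.pi - 1e-9] = 0.0  # snap wrap-around rounding onto bin 0

    edges = params.radial_edges
    r_bin = np.searchsorted(edges, r_norm, side="right") - 1
    t_bin = np.minimum((theta / (2 * np.pi) * params.n_theta).astype(int), params.n_theta - 1)
    valid = (r_norm >= edges[0]) & (r_norm <= edges[-1])
    r_bin = np.clip(r_bin, 0, params.n_r - 1)  # puts r == r_outer in the last bin
    valid &= ~np.eye(n, dtype=bool)  # exclude the reference point itself

    hist = np.zeros((n, params.n_r, params.n_theta))
    ref_idx, other_idx = np.nonzero(valid)
    np.add.at(hist, (ref_idx, r_bin[valid], t_bin[valid]), 1.0)
    return hist


def compute_descriptor(
    points: np.ndarray,
    ref_index: int,
    n_r: int = 5,
    n_theta: int = 12,
    r_inner: float = 0.125,
    r_outer: float = 2.0,
) -> ShapeContextDescriptor:
    """Shape-context histogram of ``points`` around ``points[ref_index]``."""
    params = ShapeContextParams(n_r=n_r, n_theta=n_theta, r_inner=r_inner, r_outer=r_outer)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if not (0 <= ref_index < len(pts)):
        raise ShapeContextError(f"ref_index {ref_index} out of range for {len(pts)} points")
    hist = compute_descriptors(pts, params)[ref_index]
    return ShapeContextDescriptor(hist, ref_index=ref_index, params=params)


def _normalise(h: np.ndarray) -> np.ndarray:
    total = h.sum(axis=tuple(range(1, h.ndim)), keepdims=True) if h.ndim > 2 else h.sum()
    if np.ndim(total) == 0:
        return h / total if total > 0 else h
    safe = np.where(total > 0, total, 1.0)
    return h / safe


def descriptor_cost(h_p: ShapeContextDescriptor, h_q: ShapeContextDescriptor) -> float:
    """Chi-squared distance between two normalised histograms.

    0.5 * sum (a-b)^2 / (a+b) over bins, empty-empty bins contributing 0.
    Symmetric, zero iff the normalised histograms coincide.
    """
    if h_p.params != h_q.params:
        raise ShapeContextError(
            f"mismatched bin geometry: {h_p.params} vs {h_q.params}"
        )
    a = _normalise(h_p.histogram)
    b = _normalise(h_q.histogram)
    denom = a + b
    mask = denom > 0
    return float(0.5 * np.sum((a[mask] - b[mask]) ** 2 / denom[mask]))


def cost_matrix(
    points_p: np.ndarray,
    points_q: np.ndarray,
    params: ShapeContextParams = ShapeContextParams(),
) -> np.ndarray:
    """Chi-squared cost between every descriptor of P and every one of Q."""
    hp = compute_descriptors(points_p, params).reshape(len(points_p), -1)
    hq = compute_descriptors(points_q, params).reshape(len(points_q), -1)
    hp = hp / np.where(hp.sum(axis=1, keepdims=True) > 0, hp.sum(axis=1, keepdims=True), 1.0)
    hq = hq / np.where(hq.sum(axis=1, keepdims=True) > 0, hq.sum(axis=1, keepdims=True), 1.0)
    a = hp[:, None, :]
    b = hq[None, :, :]
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, (a - b) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    return 0.5 * terms.sum(axis=-1)


def match_points(
    points_p: np.ndarray,
    points_q: np.ndarray,
    params: ShapeContextParams = ShapeContextParams(),
) -> CorrespondenceSet:
    """Optimal one-to-one assignment between two raw point sets.

    Solves the bipartite assignment minimising total chi-squared cost
    exactly; |pairs| = min(|P|, |Q|); pairs sorted by index in P.
    """
    points_p = np.asarray(points_p, dtype=float).reshape(-1, 2)
    points_q = np.asarray(points_q, dtype=float).reshape(-1, 2)
    C = cost_matrix(points_p, points_q, params)
    rows, cols = linear_sum_assignment(C)
    order = np.argsort(rows)
    rows, cols = rows[order], cols[order]
    costs = C[rows, cols]
    return CorrespondenceSet(
        pairs=list(zip(rows.tolist(), cols.tolist())),
        total_cost=float(costs.sum()),
        per_pair_cost=costs,
        points_p=points_p,
        points_q=points_q,
    )


def match_shapes(
    P: BorderContour,
    Q: BorderContour,
    n_samples: int = 100,
    params: ShapeContextParams = ShapeContextParams(),
) -> CorrespondenceSet:
    """Match two border contours after uniform arc-length downsampling."""
    if n_samples < 3:
        raise ShapeContextError(f"n_samples must be >= 3, got {n_samples}")
    p = resample_contour(P, n_samples)
    q = resample_contour(Q, n_samples)
    return match_points(p.points, q.points, params)
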