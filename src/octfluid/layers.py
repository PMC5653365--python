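"""ILM / RPE boundary segmentation by graph shortest path, and RPE flattening.

Each B-scan column contributes one boundary row per layer.  A pixel graph with
8-connectivity is built; the directed edge weight from pixel p1 to pixel p2 is

* ILM:  ``4*MaxG - VerGrad(p1) - VerGrad(p2) + 2*mean(R)``  — R the (up to)
  ``R_window`` pixels directly above p1, small only when the region above is
  dark background, which singles out the topmost retinal boundary;
* RPE:  ``4*MaxG - VerGrad(p1) - VerGrad(p2) - mean(U) - beta*D`` — U the
  ``U_window`` pixels directly below p1 and D the vertical distance of p1
  from the ILM, so that under sub-retinal fluid the deeper true RPE (choroid
  below, larger D) costs strictly less than the decoy edge above the fluid.

``VerGrad`` is the response to the vertical kernel (-2, 0, 2)^T; with
intensities in [0, 1] (MaxG = 1) its extremes are +-2*MaxG on an ideal step.
The weight computations expect their input in *reflectivity* orientation
(dark vitreous above the ILM, bright tissue below); :func:`segment_layers`
therefore evaluates them on ``1 - T``, a monotone relabeling of the
neutrosophic membership plane.

Elevated RPE (pigment epithelial detachment) is flattened by locating the
apex of maximal windowed curvature, walking outward to the feet of the
elevation, and replacing the intervening rows by the linear base chord, so
that sub-RPE fluid ends up above the flattened boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ._exceptions import InvalidInputError
from .config import LayerParams
from .ns import NSImage

__all__ = [
    "BoundaryCurve",
    "vertical_gradient",
    "ilm_edge_weight",
    "rpe_edge_weight",
    "shortest_boundary",
    "flatten_rpe",
    "segment_layers",
]

#: maximum gray level; membership planes are normalized to [0, 1]
MAX_G = 1.0
#: lower clip keeping every edge weight positive for Dijkstra
WEIGHT_EPS = 1e-6
#: zero-cost virtual source/sink links (must be nonzero to survive sparse storage)
_VIRTUAL_EPS = 1e-12

_OFFSETS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class BoundaryCurve:
    """One row index per column of a retinal layer boundary."""

    rows: np.ndarray
    kind: str = "ILM"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.ndim != 1 or self.rows.size < 1:
            raise InvalidInputError("a boundary curve needs a 1D row per column")
        if np.any(self.rows < 0):
            raise InvalidInputError("boundary rows must be non-negative")

    @property
    def n_cols(self) -> int:
        return int(self.rows.size)

    def as_int(self) -> np.ndarray:
        return np.rint(self.rows).astype(np.intp)


def vertical_gradient(img: np.ndarray, direction: str = "dark_to_bright") -> np.ndarray:
    """Vertical edge response of the 3x1 kernel (-2, 0, 2), mirror-padded.

    ``dark_to_bright`` responds maximally (+2*MaxG) where a dark band sits
    above a bright band; ``bright_to_dark`` is its negation.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3:
        raise InvalidInputError("vertical gradient needs a 2D image with >= 3 rows")
    if direction not in ("dark_to_bright", "bright_to_dark"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    kernel = np.array([[-2.0], [0.0], [2.0]])
    grad = ndimage.correlate(img, kernel, mode="reflect")
    return grad if direction == "dark_to_bright" else -grad


def _mean_above(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel mean of up to ``window`` pixels strictly above, same column.

    At the top row no pixel exists above; the pixel's own value is used.
    """
    n_rows, n_cols = img.shape
    cs = np.vstack([np.zeros((1, n_cols)), np.cumsum(img, axis=0)])
    r = np.arange(n_rows)
    lo = np.maximum(0, r - window)
    counts = (r - lo).astype(np.float64)
    sums = cs[r] - cs[lo]
    means = sums / np.maximum(counts, 1.0)[:, None]
    means[0] = img[0]
    return means


def _mean_below(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel mean of up to ``window`` pixels strictly below, same column."""
    n_rows, n_cols = img.shape
    cs = np.vstack([np.zeros((1, n_cols)), np.cumsum(img, axis=0)])
    r = np.arange(n_rows)
    hi = np.minimum(n_rows, r + 1 + window)
    counts = (hi - (r + 1)).astype(np.float64)
    sums = cs[hi] - cs[r + 1]
    means = sums / np.maximum(counts, 1.0)[:, None]
    means[-1] = img[-1]
    return means


def _check_neighbors(p1, p2) -> None:
    if max(abs(p1[0] - p2[0]), abs(p1[1] - p2[1])) != 1:
        raise InvalidInputError(f"{p1} and {p2} are not 8-neighbors")


def ilm_edge_weight(p1, p2, VerGrad: np.ndarray, img: np.ndarray,
                    params: LayerParams | None = None) -> float:
    """ILM weight of the directed edge p1 -> p2 (clipped positive)."""
    params = params or LayerParams()
    _check_neighbors(p1, p2)
    mean_r = _mean_above(np.asarray(img, dtype=np.float64), params.R_window)
    w = 4.0 * MAX_G - VerGrad[p1] - VerGrad[p2] + 2.0 * mean_r[p1]
    return float(max(w, WEIGHT_EPS))


def rpe_edge_weight(p1, p2, VerGrad: np.ndarray, img: np.ndarray,
                    ilm: BoundaryCurve, params: LayerParams | None = None) -> float:
    """RPE weight of the directed edge p1 -> p2 (clipped positive).

    ``D = row(p1) - ilm_row(col(p1))``; negative D (above the ILM) is allowed
    by the formula but such pixels are excluded from the path search.
    """
    params = params or LayerParams()
    _check_neighbors(p1, p2)
    mean_u = _mean_below(np.asarray(img, dtype=np.float64), params.U_window)
    d = float(p1[0]) - float(ilm.rows[p1[1]])
    w = (4.0 * MAX_G - VerGrad[p1] - VerGrad[p2]
         - mean_u[p1] - params.beta * d)
    return float(max(w, WEIGHT_EPS))


def _curve_from_node_costs(a: np.ndarray, b: np.ndarray,
                           valid: np.ndarray | None = None) -> np.ndarray:
    """Shortest left-to-right path where edge(p->q) = max(a[p] + b[q], eps).

    Dijkstra runs from a virtual source attached to every (valid) pixel of
    column 0 to a virtual sink reached from every (valid) pixel of the last
    column; the returned array holds, per column, the last pixel the path
    visited in that column.
    """
    n_rows, n_cols = a.shape
    n = n_rows * n_cols
    idx = np.arange(n).reshape(n_rows, n_cols)
    vflat = None if valid is None else np.asarray(valid, dtype=bool).ravel()

    frm, to, wgt = [], [], []
    for dr, dc in _OFFSETS_8:
        rs = slice(max(0, -dr), n_rows - max(0, dr))
        cs = slice(max(0, -dc), n_cols - max(0, dc))
        rd = slice(max(0, dr), n_rows - max(0, -dr))
        cd = slice(max(0, dc), n_cols - max(0, -dc))
        f = idx[rs, cs].ravel()
        t = idx[rd, cd].ravel()
        w = np.maximum(a[rs, cs].ravel() + b[rd, cd].ravel(), WEIGHT_EPS)
        if vflat is not None:
            keep = vflat[f] & vflat[t]
            f, t, w = f[keep], t[keep], w[keep]
        frm.append(f)
        to.append(t)
        wgt.append(w)

    source, sink = n, n + 1
    left = idx[:, 0][vflat[idx[:, 0]]] if vflat is not None else idx[:, 0]
    right = idx[:, -1][vflat[idx[:, -1]]] if vflat is not None else idx[:, -1]
    if left.size == 0 or right.size == 0:
        raise InvalidInputError("no admissible pixels in the first or last column")
    frm.append(np.full(left.size, source))
    to.append(left)
    wgt.append(np.full(left.size, _VIRTUAL_EPS))
    frm.append(right)
    to.append(np.full(right.size, sink))
    wgt.append(np.full(right.size, _VIRTUAL_EPS))

    graph = coo_matrix(
        (np.concatenate(wgt), (np.concatenate(frm), np.concatenate(to))),
        shape=(n + 2, n + 2)).tocsr()
    dist, pred = dijkstra(graph, directed=True, indices=source,
                          return_predecessors=True)
    if not np.isfinite(dist[sink]):
        raise RuntimeError("virtual sink unreachable — internal graph error")

    path = []
    node = pred[sink]
    while node != source and node >= 0:
        path.append(int(node))
        node = pred[node]
    path.reverse()

    rows = np.full(n_cols, -1, dtype=np.intp)
    for node in path:  # later visits overwrite: last-visited pixel per column
        rows[node % n_cols] = node // n_cols
    if np.any(rows < 0):
        raise RuntimeError("path skipped a column — internal graph error")
    return rows


def shortest_boundary(weight_fn: Callable, shape: tuple[int, int]) -> BoundaryCurve:
    """Shortest boundary under an arbitrary directed 8-neighbor weight function.

    ``weight_fn((r1, c1), (r2, c2))`` must return the weight of the directed
    edge between any two 8-neighbors.  Intended for small grids and testing;
    :func:`segment_layers` uses a vectorized equivalent.
    """
    n_rows, n_cols = shape
    n = n_rows * n_cols
    source, sink = n, n + 1
    frm, to, wgt = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in _OFFSETS_8:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                    frm.append(r * n_cols + c)
                    to.append(r2 * n_cols + c2)
                    wgt.append(max(float(weight_fn((r, c), (r2, c2))), WEIGHT_EPS))
    for r in range(n_rows):
        frm.append(source)
        to.append(r * n_cols)
        wgt.append(_VIRTUAL_EPS)
        frm.append(r * n_cols + (n_cols - 1))
        to.append(sink)
        wgt.append(_VIRTUAL_EPS)
    graph = coo_matrix((wgt, (frm, to)), shape=(n + 2, n + 2)).tocsr()
    dist, pred = dijkstra(graph, directed=True, indices=source,
                          return_predecessors=True)
    if not np.isfinite(dist[sink]):
        raise RuntimeError("virtual sink unreachable — internal graph error")
    path = []
    node = pred[sink]
    while node != source and node >= 0:
        path.append(int(node))
        node = pred[node]
    path.reverse()
    rows = np.full(n_cols, -1, dtype=np.intp)
    for node in path:
        rows[node % n_cols] = node // n_cols
    if np.any(rows < 0):
        raise RuntimeError("path skipped a column — internal graph error")
    return BoundaryCurve(rows, kind="ILM")


def _windowed_curvature(rows: np.ndarray, W: int) -> np.ndarray:
    """Windowed second difference sum_{j=1..W} [r(i-j) + r(i+j) - 2 r(i)].

    Maximal at the apex of an upward elevation (rows grow downward).  Only the
    interior i in [W, n-W) is meaningful; the borders are set to -inf.
    """
    n = rows.size
    kernel = np.ones(2 * W + 1)
    kernel[W] = -2.0 * W
    curv = np.convolve(rows, kernel, mode="same")
    curv[:W] = -np.inf
    curv[n - W:] = -np.inf
    return curv


def flatten_rpe(rpe: BoundaryCurve, params: LayerParams | None = None) -> BoundaryCurve:
    """Replace elevated RPE segments by their linear base chord.

    The apex (Pick) is the interior index of maximal windowed curvature; the
    feet (PickStart/PickEnd) are found by walking left/right while the curve
    stays above (smaller row than) the point ``Tr`` columns further out; the
    rows in between become the straight chord.  Repeats up to
    ``max_flatten_iters`` times while the maximal curvature stays above
    ``min_curvature``, handling multiple elevations.
    """
    params = params or LayerParams()
    W, Tr = params.flatten_W, params.flatten_Tr
    rows = np.array(rpe.rows, dtype=np.float64)
    n = rows.size
    if n < 2 * W + 1:
        raise InvalidInputError(
            f"curve of length {n} is shorter than 2*flatten_W+1 = {2 * W + 1}")

    for _ in range(params.max_flatten_iters):
        # curvature and foot walks run on a median-smoothed copy so +-1 px
        # path noise cannot stop the walks early on the elevation slope
        work = ndimage.median_filter(rows, size=5, mode="nearest")
        curv = _windowed_curvature(work, W)
        pick = int(np.argmax(curv))
        if not np.isfinite(curv[pick]) or curv[pick] < params.min_curvature:
            break
        curr = pick
        while curr - Tr >= 0 and curr > 0 and work[curr] < work[curr - Tr]:
            curr -= 1
        pick_start = curr
        curr = pick
        while curr + Tr <= n - 1 and curr < n - 1 and work[curr] < work[curr + Tr]:
            curr += 1
        pick_end = curr
        if pick_end - pick_start < 2:
            break
        # chord endpoints: the deepest row in a small window just outside
        # each foot, robust against a foot landing on the slope
        start_row = float(work[max(0, pick_start - 4):pick_start + 1].max())
        end_row = float(work[pick_end:pick_end + 5].max())
        span = np.arange(pick_start, pick_end + 1)
        # the chord passes between pixels: assign it to the deeper row so the
        # detachment interior stays entirely above the flattened boundary
        rows[span] = np.ceil(np.interp(span, [pick_start, pick_end],
                                       [start_row, end_row]))
    return BoundaryCurve(rows, kind="RPE_flattened")


def segment_layers(ns: NSImage, params: LayerParams | None = None,
                   return_raw_rpe: bool = False):
    """Segment the ILM and the flattened RPE of a B-scan in the NS domain.

    All gradient/mean quantities are evaluated on the reflectivity image
    ``1 - T`` (dark background above the ILM, bright tissue below), where the
    weight equations behave as designed.  The RPE search is restricted to
    rows at least ``min_ilm_rpe_gap`` below the ILM, and the flattened RPE is
    forced strictly below the ILM at every column.
    """
    params = params or LayerParams()
    refl = 1.0 - ns.T
    grad_src = refl
    if params.presmooth:
        # horizontal oriented Gaussian for the gradient only: averages the
        # speckle along the layers, leaving the near-horizontal boundaries
        # sharp; the R/U column means stay on the raw reflectivity so they
        # do not skim the blurred tail of a bright band
        from .ns import build_filter_bank
        kernel = build_filter_bank((3, 9), 1).filters[0]
        grad_src = ndimage.correlate(refl, kernel, mode="reflect")
    n_rows, n_cols = refl.shape

    # ILM: dark-above / bright-below edge, penalized by brightness above
    vg = vertical_gradient(grad_src, "dark_to_bright")
    a = 4.0 * MAX_G - vg + 2.0 * _mean_above(refl, params.R_window)
    b = -vg
    ilm = BoundaryCurve(_curve_from_node_costs(a, b), kind="ILM")

    # RPE: bright-above / dark-below edge, rewarded for brightness below
    # (choroid vs fluid) and for depth from the ILM
    vg = vertical_gradient(grad_src, "bright_to_dark")
    d = np.arange(n_rows, dtype=np.float64)[:, None] - ilm.rows[None, :]
    a = (4.0 * MAX_G - vg - _mean_below(refl, params.U_window) - params.beta * d)
    b = -vg
    valid = np.arange(n_rows)[:, None] >= (ilm.rows[None, :] + params.min_ilm_rpe_gap)
    valid[-1, :] = True  # the bottom row is always admissible
    rpe = BoundaryCurve(_curve_from_node_costs(a, b, valid), kind="RPE")

    rpe_flat = flatten_rpe(rpe, params)
    rpe_flat.rows = np.minimum(np.maximum(rpe_flat.rows, ilm.rows + 1.0),
                               float(n_rows - 1))
    if return_raw_rpe:
        return ilm, rpe_flat, rpe
    return ilm, rpe_flat
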