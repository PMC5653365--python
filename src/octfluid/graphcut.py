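"""Binary fluid/tissue segmentation by kernel graph cut.

The labeling A minimizes

    E(A) = lambda1 * sum_p R_p(A_p)  +  lambda2 * sum_{p,q} B_pq * [A_p != A_q]

where the regional penalty is the RBF-kernel squared distance of a pixel's
membership value to the class center,

    R1_p(A_p) = 2 - 2 exp(-(mu_{A_p} - t_p)^2 / (2 sigma^2)),

damped for indeterminate pixels: whichever of R1_p('O'), R1_p('B') is larger
is multiplied by (1 - I_p), weakening the strong (and possibly noise-driven)
terminal attachment of noisy pixels.  The boundary term is the classical
contrast-sensitive n-link weight exp(-(t_p - t_q)^2 / (2 sigma_b^2)) / dist.

The energy is minimized exactly by a single s-t min-cut on the two-terminal
graph: each pixel holds a t-link of capacity lambda1*R_p('B') to the object
terminal and lambda1*R_p('O') to the background terminal, seeds are enforced
with a hard-constraint capacity exceeding any finite cut, and n-links carry
lambda2*B_pq.  Max-flow runs through scipy's Dinic implementation on
integer capacities scaled so that quantization sits many orders of magnitude
below the energy gaps between labelings.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from ._exceptions import InvalidInputError, InvalidParameterError
from .config import EnergyParams
from .seeds import SeedSet

__all__ = [
    "rbf_regional",
    "ge",
    "regional_terms",
    "boundary_weight",
    "segmentation_energy",
    "build_and_cut",
]

_AXIAL = ((0, 1), (1, 0))
_DIAGONAL = ((1, 1), (1, -1))


def rbf_regional(p_val, mu, sigma: float):
    """Kernel-space squared distance 2 - 2*exp(-(mu - p)^2 / (2 sigma^2)).

    Accepts scalars or arrays; the range is [0, 2).
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    return 2.0 - 2.0 * np.exp(-((np.asarray(mu, dtype=np.float64) - p_val) ** 2)
                              / (2.0 * sigma ** 2))


def ge(a, b):
    """Strict greater-than indicator: 1 iff a > b, else 0 (ties fall to 0)."""
    return np.where(np.asarray(a) > np.asarray(b), 1, 0)[()]


def regional_terms(R1_O, R1_B, I_p, floor: bool = True):
    """Indeterminacy damping: only the strictly larger penalty is scaled by (1 - I).

    Ties leave both penalties unchanged.  With ``floor`` (the default) the
    damped penalty never drops below its undamped competitor, so a pixel's
    indeterminacy can neutralize its regional preference — handing the
    decision to the boundary term — but never invert it; this matters where
    both penalties saturate near 2 (pixels far from both class means), whose
    exponentially thin margins any nonzero I would otherwise flip.
    """
    R1_O = np.asarray(R1_O, dtype=np.float64)
    R1_B = np.asarray(R1_B, dtype=np.float64)
    I_p = np.asarray(I_p, dtype=np.float64)
    damp_O = (1.0 - I_p) * R1_O
    damp_B = (1.0 - I_p) * R1_B
    if floor:
        damp_O = np.maximum(damp_O, R1_B)
        damp_B = np.maximum(damp_B, R1_O)
    R_O = np.where(R1_O > R1_B, damp_O, R1_O)
    R_B = np.where(R1_B > R1_O, damp_B, R1_B)
    return R_O[()], R_B[()]


def boundary_weight(t_p, t_q, dist: float, sigma_b: float):
    """Contrast-sensitive n-link weight exp(-(t_p-t_q)^2 / (2 sigma_b^2)) / dist."""
    if dist <= 0:
        raise InvalidParameterError("dist must be positive")
    if sigma_b <= 0:
        raise InvalidParameterError("sigma_b must be positive")
    tp = np.asarray(t_p, dtype=np.float64)
    tq = np.asarray(t_q, dtype=np.float64)
    return np.exp(-((tp - tq) ** 2) / (2.0 * sigma_b ** 2)) / dist


def _neighbor_offsets(neighborhood: int):
    return _AXIAL if neighborhood == 4 else _AXIAL + _DIAGONAL


def _regional_penalties(T: np.ndarray, I: np.ndarray, mu_O: float, mu_B: float,
                        params: EnergyParams):
    R1_O = rbf_regional(T, mu_O, params.sigma)
    R1_B = rbf_regional(T, mu_B, params.sigma)
    return regional_terms(R1_O, R1_B, I, floor=params.damping_floor)


def segmentation_energy(labels: np.ndarray, T: np.ndarray, I: np.ndarray,
                        mu_O: float, mu_B: float,
                        params: EnergyParams | None = None) -> float:
    """Evaluate the full energy of a binary labeling (1 = fluid/'O')."""
    params = params or EnergyParams()
    labels = np.asarray(labels, dtype=bool)
    R_O, R_B = _regional_penalties(T, I, mu_O, mu_B, params)
    regional = float(np.where(labels, R_O, R_B).sum())
    boundary = 0.0
    for dr, dc in _neighbor_offsets(params.neighborhood):
        dist = float(np.hypot(dr, dc))
        t_p = T[max(0, -dr):T.shape[0] - max(0, dr), max(0, -dc):T.shape[1] - max(0, dc)]
        t_q = T[max(0, dr):T.shape[0] - max(0, -dr), max(0, dc):T.shape[1] - max(0, -dc)]
        l_p = labels[max(0, -dr):T.shape[0] - max(0, dr), max(0, -dc):T.shape[1] - max(0, dc)]
        l_q = labels[max(0, dr):T.shape[0] - max(0, -dr), max(0, dc):T.shape[1] - max(0, -dc)]
        b = boundary_weight(t_p, t_q, dist, params.sigma_boundary)
        boundary += float(b[l_p != l_q].sum())
    return params.lambda1 * regional + params.lambda2 * boundary


def class_means(T: np.ndarray, seeds: SeedSet, params: EnergyParams):
    """Class centers mu_O / mu_B from the seed pixels' T values (or the
    k-means cluster centers when ``params.mu_source == 'centers'``)."""
    if params.mu_source == "centers" and seeds.cluster_centers is not None:
        centers = np.asarray(seeds.cluster_centers, dtype=np.float64)
        return float(centers[:2].mean()), float(centers[2:].mean())
    fl = np.asarray(seeds.fluid, dtype=np.intp)
    ti = np.asarray(seeds.tissue, dtype=np.intp)
    mu_O = float(T[fl[:, 0], fl[:, 1]].mean()) if len(fl) else float("nan")
    mu_B = float(T[ti[:, 0], ti[:, 1]].mean())
    return mu_O, mu_B


def build_and_cut(T: np.ndarray, I: np.ndarray, seeds: SeedSet,
                  params: EnergyParams | None = None,
                  mu_O: float | None = None,
                  mu_B: float | None = None) -> np.ndarray:
    """Globally minimize the energy and return the binary fluid mask.

    Seed pixels are hard-constrained to their class.  An empty fluid seed set
    returns the all-background mask (the normal-scan path); an empty tissue
    seed set is an error.
    """
    params = params or EnergyParams()
    T = np.asarray(T, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    if T.shape != I.shape:
        raise InvalidInputError("T and I must share one shape")
    if not seeds.tissue:
        raise InvalidInputError("tissue seed set is empty")
    if not seeds.fluid:
        return np.zeros(T.shape, dtype=np.uint8)

    auto_O, auto_B = class_means(T, seeds, params)
    mu_O = auto_O if mu_O is None else mu_O
    mu_B = auto_B if mu_B is None else mu_B

    n_rows, n_cols = T.shape
    n = n_rows * n_cols
    R_O, R_B = _regional_penalties(T, I, mu_O, mu_B, params)
    # t-link orientation: R_p('B') attaches to the object terminal (source)
    cap_src = params.lambda1 * R_B.ravel()
    cap_snk = params.lambda1 * R_O.ravel()
    if params.swap_tlinks:
        cap_src, cap_snk = cap_snk, cap_src

    idx = np.arange(n).reshape(n_rows, n_cols)
    nl_from, nl_to, nl_cap = [], [], []
    for dr, dc in _neighbor_offsets(params.neighborhood):
        dist = float(np.hypot(dr, dc))
        t_p = T[max(0, -dr):n_rows - max(0, dr), max(0, -dc):n_cols - max(0, dc)]
        t_q = T[max(0, dr):n_rows - max(0, -dr), max(0, dc):n_cols - max(0, -dc)]
        f = idx[max(0, -dr):n_rows - max(0, dr), max(0, -dc):n_cols - max(0, dc)].ravel()
        t = idx[max(0, dr):n_rows - max(0, -dr), max(0, dc):n_cols - max(0, -dc)].ravel()
        cap = params.lambda2 * boundary_weight(t_p, t_q, dist, params.sigma_boundary).ravel()
        nl_from.append(f)
        nl_to.append(t)
        nl_cap.append(cap)
    nl_from = np.concatenate(nl_from)
    nl_to = np.concatenate(nl_to)
    nl_cap = np.concatenate(nl_cap)
    if np.any(nl_cap < 0):
        raise InvalidInputError("negative boundary capacity — non-submodular energy")

    fl = np.asarray(seeds.fluid, dtype=np.intp)
    ti = np.asarray(seeds.tissue, dtype=np.intp)
    fl_idx = fl[:, 0] * n_cols + fl[:, 1]
    ti_idx = ti[:, 0] * n_cols + ti[:, 1]
    cap_src = cap_src.copy()
    cap_snk = cap_snk.copy()
    cap_src[fl_idx] = 0.0  # placeholder; K assigned below
    cap_snk[fl_idx] = 0.0
    cap_src[ti_idx] = 0.0
    cap_snk[ti_idx] = 0.0

    # Upper-bound the min cut by the cut value of the per-pixel threshold
    # labeling (seeds forced to their class): its regional part is the cheaper
    # t-link of every free pixel, its boundary part the n-links across
    # disagreeing neighbors.  The hard-constraint capacity K sits just above
    # this bound, so no seed t-link is ever cut.
    thresh = cap_snk < cap_src  # object iff the sink link is the cheaper cut
    thresh[fl_idx] = True
    thresh[ti_idx] = False
    cut_bound = float(np.minimum(cap_src, cap_snk).sum()
                      + nl_cap[thresh[nl_from] != thresh[nl_to]].sum()) + 1.0
    K = cut_bound + 1.0
    cap_src[fl_idx] = K
    cap_snk[ti_idx] = K

    # scipy's max-flow truncates capacities (and accumulates flow) in int32,
    # so scale the largest capacity — K, which also bounds the flow value —
    # just below 2^31, leaving headroom for rounding
    scale = (2.0 ** 31 - 2.0 ** 20) / max(K, float(nl_cap.max(initial=1.0)))

    source, sink = n, n + 1
    frm = np.concatenate([np.full(n, source), np.arange(n),     # t-links + reverses
                          np.arange(n), np.full(n, sink),
                          nl_from, nl_to])
    to = np.concatenate([np.arange(n), np.full(n, source),
                         np.full(n, sink), np.arange(n),
                         nl_to, nl_from])
    cap = np.concatenate([cap_src, np.zeros(n),
                          cap_snk, np.zeros(n),
                          nl_cap, nl_cap])
    cap_int = np.rint(cap * scale).astype(np.int64)
    graph = coo_matrix((cap_int, (frm, to)), shape=(n + 2, n + 2)).tocsr()
    graph.sum_duplicates()

    result = maximum_flow(graph, source, sink)
    residual = graph - result.flow
    residual.data = (residual.data > 0).astype(np.int64)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, source, directed=True,
                                return_predecessors=False)
    labels = np.zeros(n, dtype=np.uint8)
    labels[reach[(reach != source) & (reach != sink)]] = 1

    if labels[fl_idx].min(initial=1) != 1 or labels[ti_idx].max(initial=0) != 0:
        raise RuntimeError("min-cut violated seed hard constraints")
    return labels.reshape(n_rows, n_cols)
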