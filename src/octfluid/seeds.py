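"""Fully-automated fluid/tissue seed initialization.

The scan is mapped to the conventional neutrosophic domain and its membership
plane is coarsely partitioned with scalar k-means.  Clusters are ranked by
descending center: in the inverted membership plane the darkest structures
(fluid — and the vitreous background, which the pipeline later discards) hold
the highest memberships, so fluid seeds are drawn from the top *two* clusters
(the second guards against scans whose first cluster is pure background).
Tissue seeds come from the remaining k-2 clusters with geometrically decaying
proportions p_i = 1/2^(i-2) (i = 3..k, normalized), so each cluster receives
more seeds than all farther-from-fluid clusters combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._exceptions import InvalidInputError
from .config import NSParams, SeedParams
from .io import validate_gray
from .layers import BoundaryCurve
from .ns import to_ns_conventional

__all__ = [
    "SeedSet",
    "coarse_partition",
    "sample_fluid_seeds",
    "sample_tissue_seeds",
    "tissue_allocation",
    "init_seeds",
]


@dataclass
class SeedSet:
    """Pixel coordinates of the fluid (object) and tissue (background) seeds."""

    fluid: list = field(default_factory=list)
    tissue: list = field(default_factory=list)
    cluster_centers: np.ndarray = None
    low_fluid: bool = False

    def __post_init__(self) -> None:
        overlap = set(map(tuple, self.fluid)) & set(map(tuple, self.tissue))
        if overlap:
            raise InvalidInputError(f"fluid and tissue seeds overlap: {sorted(overlap)[:3]}")


def coarse_partition(T: np.ndarray, mask: np.ndarray | None,
                     params: SeedParams | None = None):
    """k-means partition of the masked membership values.

    Returns ``(labels, centers)``: ``labels`` is a 2D int array with clusters
    1..k ranked by descending center (0 marks pixels outside the mask), and
    ``centers`` the sorted (descending) cluster centers.
    """
    params = params or SeedParams()
    T = np.asarray(T, dtype=np.float64)
    if mask is None:
        mask = np.ones(T.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != T.shape:
        raise InvalidInputError("mask and T must have the same shape")
    vals = T[mask]
    if vals.size < params.k:
        raise InvalidInputError(
            f"only {vals.size} masked pixels for k={params.k} clusters")

    km = KMeans(n_clusters=params.k, n_init=10,
                random_state=int(params.rng_seed) % (2 ** 31))
    raw = km.fit_predict(vals.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(-centers)            # descending centers
    rank = np.empty_like(order)
    rank[order] = np.arange(1, params.k + 1)

    labels = np.zeros(T.shape, dtype=np.intp)
    labels[mask] = rank[raw]
    return labels, centers[order]


def _coords_of(labels: np.ndarray, which) -> np.ndarray:
    rr, cc = np.nonzero(np.isin(labels, which))
    return np.stack([rr, cc], axis=1)


def sample_fluid_seeds(labels: np.ndarray, centers: np.ndarray,
                       params: SeedParams | None = None,
                       rng: np.random.Generator | None = None) -> list:
    """Draw up to FN fluid seeds uniformly from clusters 1-2 (all if fewer)."""
    params = params or SeedParams()
    rng = rng or np.random.default_rng(params.rng_seed)
    coords = _coords_of(labels, (1, 2))
    if coords.shape[0] == 0:
        return []
    take = min(params.FN, coords.shape[0])
    pick = rng.choice(coords.shape[0], size=take, replace=False)
    return [tuple(map(int, coords[i])) for i in pick]


def tissue_allocation(k: int, TN: int) -> np.ndarray:
    """Per-cluster tissue seed counts for clusters 3..k.

    Unnormalized proportions p_i = 1/2^(i-2); counts are Np_i * TN rounded
    half-up, with the rounding residue assigned to cluster 3 so the total is
    exactly TN.
    """
    i = np.arange(3, k + 1)
    p = 0.5 ** (i - 2)
    np_i = p / p.sum()
    counts = np.floor(np_i * TN + 0.5).astype(int)
    counts[0] += TN - counts.sum()
    if counts[0] < 0:
        raise InvalidInputError("TN too small for the requested k")
    return counts


def sample_tissue_seeds(labels: np.ndarray, centers: np.ndarray,
                        params: SeedParams | None = None,
                        rng: np.random.Generator | None = None) -> list:
    """Draw up to TN tissue seeds from clusters 3..k with geometric weights."""
    params = params or SeedParams()
    rng = rng or np.random.default_rng(params.rng_seed)
    k = len(centers)
    if k < 3:
        raise InvalidInputError("need at least 3 clusters for tissue seeds")
    counts = tissue_allocation(k, params.TN)
    seeds: list = []
    any_pixels = False
    for cluster, want in zip(range(3, k + 1), counts):
        coords = _coords_of(labels, (cluster,))
        if coords.shape[0] == 0:
            continue
        any_pixels = True
        take = min(int(want), coords.shape[0])
        if take == 0:
            continue
        pick = rng.choice(coords.shape[0], size=take, replace=False)
        seeds.extend(tuple(map(int, coords[i])) for i in pick)
    if not any_pixels:
        raise InvalidInputError("no tissue clusters populated — not a valid scan")
    return seeds


def init_seeds(g: np.ndarray, ilm: BoundaryCurve | None = None,
               rpe_flat: BoundaryCurve | None = None,
               params: SeedParams | None = None,
               ns_params: NSParams | None = None) -> SeedSet:
    """Run the full automated seed initialization on a B-scan.

    Transforms ``g`` with the conventional NS transform, coarsely partitions
    the membership plane, and samples both seed sets with one deterministic
    RNG stream seeded by ``params.rng_seed``.  With ``restrict_to_band`` the
    partition and the samples are confined strictly between the ILM and the
    flattened RPE; the default considers the whole scan, in which case
    fluid-free scans place their fluid seeds in the dark background that the
    pipeline later clips away.
    """
    params = params or SeedParams()
    g = validate_gray(g)
    ns = to_ns_conventional(g, ns_params)

    mask = None
    if params.restrict_to_band:
        if ilm is None or rpe_flat is None:
            raise InvalidInputError("restrict_to_band requires both layer curves")
        rows = np.arange(g.shape[0])[:, None]
        mask = (rows > ilm.rows[None, :]) & (rows < rpe_flat.rows[None, :])
        if not mask.any():
            raise InvalidInputError("empty ILM-RPE band")

    labels, centers = coarse_partition(ns.T, mask, params)
    rng = np.random.default_rng(params.rng_seed)
    fluid = sample_fluid_seeds(labels, centers, params, rng)
    tissue = sample_tissue_seeds(labels, centers, params, rng)
    return SeedSet(fluid=fluid, tissue=tissue, cluster_centers=centers,
                   low_fluid=len(fluid) < 0.1 * params.FN)
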