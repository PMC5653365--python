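"""Parameter containers for every pipeline stage, plus YAML round-tripping.

All parameters carry the defaults used throughout the package; a YAML config
file with dotted sections (``ns:``, ``layers:``, ``seeds:``, ``energy:``,
``pipeline:``) overrides any subset of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

from ._exceptions import InvalidParameterError


@dataclass
class NSParams:
    """Parameters of the neutrosophic-domain transforms.

    lambda_corr
        Indeterminacy threshold of the lambda-correction: pixels with
        I >= lambda_corr are replaced by the most deviating directional
        filter response.  0.7 in all experiments.
    entropy_tol
        Convergence tolerance on the change of the indeterminacy entropy
        between iterations.
    conv_window
        Side of the square averaging window (odd) used for the local-mean
        image in both transforms.
    alpha, beta
        Indeterminacy thresholds of the alpha-mean and beta-enhancement
        operations of the conventional transform.
    entropy_bins
        Histogram bins over [0, 1] for the entropy criterion.
    max_iters
        Hard iteration cap guarding non-convergent entropy loops.
    proposed_local_mean
        When True the layered-structure transform builds T from the
        ``conv_window`` local-mean image (as the conventional transform
        does) instead of the raw normalized intensity.  The default keeps T
        sharp: pre-smoothing with an isotropic window smears the layer
        edges by half a window, which is exactly what the oriented-filter
        indeterminacy is designed to avoid.
    """

    lambda_corr: float = 0.7
    entropy_tol: float = 1e-3
    conv_window: int = 11
    alpha: float = 0.85
    beta: float = 0.85
    entropy_bins: int = 100
    max_iters: int = 50
    proposed_local_mean: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_corr < 1.0:
            raise InvalidParameterError("lambda_corr must lie in (0, 1)")
        if self.entropy_tol <= 0:
            raise InvalidParameterError("entropy_tol must be positive")
        if self.conv_window < 3 or self.conv_window % 2 == 0:
            raise InvalidParameterError("conv_window must be an odd integer >= 3")
        if self.max_iters < 1:
            raise InvalidParameterError("max_iters must be >= 1")


@dataclass
class LayerParams:
    """Parameters of the shortest-path layer segmentation and RPE flattening.

    R_window: pixels above a node averaged in the ILM weight (term 2*mean(R)).
    U_window: pixels below a node averaged in the RPE weight (term -mean(U)).
    beta:     coefficient of the node-to-ILM vertical distance in the RPE weight.
    flatten_W / flatten_Tr: curvature half-window and elevation look-ahead of
        the RPE flattening.
    min_ilm_rpe_gap: the RPE path is restricted to rows >= ILM + this gap.
    min_curvature: windowed-second-difference magnitude (px * columns) below
        which no elevation is flattened; anatomical undulation of a few px
        stays well below it while pathological elevations exceed it by an
        order of magnitude.
    """

    R_window: int = 40
    U_window: int = 10
    beta: float = 0.004
    flatten_W: int = 150
    flatten_Tr: int = 40
    min_ilm_rpe_gap: int = 5
    min_curvature: float = 1000.0
    max_flatten_iters: int = 5
    #: smooth the reflectivity with the horizontal oriented Gaussian before
    #: gradient/mean computation — suppresses speckle along the layers
    #: without blurring the (near-horizontal) boundaries themselves
    presmooth: bool = True

    def __post_init__(self) -> None:
        for name in ("R_window", "U_window", "flatten_W", "flatten_Tr",
                     "min_ilm_rpe_gap", "max_flatten_iters"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.beta <= 0:
            raise InvalidParameterError("beta must be positive")


@dataclass
class SeedParams:
    """Parameters of the automated seed initialization.

    k: number of k-means clusters of the coarse partition (>= 4: at least two
       fluid plus two tissue clusters).
    FN / TN: number of fluid / tissue seed points drawn.
    restrict_to_band: when True, clustering and sampling are confined to the
       ILM..flattened-RPE band; the default samples the whole scan, which is
       what makes fluid-free scans come out empty after post-filtering (their
       dark background absorbs the fluid clusters and is discarded later).
    """

    k: int = 7
    FN: int = 500
    TN: int = 700
    rng_seed: int = 0
    restrict_to_band: bool = False

    def __post_init__(self) -> None:
        if self.k < 4:
            raise InvalidParameterError("k must be >= 4 (two fluid + two tissue clusters)")
        if self.FN <= 0 or self.TN <= 0:
            raise InvalidParameterError("FN and TN must be positive")


@dataclass
class EnergyParams:
    """Parameters of the kernel graph-cut energy.

    lambda1 / lambda2: regional and boundary weights (1e12 / 1e8); their 1e4
        ratio makes the boundary term a tie-breaker at class boundaries.
    sigma: RBF width of the kernel regional term.
    sigma_boundary: Gaussian width of the boundary (n-link) term.
    neighborhood: 4 or 8.
    swap_tlinks: exchange the terminal attachment of the regional penalties
        (the conventional orientation ties R_p('B') to the object terminal).
    mu_source: 'seeds' takes the class centers as means of the seed pixels'
        T values; 'centers' uses the k-means cluster centers.
    damping_floor: when True (default) the indeterminacy damping of the
        larger regional penalty is floored at the smaller one, so noise can
        neutralize a pixel's regional commitment but never invert it; False
        applies the bare (1 - I) multiplier.
    """

    lambda1: float = 1e12
    lambda2: float = 1e8
    sigma: float = 0.1
    sigma_boundary: float = 0.1
    neighborhood: int = 8
    swap_tlinks: bool = False
    mu_source: str = "seeds"
    damping_floor: bool = True

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 < 0:
            raise InvalidParameterError("lambda1 must be > 0 and lambda2 >= 0")
        if self.sigma <= 0 or self.sigma_boundary <= 0:
            raise InvalidParameterError("sigma values must be positive")
        if self.neighborhood not in (4, 8):
            raise InvalidParameterError("neighborhood must be 4 or 8")
        if self.mu_source not in ("seeds", "centers"):
            raise InvalidParameterError("mu_source must be 'seeds' or 'centers'")


@dataclass
class PipelineConfig:
    """Full pipeline configuration: one sub-config per stage plus the
    post-filter area threshold and the voxel geometry for volume estimates.

    Voxel defaults correspond to Spectralis-style scans: 3.87 um/px axial,
    5.88 um/px lateral, 120 um between B-scans.
    """

    ns: NSParams = field(default_factory=NSParams)
    layers: LayerParams = field(default_factory=LayerParams)
    seeds: SeedParams = field(default_factory=SeedParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    min_region_px: int = 40
    px_height_mm: float = 3.87e-3
    px_width_mm: float = 5.88e-3
    slice_spacing_mm: float = 0.12

    def __post_init__(self) -> None:
        if self.min_region_px < 0:
            raise InvalidParameterError("min_region_px must be >= 0")
        for name in ("px_height_mm", "px_width_mm", "slice_spacing_mm"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d or {})
        kwargs: dict[str, Any] = {}
        for key, sub in (("ns", NSParams), ("layers", LayerParams),
                         ("seeds", SeedParams), ("energy", EnergyParams)):
            if key in d:
                kwargs[key] = sub(**d.pop(key))
        kwargs.update(d.pop("pipeline", {}))
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
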