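"""Synthetic OCT-like B-scans and volumes with exact ground truth.

The phantom emulates the statistical structure the segmentation method relies
on: a dark vitreous above a smooth ILM curve, bright retinal tissue, a thin
hyper-reflective RPE band, a darker choroid below, dark fluid pockets of the
three clinical types (intraretinal, subretinal, sub-RPE with an elevated RPE),
and multiplicative gamma speckle.  Ground truth (boundary curves and fluid
mask) is recorded before noise.

Band means on the normalized [0, 1] scale: background 0.05, tissue 0.55, RPE
band 0.85, choroid 0.25, fluid 0.08 — ordered background < fluid < choroid <
tissue < RPE band.  The speckle multiplier is Gamma(L, 1/L) with L = 4
(mean 1, intensity-preserving in expectation), the standard fully-developed
speckle surrogate for averaged OCT frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._exceptions import InvalidSpecError
from .layers import BoundaryCurve

__all__ = [
    "FluidBlob",
    "PhantomSpec",
    "PhantomTruth",
    "generate_bscan",
    "generate_volume",
    "make_spec",
    "PRESETS",
]

BAND_INTENSITIES = {
    "background": 0.05,
    "fluid": 0.08,
    "choroid": 0.25,
    "tissue": 0.55,
    "rpe": 0.85,
}


@dataclass
class FluidBlob:
    """One elliptical fluid pocket.

    ``kind``: intraretinal (inside the tissue), subretinal (a lens resting on
    the RPE band) or subrpe (dark interior of an RPE elevation; its geometry
    is carried by ``PhantomSpec.rpe_elevation``).
    """

    kind: str
    center_col: int
    center_row: int = 0           # ignored for subretinal/subrpe
    radius_row: float = 12.0
    radius_col: float = 20.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (160, 384)
    ilm_base: int = 40
    rpe_base: int = 115
    band_thickness: int = 8
    curve_amplitude: float = 2.0
    curve_wavelength: float = 900.0
    intensities: dict = field(default_factory=lambda: dict(BAND_INTENSITIES))
    fluid_blobs: list = field(default_factory=list)
    rpe_elevation: tuple | None = None    # (center_col, height, half_width)
    speckle_L: float | None = 4.0         # None disables speckle
    rng_seed: int = 0


@dataclass
class PhantomTruth:
    """A rendered phantom with its noise-free ground truth."""

    image: np.ndarray
    true_ilm: BoundaryCurve
    true_rpe: BoundaryCurve           # follows the (possibly elevated) RPE
    true_rpe_flat: BoundaryCurve      # the un-elevated base interface
    fluid_mask: np.ndarray
    spec: PhantomSpec = None

    @property
    def fluid_area(self) -> int:
        return int(self.fluid_mask.sum())


def _smooth_curve(base: float, n_cols: int, amplitude: float, wavelength: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Sum of two low-frequency sinusoids with random phases."""
    x = np.arange(n_cols, dtype=np.float64)
    rows = np.full(n_cols, float(base))
    for harmonic in (1.0, 2.0):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        rows += (amplitude / harmonic) * np.sin(2.0 * np.pi * harmonic * x
                                                / wavelength + phase)
    return rows


def generate_bscan(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom B-scan with exact truth (computed before noise)."""
    n_rows, n_cols = spec.shape
    rng = np.random.default_rng(spec.rng_seed)
    ints = spec.intensities

    ilm_rows = np.rint(_smooth_curve(spec.ilm_base, n_cols, spec.curve_amplitude,
                                     spec.curve_wavelength, rng))
    rpe_rows = np.rint(_smooth_curve(spec.rpe_base, n_cols, spec.curve_amplitude,
                                     spec.curve_wavelength, rng))
    if np.any(rpe_rows - ilm_rows < spec.band_thickness + 10):
        raise InvalidSpecError("ILM and RPE base curves are too close")
    if np.any(ilm_rows < 1) or np.any(rpe_rows > n_rows - 2):
        raise InvalidSpecError("layer curves leave the image")

    elevation = np.zeros(n_cols)
    if spec.rpe_elevation is not None:
        center, height, half_w = spec.rpe_elevation
        if height <= 0 or half_w <= 0:
            raise InvalidSpecError("elevation height and half-width must be positive")
        x = np.arange(n_cols, dtype=np.float64)
        elevation = np.maximum(0.0, height * (1.0 - np.abs(x - center) / half_w))
        if np.any(rpe_rows - elevation - spec.band_thickness <= ilm_rows + 5):
            raise InvalidSpecError("RPE elevation collides with the ILM")
        # under a detachment the fluid is bounded below by Bruch's membrane,
        # which runs straight between the detachment feet
        span = np.flatnonzero(elevation > 0)
        c0, c1 = int(span[0]), int(span[-1])
        rpe_rows[c0:c1 + 1] = np.rint(np.interp(np.arange(c0, c1 + 1),
                                                [c0, c1],
                                                [rpe_rows[c0], rpe_rows[c1]]))

    rpe_elev = rpe_rows - np.rint(elevation)
    band_top = rpe_elev - spec.band_thickness

    rows = np.arange(n_rows, dtype=np.float64)[:, None]
    img = np.full(spec.shape, ints["background"])
    img[(rows >= ilm_rows[None, :]) & (rows < band_top[None, :])] = ints["tissue"]
    img[(rows >= band_top[None, :]) & (rows < rpe_elev[None, :])] = ints["rpe"]
    # under a detachment the fluid rests on Bruch's membrane, which shows as
    # a thin hyper-reflective line at the base (rpe_rows - 1)
    subrpe = (rows >= rpe_elev[None, :]) & (rows < rpe_rows[None, :] - 1)
    img[subrpe] = ints["fluid"]
    bruch = (elevation[None, :] > 0) & (rows == rpe_rows[None, :] - 1) \
        & (rows >= rpe_elev[None, :])
    img[bruch] = ints["rpe"]
    img[rows >= rpe_rows[None, :]] = ints["choroid"]

    fluid_mask = subrpe.copy()
    cols = np.arange(n_cols, dtype=np.float64)[None, :]
    for blob in spec.fluid_blobs:
        if blob.kind == "intraretinal":
            rr, rc = blob.radius_row, blob.radius_col
            e = (((rows - blob.center_row) / rr) ** 2
                 + ((cols - blob.center_col) / rc) ** 2) <= 1.0
            inside = (rows >= ilm_rows[None, :] + 2) & (rows < band_top[None, :] - 2)
            if np.any(e & ~inside):
                raise InvalidSpecError(
                    f"intraretinal blob at col {blob.center_col} leaves the tissue band")
            blob_mask = e
        elif blob.kind == "subretinal":
            rr, rc = blob.radius_row, blob.radius_col
            u = (cols - blob.center_col) / rc
            depth = np.where(np.abs(u) <= 1.0, rr * np.sqrt(np.maximum(0.0, 1.0 - u ** 2)), 0.0)
            blob_mask = (rows >= band_top[None, :] - depth) & (rows < band_top[None, :]) \
                & (np.abs(u) <= 1.0)
            if np.any(blob_mask & (rows < ilm_rows[None, :] + 2)):
                raise InvalidSpecError(
                    f"subretinal blob at col {blob.center_col} reaches the ILM")
        elif blob.kind == "subrpe":
            continue  # geometry carried by spec.rpe_elevation
        else:
            raise InvalidSpecError(f"unknown blob kind {blob.kind!r}")
        img[blob_mask] = ints["fluid"]
        fluid_mask |= blob_mask

    clean = img.copy()
    if spec.speckle_L is not None:
        mult = rng.gamma(shape=spec.speckle_L, scale=1.0 / spec.speckle_L,
                         size=spec.shape)
        clean = np.clip(clean * mult, 0.0, 1.0)

    return PhantomTruth(
        image=clean,
        true_ilm=BoundaryCurve(ilm_rows, "ILM"),
        true_rpe=BoundaryCurve(rpe_elev, "RPE"),
        true_rpe_flat=BoundaryCurve(rpe_rows, "RPE_flattened"),
        fluid_mask=fluid_mask,
        spec=spec,
    )


def generate_volume(spec_base: PhantomSpec, n_slices: int,
                    blob_extent_slices: float = 3.0) -> list[PhantomTruth]:
    """Render a stack of phantoms whose blobs follow a spherical-cap profile.

    Blob radii (and the RPE elevation height) at slice offset d from the
    central slice scale with sqrt(1 - (d/extent)^2), so fluid appears in
    consecutive slices as in real pathology.
    """
    if n_slices < 1:
        raise InvalidSpecError("n_slices must be >= 1")
    center = (n_slices - 1) / 2.0
    truths = []
    for s in range(n_slices):
        d = (s - center) / max(blob_extent_slices, 1e-9)
        scale = float(np.sqrt(max(0.0, 1.0 - d ** 2)))
        blobs = []
        for blob in spec_base.fluid_blobs:
            if scale < 0.2:
                continue
            blobs.append(replace(blob, radius_row=blob.radius_row * scale,
                                 radius_col=blob.radius_col * scale))
        elev = spec_base.rpe_elevation
        if elev is not None:
            if scale < 0.2 or elev[1] * scale < 2.0:
                elev = None
            else:
                elev = (elev[0], float(np.rint(elev[1] * scale)), elev[2])
        spec = replace(spec_base, fluid_blobs=blobs, rpe_elevation=elev,
                       rng_seed=spec_base.rng_seed * 1009 + s)
        truths.append(generate_bscan(spec))
    return truths


def _mixed_blobs(rng: np.random.Generator, spec: PhantomSpec,
                 kinds: Sequence[str]) -> tuple[list, tuple | None]:
    """Place non-overlapping blobs of the requested kinds."""
    n_cols = spec.shape[1]
    tissue_top = spec.ilm_base + 6
    tissue_bottom = spec.rpe_base - spec.band_thickness - 6
    blobs: list[FluidBlob] = []
    elevation = None
    used: list[tuple[float, float]] = []

    def free_span(col: float, half: float) -> bool:
        return all(col + half < lo or col - half > hi for lo, hi in used)

    for kind in kinds:
        for _ in range(40):  # rejection sampling for non-overlap
            if kind == "intraretinal":
                rr = rng.uniform(8, 14)
                rc = rng.uniform(16, 30)
                col = rng.uniform(rc + 12, n_cols - rc - 12)
                row = rng.uniform(tissue_top + rr + 3, tissue_bottom - rr - 3)
                if free_span(col, rc + 6):
                    blobs.append(FluidBlob("intraretinal", int(col), int(row), rr, rc))
                    used.append((col - rc - 6, col + rc + 6))
                    break
            elif kind == "subretinal":
                rr = rng.uniform(10, 16)
                rc = rng.uniform(24, 40)
                col = rng.uniform(rc + 12, n_cols - rc - 12)
                if free_span(col, rc + 6):
                    blobs.append(FluidBlob("subretinal", int(col), 0, rr, rc))
                    used.append((col - rc - 6, col + rc + 6))
                    break
            elif kind == "subrpe":
                if elevation is not None:
                    break
                height = float(np.rint(rng.uniform(15, 24)))
                half_w = rng.uniform(35, 55)
                lo = max(160.0, half_w + 10)
                hi = min(float(n_cols) - half_w - 10, 224.0)
                col = rng.uniform(lo, hi)
                if free_span(col, half_w + 6):
                    elevation = (float(int(col)), height, float(int(half_w)))
                    used.append((col - half_w - 6, col + half_w + 6))
                    break
            else:
                raise InvalidSpecError(f"unknown fluid kind {kind!r}")
    return blobs, elevation


PRESETS = ("clean", "intraretinal", "subretinal", "subrpe", "mixed", "normal")


def make_spec(preset: str = "mixed", rng_seed: int = 0,
              shape: tuple[int, int] = (160, 384),
              speckle_L: float | None = 4.0) -> PhantomSpec:
    """Build a randomized PhantomSpec for one of the named presets.

    ``clean`` — no fluid, no speckle; ``normal`` — speckle but no fluid;
    ``intraretinal``/``subretinal``/``subrpe`` — one blob of that type;
    ``mixed`` — one to three blobs of random types.
    """
    if preset not in PRESETS:
        raise InvalidSpecError(f"unknown preset {preset!r}; choose from {PRESETS}")
    rng = np.random.default_rng(rng_seed)
    spec = PhantomSpec(shape=shape, rng_seed=rng_seed,
                       speckle_L=None if preset == "clean" else speckle_L)
    if preset in ("clean", "normal"):
        return spec
    if preset == "mixed":
        kinds = list(rng.choice(["intraretinal", "subretinal", "subrpe"],
                                size=rng.integers(1, 4), replace=False))
    else:
        kinds = [preset]
    blobs, elevation = _mixed_blobs(rng, spec, kinds)
    return replace(spec, fluid_blobs=blobs, rpe_elevation=elevation)
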