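# Methods

This note documents the models and algorithmic choices behind `octfluid`:
what each stage computes, which parameters matter, what the synthetic
phantoms do and do not emulate, and where the design was genuinely open.

## Neutrosophic transforms

Both transforms represent a B-scan by a fluid-membership plane `T` and an
indeterminacy plane `I`, with all segmentation applied to `T`. The
membership is an *inverted* normalized intensity so that dark structures
(fluid, vitreous) score near 1 and hyper-reflective structures (RPE band,
hard exudates) near 0 — the latter therefore cannot masquerade as fluid.

**Layered-structure transform** (`to_ns_proposed`, used by the pipeline).
`T = 1 − (g − g_min)/(g_max − g_min)` on the raw intensities. Indeterminacy
is the minimum absolute deviation between `T` and its filtering with 10
oriented Gaussian kernels (base extent 3×9 px, σ = extent/6, orientations
0°–162° in 18° steps): a pixel sitting on a (near-)horizontal layer boundary
is reproduced almost exactly by the horizontal kernel and receives low `I`,
while isolated speckle deviates from *every* oriented average and receives
high `I`. Pixels with `I ≥ λ` (default λ = 0.7) are replaced by the filter
response that deviates the most (λ-correction, the strongest plausible
smoothing for that pixel), and the filter/indeterminacy/correction loop
repeats until the Shannon entropy of `I` (100 bins over [0,1], natural log)
changes by less than 10⁻³, capped at 50 iterations.

Building `T` from the raw intensity rather than a windowed local mean is a
deliberate choice: an 11×11 pre-average smears every layer edge over half a
window, which measurably biases the ILM shortest path ~4 px into the
vitreous and leaves a wide high-membership transition strip inside the
retained band. The whole point of the oriented-filter indeterminacy is to
handle noise *without* isotropic smoothing; `NSParams.proposed_local_mean`
restores the windowed variant for comparison.

**Conventional transform** (`to_ns_conventional`, used for seeding).
`T` from the 11×11 local-mean image; `I` as the normalized deviation of each
pixel from its windowed mean; α-mean (replace the membership of high-`I`
pixels by the windowed mean) and β-enhancement (S-shaped contrast sharpening
of high-`I` pixels) iterated under the same entropy criterion. α = β = 0.85
and the 11×11 window are conventional values, exposed in the config. The
windowed `T` is exactly what the coarse k-means partition needs: speckle is
averaged down so the clusters align with anatomical tiers.

Degenerate (constant) images raise an error in both transforms: no
normalization, and no meaningful segmentation, exists.

## Layer segmentation

Boundaries are minimum-cost paths on the 8-connected pixel graph from a
virtual source (all pixels of column 0) to a virtual sink (last column),
computed with Dijkstra's algorithm on sparse matrices. The weight equations
are evaluated on the *reflectivity* image `refl = 1 − T` (dark vitreous
above the ILM, bright tissue below), the orientation in which their
penalty/reward terms act as designed: `mean(R)` above a candidate ILM node
is small only over the dark background, and `mean(U)` below a candidate RPE
node distinguishes bright choroid (true path) from dark fluid (decoy path
above a sub-retinal pocket), with `β·D = 0.004 ×` depth-below-ILM breaking
the remaining ties toward the deeper, anatomically correct boundary.
Defaults `R = 40`, `U = 10` px.

The vertical gradient is the response to the kernel `(−2, 0, 2)ᵀ` (extremes
±2·MaxG with MaxG = 1 on normalized planes). For gradient computation only,
the reflectivity is pre-averaged with the *horizontal* oriented kernel of
the filter bank — speckle is suppressed along the layers while the
near-horizontal boundaries stay sharp. The R/U column means intentionally
use the unsmoothed reflectivity: computing them on the blurred image lets
the U-window skim the smeared tail of the bright RPE band and biases the
path one row outward. Edge weights are clipped below at 10⁻⁶ so Dijkstra's
nonnegativity assumption holds even when the reward terms dominate. The RPE
search is restricted to rows at least 5 below the ILM so the two paths
cannot collapse onto each other.

**RPE flattening.** A detachment shows as an upward bump of the RPE path.
With rows increasing downward, the apex is the index maximizing the
windowed second difference `Σ_{j≤W} [RPE(i−j) + RPE(i+j) − 2·RPE(i)]`
(W = 150). (The naive one-sided sum `Σ [RPE(i)−RPE(i−j)] + [RPE(i+j)−RPE(i)]`
telescopes into an antisymmetric slope measure that vanishes at a symmetric
apex and cannot serve as a curvature.) From the apex the algorithm walks
left/right while the curve remains above the point `Tr = 40` columns further
out, then replaces the span by the straight chord between the feet. Three
numerical safeguards matter in the presence of ±1 px path noise: the
curvature and the walks run on a 5-column median-smoothed copy of the curve
(noise otherwise stops the walks early on the slope); each chord endpoint is
the deepest row within 5 columns outside its foot; and the interpolated
chord is discretized to the *deeper* pixel row (ceil), since the continuous
boundary passes between pixels and the detachment interior must stay above
it. Flattening is gated on the apex curvature exceeding `min_curvature`
(default 1000 px·columns — an order of magnitude above anatomical
undulation, an order below real detachments) and repeats up to 5 times so
multiple detachments are each flattened; a flat or gently undulating curve
is returned untouched.

## Automated seeding

The conventional-NS membership plane of the *whole scan* is partitioned by
scalar k-means (k = 7, k-means++ with 10 restarts, fixed RNG seed), clusters
ranked by descending center. Fluid seeds (500) come from the top two
clusters — the second guards against scans whose brightest-membership
cluster is pure vitreous background. Tissue seeds (700) come from the
remaining five clusters with proportions `p_i = 1/2^(i−2)` normalized over
i = 3..k, rounded half-up with the residue assigned to cluster 3; each
cluster thereby receives more seeds than all farther-from-fluid clusters
combined, concentrating the background model on the *dark* tissue that the
cut would otherwise mistake for fluid. Whole-scan seeding is what makes
fluid-free scans come out empty: their fluid clusters are the vitreous and
choroid, the cut labels those regions as "fluid", and the band clip discards
them. `SeedParams.restrict_to_band` confines seeding to the ILM–RPE band
instead (useful when the layer curves are trusted and background is absent).

## Kernel graph-cut energy

Labels minimize `E(A) = λ₁·Σ_p R_p(A_p) + λ₂·Σ_{pq} B_pq·[A_p ≠ A_q]` over
the 8-neighborhood, with λ₁ = 10¹², λ₂ = 10⁸: the boundary term is a
tie-breaker at 10⁻⁴ of the regional scale. The regional penalty is the
RBF-kernel squared distance `R1_p = 2 − 2·exp(−(μ − t_p)²/2σ²)`, σ = 0.1,
with class centers μ_O/μ_B the mean membership of the fluid/tissue seeds
(cluster centers are a config alternative). Indeterminacy damps the larger
of the two penalties by `(1 − I_p)`, weakening a noisy pixel's strongest
terminal attachment; ties are left untouched.

The damping carries a floor: the damped penalty never drops below its
undamped competitor. Without it, any pixel far from *both* class centers
(both penalties saturated within ~10⁻⁴ of 2 — e.g. the bright RPE band,
whose membership is near 0) would have its exponentially thin preference
inverted by arbitrarily small indeterminacy, and the energy's global optimum
labels entire bright bands as fluid. The floor preserves the intended
mechanism — high-`I` pixels lose regional commitment and defer to the
boundary term — while never inverting the kernel evidence;
`EnergyParams.damping_floor=False` restores the bare multiplier.

The minimum is exact, not approximate: a two-terminal graph with t-links
`λ₁·R_p('B')` to the object terminal and `λ₁·R_p('O')` to the background
terminal (the conventional orientation; `swap_tlinks` flips it), n-links
`λ₂·B_pq` with `B_pq = exp(−(t_p−t_q)²/2σ_b²)/dist`, and hard seed
constraints with capacity `K` strictly above an upper bound on the min cut
(the cut value of the per-pixel threshold labeling). All pairwise terms are
nonnegative Potts, so the min cut is the global optimum. Max-flow runs
through scipy's Dinic implementation, which requires int32 capacities;
capacities are scaled so `K` — which also bounds the max-flow value — sits
just below 2³¹. The resulting quantization is ~10⁻⁹ relative on the
capacities, orders of magnitude below the energy gaps between labelings
(verified against exhaustive enumeration in the test suite). Empty fluid
seeds short-circuit to an all-background mask; empty tissue seeds are an
error.

## Pipeline and volumes

Per scan: layered-structure NS transform → layer segmentation on `T` →
seeding → min-cut → post-filter. The post-filter zeroes fluid outside rows
`[ILM, flattened RPE]` (inclusive) and removes 8-connected components with
area strictly below `min_region_px = 40`. Volumes stack per-slice masks;
fluid volume = voxel count × voxel size (defaults 3.87 µm axial × 5.88 µm
lateral × 120 µm slice spacing, ≈ 2.73·10⁻⁶ mm³/voxel); the largest
26-connected 3D component is reported alongside the total, covering both
readings of "fluid in consecutive slices". With a fixed seed the pipeline is
byte-deterministic.

## Phantoms

`PhantomSpec` renders 160×384 B-scans: smooth sinusoidal ILM and RPE curves
(amplitude 2 px), bands at background 0.05 / tissue 0.55 / RPE 0.85 (8 px
thick) / choroid 0.25, fluid 0.08, and multiplicative Gamma(L, 1/L) speckle
with L = 4 (mean 1, σ = 0.5 — heavier than typical frame-averaged clinical
scans, a deliberately hard setting). Intraretinal fluid is an ellipse in the
tissue; subretinal fluid a lens resting on the RPE band; sub-RPE fluid the
dark interior of a tent-shaped RPE elevation (height 15–24 px, half-width
35–55 px) above a straight base — under a detachment the base is Bruch's
membrane, rendered as a thin hyper-reflective line on which the fluid rests,
as in real detachment anatomy. Truth masks and curves are computed before
noise. Volumes scale blob radii and elevation height with a spherical-cap
profile across slices. Blob geometry (radii ~8–40 px at ~4–6 µm/px,
i.e. cysts and pockets of ~0.05–0.5 mm) was fixed once as representative of
exudative-AMD pathology.

What the phantoms do *not* emulate: vessel shadowing, hard exudates and
other hyper-reflective foci inside the retina, the 11 interior retinal
layers, intensity roll-off with depth, motion artifacts, and fluid with
partial-volume boundaries. Passing the phantom suite therefore demonstrates
the mechanics of the method — boundary steering, seeding, exact energy
minimization, normal-scan rejection — under controlled speckle, not clinical
performance; clinical accuracy must be established on annotated scans.

## Known limitations

- The ILM/RPE localization is exact only up to ±1 px under heavy speckle;
  the flattening compensates with its deeper-row discretization.
- A detachment whose apex lies within `flatten_W` columns of the scan edge
  cannot be flattened (the curvature window is undefined there).
- Fluid regions smaller than `min_region_px` are discarded by design; the
  same filter is what keeps fluid-free scans clean.
- The boundary term is effectively inert at the default λ₁/λ₂ ratio except
  at regional ties; raising λ₂ trades boundary smoothness against small-
  region sensitivity.
- All fluid is segmented as one class; no intraretinal/subretinal/sub-RPE
  subtyping is attempted.
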