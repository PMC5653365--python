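# octfluid

Fully automated segmentation of retinal fluid in spectral-domain OCT B-scans
of exudative (wet) AMD eyes — intraretinal cysts, subretinal fluid and
sub-RPE fluid under pigment epithelial detachments — with no user-drawn seeds
and no trained model.

OCT B-scans are noisy (multiplicative speckle) and fluid pockets share their
darkness and texture with the vitreous above the retina and the choroid below
it, which defeats plain intensity thresholding and makes classical
interactive graph cut both seed-hungry and noise-sensitive. This package
addresses those failure modes with four cooperating pieces:

1. **Neutrosophic (NS) transform.** Each scan is mapped to a membership plane
   `T` (inverted normalized intensity, so dark fluid scores high) and an
   indeterminacy plane `I`. `I(i,j) = min_k |T(i,j) − FI_k(i,j)|` over a bank
   of 10 elongated Gaussian filters rotated across 180°, so pixels on (near-)
   horizontal retinal layers are *not* marked as noise; pixels with
   `I ≥ λ = 0.7` are replaced by their most deviating filter response
   (λ-correction), iterated until the entropy of `I` stabilizes.
2. **Layer segmentation by graph shortest path.** The ILM and the RPE are
   extracted as minimum-cost left-to-right paths on the 8-connected pixel
   graph with edge weights
   `W = 4·MaxG − VerGrad(p₁) − VerGrad(p₂) + 2·mean(R)` (ILM) and
   `W = 4·MaxG − VerGrad(p₁) − VerGrad(p₂) − mean(U) − β·D` (RPE),
   where `R` / `U` are short pixel columns above/below the node and `D` is
   the depth below the ILM — the terms that keep the ILM path out of bright
   inner layers and steer the RPE path *under* sub-retinal fluid. Elevated
   RPE (detachments) is flattened by locating the apex of maximal windowed
   curvature, walking to the feet of the elevation and interpolating the base
   chord, so that all fluid lies between the ILM and the flattened RPE.
3. **Automated seeding.** A conventional NS transform plus scalar k-means
   (k = 7) coarsely partitions the scan; `FN = 500` fluid seeds are drawn
   from the two most fluid-like clusters and `TN = 700` tissue seeds from the
   rest with geometrically decaying proportions `p_i = 1/2^(i−2)`.
4. **Kernel graph cut.** Fluid/tissue labels minimize
   `E(A) = λ₁·Σ R_p(A_p) + λ₂·Σ B_pq·[A_p ≠ A_q]` with the RBF-kernel
   regional penalty `R1_p = 2 − 2·exp(−(μ_{A_p} − t_p)²/2σ²)` damped by
   `(1 − I_p)` on the larger side, solved exactly by max-flow/min-cut
   (λ₁ = 10¹², λ₂ = 10⁸, σ = 0.1). Segmented regions outside the
   ILM–flattened-RPE band or smaller than 40 px are discarded, which also
   makes fluid-free scans come out empty automatically.

A synthetic phantom generator (`octfluid.phantom`) renders layered B-scans —
dark vitreous, tissue, bright RPE band, choroid, the three fluid types, a
thin Bruch's-membrane line under detachments, gamma speckle — with exact
ground-truth curves and masks, so the whole pipeline is testable without any
clinical data.

## Worked example

```python
import octfluid as of

truth = of.generate_bscan(of.make_spec("mixed", rng_seed=3))   # phantom + truth
res = of.segment_bscan(truth.image, rng_seed=3)                # full pipeline
rep = of.evaluate_mask(res.mask, truth.fluid_mask)

print(f"true fluid px : {truth.fluid_area}")
print(f"found fluid px: {res.fluid_px}")
print(f"dice={rep.dice:.3f}  sensitivity={rep.sensitivity:.3f}  precision={rep.precision:.3f}")
print(f"ILM MAE  = {of.boundary_mae(res.ilm, truth.true_ilm):.2f} px")
print(f"RPE MAE  = {of.boundary_mae(res.rpe_flat, truth.true_rpe_flat):.2f} px")
```

prints

```
true fluid px : 1234
found fluid px: 1231
dice=0.983  sensitivity=0.981  precision=0.984
ILM MAE  = 0.47 px
RPE MAE  = 0.46 px
```

i.e. on this phantom (a subretinal pocket plus an intraretinal cyst under
L = 4 speckle) the pipeline recovers 98% of the fluid area with sub-pixel
layer-boundary accuracy. `res` also carries the boundary curves, the seed
sets and the NS planes for inspection.

The same steps are available from the shell:

```
octfluid make-phantom --preset mixed --out ph/ --seed 3
octfluid segment-bscan --input ph/image.tiff --out mask.png --seed 3
octfluid segment-volume --input slices/ --pattern "*.png" --out out/
octfluid evaluate --pred out/ --truth truth/ --out report.json
```

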