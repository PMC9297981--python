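# Methods

This note records the models implemented by `cbctshade`, the assumptions
behind them, the parameters that matter, and what the synthetic experiments
do and do not establish.

## Problem setting

In-room cone-beam CT (CBCT) with a fixed, narrow field of view (FOV) of
208 mm suffers two coupled artifact families when imaging the pelvis:
scatter-induced cupping (the object centre reconstructs too dark) and
truncation artifacts (the body extends beyond the detector, producing a
bright band at the FOV edge; the common remedy, extrapolating the cut-off
projections before ramp filtering, trades the bright band for a global
lowering of grey values). Both corrupt the Hounsfield-unit (HU) scale and
hinder quantitative use. The package implements an image-domain correction:
a U-Net maps corrupted axial CBCT slices to CT-like slices, trained in two
stages — end-to-end on synthetic CBCT simulated from CT-like volumes, then
fine-tuning of only the deepest symmetric blocks on target-domain data.

## Digital pelvis phantoms

`phantom.generate_phantom` builds an elliptic body (anterior–posterior
extent 68% of the lateral width) with a 10-mm subcutaneous fat layer over a
muscle background, two femoral heads of spongy bone in a 2.5-mm cortical
shell, an anterior bladder, a central CTV, and a posterior rectum tube whose
lumen receives a seeded air pocket with configurable probability. Voxel HU =
tissue nominal + seeded Gaussian texture; air is exactly −1000 HU. Nominal
values (fat −100, muscle +45, bladder +15, spongy bone +300, cortical bone
+700, CTV +50 HU; texture SD 10–20 HU) are standard radiology ranges and are
configuration, not claims. Pelvis width is the controlled variable
(250–400 mm by default): widths above ~208 mm exceed the FOV and produce
truncation whose severity grows with width.

What the phantoms emulate: tissue contrast, HU statistics per region,
variable truncation severity, CT/CBCT air-pocket mismatch scenarios. What
they do not: realistic anatomy, deformation, metal, table/couch structures.
A green test on phantoms establishes that the pipeline corrects the
simulated physics; it cannot establish clinical image quality.

## CBCT simulation

Per axial slice (the central cone-beam plane is exactly a fan beam, and
training/evaluation are slice-based; cone-angle effects are out of scope):

1. **HU → attenuation.** CTμ = (HU + 1000) / 2¹⁶ per voxel, clipped below
   −1000 HU. Any monotone linear map would be equivalent up to the inverse
   applied after reconstruction; this scaling keeps projections in a
   numerically convenient range.
2. **Fan-beam projection.** Ray-driven line integrals from the source to
   each active detector-bin centre (source–isocenter 1172 mm,
   source–detector 1672 mm, 220° arc, 500 views full scale, 0.388-mm bins);
   bilinear sampling at 0.5 × voxel steps (numba kernels). The detector is
   collimated so the FOV diameter at the isocenter is 208 mm
   (active width ≈ 296.7 mm); truncation is emergent, not painted on.
3. **Physics corruption** in intensity space (I₀ = 1):
   beam hardening p → p^(1/f), f = 1.005 (compressive, identity at p = 1);
   scatter S = sf · g · smoothσ(I) with sf = 0.001, gain g = 25 and a
   σ = 300 mm Gaussian along the detector; Gaussian intensity noise,
   SD = 0.001; intensities floored at 10⁻⁶ before re-log. (0, 1, 0) is an
   exact identity.

   The scatter operator deserves a note. The kernel must be broad relative
   to the detector: a kernel comparable to the object makes the scatter term
   track the primary locally, so the log-domain error flattens across the
   shadow and reconstructs rim-weighted — the opposite of cupping. With
   σ = 300 mm the scatter background is genuinely low-frequency and the
   classic mechanism operates: high-attenuation central rays are inflated
   relatively more, the centre reconstructs dark, and the deficit deepens
   monotonically with the scatter factor. The gain is fixed once so that
   the default factor yields scatter-to-primary ratios of order 0.5–1 in a
   200-mm body shadow and uncorrected ("Base") HU errors on the 150-HU
   scale. Both constants are configuration with documented defaults; the
   operator is a parametric stand-in, not a scatter simulation.
4. **Truncation handling.** Rows whose edge value exceeds 0.02 attenuation
   are extended on that side by 30% of the active width with a mirrored,
   cosine-tapered rolloff (mirror about the edge sample, so the extension is
   continuous at the edge and reaches exactly zero). The extension
   participates in ramp filtering only; backprojection uses the measured
   support. This reproduces the known behaviour of this correction family:
   the bright band is suppressed at the price of a radially growing
   lowering of grey values.
5. **Short-scan FBP.** Rebinning to the virtual detector at the isocenter,
   cosine pre-weighting, generalized Parker weights for a 220° arc
   (conjugate rays' weights sum to 1; verified property), Ram-Lak filtering
   with cosine apodization (default on), distance-weighted backprojection,
   inversion of the attenuation map, −1000 HU outside the FOV circle. With
   physics off and no truncation, a 0-HU disk reconstructs with interior
   mean within a few HU and RMSE ≈ 1 HU at 500 views.

### Geometry notes

Cupping measurements need care in this geometry. For a body much wider than
the FOV, every detected ray crosses a comparable path length, so
differential scatter cupping *inside the FOV* is intrinsically small and is
confounded by the truncation bright band (uncorrected) or by the
truncation-correction lowering (corrected). The cupping experiments in the
test suite therefore use the widest body the FOV fully sees (200 mm), where
chord lengths genuinely vary and the truncation stage is a verified
pass-through.

## Network

A symmetric encoder/decoder for 256×256 single-channel slices in [0, 1].
Processing block: conv3×3 → ReLU → BN, dropout (rate 0.10), conv3×3 → ReLU
→ BN. Contracting blocks (widths 16-32-64-128 for the reference net) are
each followed by 2×2 max pooling; expanding blocks (128-64-32-16) are each
followed by a channel-preserving kernel-2/stride-2 transpose convolution,
after which the matching-resolution contracting feature map is concatenated.
A final 1×1 convolution with sigmoid produces the output slice.

The reference 4-block/16-filter configuration counts **919,777** trainable
parameters (conv + transpose-conv weights and biases, BN scale/shift). The
published figure for this architecture is 919,177; an exhaustive enumeration
of standard structural variants (transpose kernel and channel conventions,
final-conv kernel, bottleneck arrangement, bias/BN placements) produced no
standard construction matching it exactly, so the package freezes the
variant closest to the published description and count (+600 parameters,
0.065%) and documents the discrepancy rather than absorbing it silently.

Fine-tune scopes pair blocks symmetrically by depth: scope 1 retrains the
two deepest (128-wide) blocks and the transpose convolution between them;
scope 2 adds the 64-wide pair. Frozen blocks are strictly inert: no
optimizer updates and no batch-norm statistics updates, so their weights are
bit-identical before and after fine-tuning (tested).

## Training

MAE loss on randomly augmented 128×128 patches (shared crop, k·90°
rotation, horizontal flip for input and label), Adam with learning rate
0.001, β₁ = 0.9, β₂ = 0.999, batch 8. Because augmentation generates fresh
patches, an epoch is a configurable number of optimizer steps
(`steps_per_epoch`), not a fixed pass over the data. Validation (MAE, SSIM,
PSNR) runs per epoch on full, un-augmented slices — the deployment
condition — and the returned checkpoint is the epoch with maximum
validation SSIM. Gradients are clipped to a global L2 norm of 1.0; without
clipping the desk-scale configuration occasionally diverges (saturated
sigmoid outputs whose SSIM can still look acceptable, which would poison the
SSIM-based checkpoint). Epoch budgets are artifact choices (the source
protocol does not state them): defaults are 50 pretrain / 30 fine-tune
epochs, reduced in the desk-scale demonstration to 10/5 (plus a 15-epoch
noFT baseline) at 15 steps per epoch.

Protocols: `noFT` trains a fresh network on the target data only; `FTx`
pretrains end-to-end on the synthetic set (the Synth model), then retrains
only the x deepest pairs on the target set. The LOO-CV harness produces one
fold per volume pair, fine-tunes on the remainder, and reports per-fold
median PSNR/SSIM/MAE for Base (the uncorrected input), noFT and FTx.

## Metrics

PSNR and SSIM are computed on the normalized [0, 1] scale (peak/data range
1.0; SSIM: Gaussian 11×11 window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, via
scikit-image, cross-checked in the tests against an independent
definitional implementation to 10⁻⁶). MAE is reported in HU after exact
denormalization (HU = 4100·x − 1000). Voxels that are air (< −300 HU,
configurable) in exactly one of the two volumes are excluded from HU
comparisons — the air-pocket mismatch rule. ROI analysis places seeded,
non-overlapping 8×8×8 cubes fully inside a labeled tissue and compares mean
HU per cube; CNR is signed, (μ_fg − μ_bg)/pooled SD (background-only SD
available as an option). Per-volume summaries are slice-wise medians and
IQRs.

## Desk-scale demonstration

`pipeline.run_demo` (also `cbctshade demo`) generates 12 pretraining and 6
target phantoms (widths 250–340 mm, 4 slices each), simulates CBCT with a
reduced geometry (200 views, 0.776-mm bins — same distances, arc and FOV),
trains a 2-block/8-filter network with the FT2 and noFT protocols (~30
epochs total), and evaluates held-out target phantoms. With seed 1 this
reproduces the qualitative ordering of the full-scale method: Base is worst
on every metric and the corrected outputs recover most of the HU error.
Runtime is a few minutes on one CPU. The reduced scale preserves the
experiment's structure, not its clinical numbers; the full-scale clinical
results are out of reach by design.

## Known limitations

- 2D fan-beam per slice; no cone-angle effects, no 3D (FDK) reconstruction.
- The physics corruption is parametric and detector-domain; it cannot see
  scattered flux originating outside the detector's shadow, so effective
  scatter differs between truncated and untruncated bodies.
- No ring artifacts, detector lag, or polychromatic spectra.
- The numpy training engine is CPU-bound and meant for reduced networks;
  the full 919k-parameter network builds and runs forward passes, but
  full-scale training is not a supported workflow.
- Anatomical realism of the phantoms is deliberately coarse.
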