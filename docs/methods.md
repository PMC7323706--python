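# Methods

## Signal model and tensor estimation

Each voxel is modelled with the mono-exponential (Gaussian-diffusion) DTI
signal `S_i = S0·exp(−b_i g_iᵀ D g_i)`, `D` symmetric 3×3 in mm²/s. Taking
logs makes the model linear in `[ln S0, dxx, dyy, dzz, dxy, dxz, dyz]`; the
default estimator is ordinary least squares on log signals, with one-pass
weighted least squares (weights = squared predicted signals) available as
`method="wls"`. The design matrix row is
`[1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz]`; a rank check
rejects ill-posed schemes and names the unresolvable columns.

Numerical policies:

- **Nonpositive signals** are clamped to `1e-6 × S0_estimate` before the
  log (the per-voxel S0 estimate is the mean positive b=0 signal, falling
  back to the largest positive signal). The clamp count is recorded per
  voxel; a voxel with no positive signal at all is masked with NaN
  sentinels rather than fit.
- **Negative eigenvalues** (possible under noise) are clamped to 0 before
  shape metrics are computed, with a per-voxel flag, so all metrics stay
  within [0, 1]. The unclamped values are kept for diagnostics.
- **Eigenvalue ordering and vector signs**: eigenvalues descending;
  each eigenvector's largest-magnitude component is made positive, so
  stored maps are reproducible bit for bit.
- **Degenerate voxels** (trace ≤ 0 after clamping) carry NaN in every
  shape metric and are excluded from ROI means; NaN is also the on-disk
  sentinel in metric maps.

## Shape metrics

FA follows the usual normalised eigenvalue-dispersion formula; the Westin
decomposition uses `C_L=(λ1−λ2)/trace`, `C_P=2(λ2−λ3)/trace`,
`C_S=3λ3/trace` with `trace = λ1+λ2+λ3`. Only this trace definition makes
the three ratios sum to one, which the package treats as a defining
invariant (enforced to 1e-12 in tests). The inverse map
`λ3 = C_S·trace/3; λ2 = λ3 + C_P·trace/2; λ1 = C_L·trace + λ2` converts a
shape triple plus trace back to eigenvalues. Published triples are rounded
to 2–3 decimals and may sum to 0.99–1.01; sums within ±0.02 of 1 are
renormalised by division, larger deviations are rejected as inconsistent.

The shape triangle is a barycentric embedding of (C_L, C_P, C_S) with the
linear corner at (0,0), planar at (1,0) and spherical at the apex
(0.5, √3/2); it is affine and invertible on the simplex. Published plots of
this kind do not fix an axis convention, so this one is the package's own
and is used consistently.

## The phantom

The generator emulates the study design this package targets: ex-vivo
mouse brains and lumbar spinal cords at 200 µm isotropic resolution, one
b=0 volume plus 20 directions at b = 1000 s/mm². The 20 directions are not
published; the package ships a fixed electrostatic-repulsion set
(`DIRECTIONS_20`, antipodal Coulomb energy minimised) so every dataset is
reproducible across releases.

Geometries are deliberately stylised — an ellipsoidal "brain" with a
cortical shell, two hippocampal blobs, a left–right callosal strip and two
rostro-caudal corticospinal columns; a spinal-cord cylinder with inner
gray matter, anterior-horn wedges, and a white-matter annulus partitioned
into anterior/lateral/posterior funiculi. The quantity under test is
shape-metric recovery per labelled region, not anatomical fidelity.

Each structure × group gets a ground-truth (C_L, C_P, C_S) target equal to
the published group mean; the inverse map converts it to eigenvalues at
trace 1.5×10⁻³ mm²/s (MD 0.5×10⁻³, plausible for fixed tissue at room
temperature — no diffusivities are published, and shape metrics are
trace-invariant, so targets are unaffected). White-matter principal axes
follow the tract direction with von Mises–Fisher dispersion (κ = 100);
gray-matter orientations are uniform on the sphere. The anterior funiculus
and anterior horn have published triples only for WT and P120; their P80
entries fall back to the parent SC_wm / SC_gm triples, which preserves the
monotone WT→P80→P120 ordering. The lateral and posterior funiculi use the
SC_wm triples throughout.

Noise is Rician: `S_noisy = sqrt((S+n1)² + n2²)`, `n1,n2 ~ N(0, σ)` with
`σ = S0/snr` (Gaussian available for debugging). S0 is 1000 a.u. in
tissue and 50 a.u. (air-like) in the background, so background masking is
exercised; the default mask drops voxels whose mean b0 signal is below
10 % of the robust (99.5th-percentile) b0 maximum. One master seed spawns
per-stage child seeds (geometry, orientations, noise) via
`numpy.random.SeedSequence`, making every dataset bit-reproducible.

Crossing fibres are modelled as a two-compartment mixture
`S = S0[(1−f)e^{−b gᵀD_a g} + f e^{−b gᵀD_b g}]` with `D_b` the same shape
rotated by the crossing angle. The default study specs keep `f = 0`: the
shape targets are defined for the single-tensor ground truth, and the
mixture is a mechanism study (how crossing spherises a single-tensor fit),
exercised by the `crossing-sweep` command. An opt-in preset assigns
qualitative fractions (callosum 0.20 > corticospinal ≈ funiculi 0.05),
reflecting the relative prevalence of crossing axon populations, not a
measured value.

## Group statistics

ROI means are computed per subject over non-sentinel voxels (metrics
averaged voxelwise, not derived from a mean tensor — which is why a
group's mean FA and its mean shape triple need not be exactly algebraically
consistent); group statistics are then taken across subjects (n = 4 per
group in the emulated design, mean ± SEM). Comparisons: one-way ANOVA with
Tukey HSD post-hoc, replicated by Mann–Whitney U (exact where there are no
ties), α = 0.05, no correction across structures/metrics beyond Tukey
within each ANOVA. Percent change versus wild type is rounded half away
from zero to integer percent. Contrasts that cannot be computed (fewer
than two subjects in a group) are flagged, not dropped. A composite SC_wm
ROI (union of the three funiculi) is reported alongside the painted
labels.

## What passing tests show — and what they do not

The phantom shares the real data's acquisition geometry, noise family and
group design, but not its anatomy, partial-volume mixing, fixation
gradients, B1 inhomogeneity or manual segmentation variability. Recovery
results therefore validate the estimator and pipeline, not the biology.

At the study's conditions (SNR 30, b = 1000, 21 measurements) the
single-tensor fit carries the well-known eigenvalue-repulsion bias: sorting
noisy eigenvalues inflates λ1−λ2 and deflates λ3, biasing C_L/C_P up and
C_S down, most strongly where eigenvalues are nearly degenerate. The
recovery test quantifies this: white-matter triples come back well within
±0.02, but for the most spherical gray-matter targets (C_S = 0.88) the
C_S bias reaches ≈ −0.033, just outside the ±0.03 gray-matter band that
test asserts. The bias is a property of the estimator at this design, not
a seed artefact (weighted least squares does not reduce it); it cancels in
group *contrasts*, which is why every directional disease effect and
significance result still reproduces.

Problem sizes: the simulated study uses 48³ grids, two geometries per
subject, 4 subjects per group × 3 groups — small enough for the whole
suite to run in well under a minute on one core while leaving every ROI
with hundreds to thousands of voxels.

## Known limitations

- Gaussian (single-tensor) diffusion only; no kurtosis or
  multi-compartment models beyond the two-tensor crossing mixture, no
  tractography, no registration or atlas segmentation.
- The published percent changes that are inconsistent with their own
  printed means (several lumbar-funiculus and anterior-horn cells) are
  excluded from exact-reproduction tests rather than reconciled by
  guesswork.
- FSL-dialect bval/bvec in the image frame only; NIfTI-1 only (no DICOM
  or vendor raw formats).
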