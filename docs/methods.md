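# Methods

This note records the quantitative model behind `zeonco`, the parameter
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions that affect results.

## 1. Imaging model and segmentation

A larva image is a 3D voxel stack `(z, y, x)` of fluorescence intensities
with anisotropic voxel size in µm (axial step typically coarser than
lateral). Segmentation proceeds as:

1. **Background estimate** — the median intensity of the whole stack. The
   tumor occupies a small fraction of the volume, so the median is robust to
   foreground.
2. **Threshold** — Otsu's method (scikit-image) by default, or a fixed
   threshold. A threshold at or below background triggers a warning, since it
   means the stack has no separable foreground.
3. **Eye exclusion** — the larval eye is strongly autofluorescent and would
   otherwise be labeled as a tumor mass (and would out-rank a regressed
   primary by size). A sphere of radius 40 µm around the eye landmark is
   masked out *before* component labeling. The eye position comes from the
   plate-map annotation when present, otherwise from a bright-blob search in
   the rostral quarter of the stack; if neither works, segmentation errors
   out and asks for a manual annotation rather than guessing.
4. **Component labeling** — 26-connected components (`scipy.ndimage.label`
   with a full 3×3×3 structuring element). 26-connectivity is the right
   default for anisotropic fluorescence data, where a mass may touch
   diagonally across the coarse z-step.
5. **Size filter** — components under `min_voxels = 30` are dropped as noise
   specks. At the default 2 µm³ voxel this is 60 µm³, far below any
   biologically meaningful focus but above salt-and-pepper noise clusters.
6. **Primary classification** — the largest mass is the primary; size ties
   are broken by proximity to the injection reference point.

Mass volume is `voxel_count × dz·dy·dx`. Centroids are intensity-unweighted
voxel-center means, computed with `numpy.bincount` over the label image
(equivalent to `scipy.ndimage.center_of_mass` but much faster on large
stacks).

## 2. Per-larva quantities

- **Growth ratio** `R = V(tp2) / V(tp1)`. `V(tp1) ≤ 0` is an error (no valid
  baseline); a missing tp2 primary gives `R = 0` (complete regression).
- **Metastasis call** — true if any secondary mass at tp2 lies more than
  100 µm caudal (larger x) of the primary centroid. The 100 µm margin keeps
  lobes of an irregular primary from being miscalled as dissemination.
- **Dispersion** — disseminated focus positions are expressed relative to the
  eye centroid along the rostro-caudal (x) axis; the readout is the sample
  variance with `n − 1` in the denominator (0 for fewer than two foci).
  Cohort-level dispersion pools all foci across larvae before taking the
  variance, matching how dispersion is reported per condition rather than
  per animal.

## 3. Cohort statistics

The comparison path mirrors standard practice in the field:

1. **Outlier removal** — a univariate ROUT-style procedure at Q = 1%:
   residuals from the median are scaled by the RSDR (the 68.27th percentile
   of absolute residuals times `n/(n−1)`, a robust σ estimate), converted to
   two-sided t-tail p-values with `df = n − 1`, and flagged by a
   Benjamini–Hochberg step-up at `Q/100`. If the RSDR is zero (a majority of
   identical values) any nonzero residual is flagged; `n < 3` warns and
   removes nothing. This is a deliberate univariate adaptation of the
   regression-based original; on clean Normal data it flags well under 0.5
   points per 20-value dataset (measured in the test suite).
2. **Normality** — D'Agostino–Pearson omnibus test (`scipy.stats.normaltest`)
   per group. Groups with `n < 8` cannot be assessed and route to the
   nonparametric branch.
3. **Test selection** — two groups: unpaired t (both normal), Wilcoxon
   signed-rank (paired, non-normal) or Mann–Whitney U (unpaired,
   non-normal). Three or more groups: one-way ANOVA with Tukey HSD (or Šidák
   pairwise) when all groups pass normality, otherwise Kruskal–Wallis.
4. **Annotation** — strict thresholds: `*` p < 0.05, `**` p < 0.01,
   `***` p < 0.001, `****` p < 0.0001; boundary values do not round up.

The measured type-I error of the complete path (outlier removal + normality +
selection) on Normal null cohorts of n = 16 per group is 4.4% over 1000
simulations, confirming the pipeline does not inflate false positives.

## 4. Toxicology

Each larva is scored for death plus six morphological and functional
endpoints: body deformity, scoliosis, abnormal yolk size, heart edema,
abnormal heartbeat, and reduced movement (a dead larva carries no
morphological flags). At each concentration,
mortality% = dead/n and teratogenicity% = flagged survivors/n, both against
the full group size n. The NOEC is the highest tested concentration at
144 hpi with mortality *and* teratogenicity strictly below 20%; if the
lowest tested concentration already fails, the NOEC is reported as below the
tested range rather than as a number.

## 5. Synthetic generator

The generator is the validation substrate: every stack comes with exact
ground truth.

**What it emulates**

- An ellipsoidal primary (default semi-axes 20×25×25 µm) whose tp2 rendering
  scales each semi-axis by `g^(1/3)`, so the true volume ratio is exactly the
  drawn growth factor `g` (analytic oracle `4/3 π a b c`).
- Spherical disseminated foci (tp2 only) at Normal-distributed caudal
  offsets, giving a known dispersion variance.
- A bright eye sphere (intensity 200 vs tumor 100 vs background 10) as the
  anatomical landmark and as a realistic segmentation confounder.
- Additive Gaussian noise (σ = 5), clipped at zero.
- A dead-cell labeling model: a `dead_fraction` of tumor voxels keeps its
  signal with probability 0.957 (lipophilic dye) or 0.054 (genetic reporter),
  otherwise drops to background. This reproduces the direction and magnitude
  of the dye-vs-reporter volume bias.

**What it does not emulate** — point-spread blur, depth-dependent
attenuation, larva autofluorescence outside the eye, pigmentation, larva
curvature or growth between time points, and motion artifacts. Segmentation
accuracy on synthetic stacks is therefore an upper bound for real data; the
thresholding and component machinery is standard and carries over, but real
stacks may need the fixed-threshold mode and manual eye annotations.

**Default geometry** — a 60×200×400 voxel grid at (2, 1, 1) µm, i.e. a
120×200×400 µm field of view around the injection site. For dispersion
studies the `dispersion_dmso` preset uses a whole-larva field:
30×100×400 voxels at (2, 2, 12) µm, spanning 4.8 mm rostro-caudally so that
focus spreads with σ = 500 µm fit within ±4σ (truncation bias ≈ 0.5%).

**Determinism** — all randomness descends from one integer seed through
`numpy.random.SeedSequence`; per-larva seeds, render noise, focus placement
and labeling each use disjoint child streams, so regenerating any single
larva is independent of cohort order.

## 6. Numerical choices and limitations

- Voxel membership in a shape is decided at the voxel center; partial-volume
  voxels are all-or-nothing. Volume error from this discretization is a few
  percent at default resolution and falls with finer voxels (verified by a
  refinement test).
- Foci closer than about one diameter can merge into one component; the
  dispersion presets jitter foci in y and z to keep merge rates low (~3–4%
  of foci at defaults).
- The ROUT adaptation is univariate (location = median), not the
  regression-based original; it is validated against an exhaustive
  Benjamini–Hochberg enumeration on small inputs rather than against the
  original implementation.
- Problem sizes in the acceptance script (24 larvae per growth condition,
  200 larvae for incidence, 2000 foci for dispersion) were chosen so that
  Monte-Carlo error is small relative to the recovery tolerances while the
  full run stays under a few minutes.
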