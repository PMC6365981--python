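# Methods

## Random-effects pooling

Each published study contributes, per histological subtype, a reported
mean `m_i` and SD `sd_i` of one biomarker over `n_i` patients. The
within-study variance of the reported mean is taken as `v_i = sd_i²/n_i`
(the squared standard error; studies publish patient-level SDs without
stating a weighting, so standard practice is adopted). The
DerSimonian–Laird moment estimator gives

    Q  = Σ wᵢ (mᵢ − m_FE)²,          wᵢ = 1/vᵢ
    τ² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ))

and the pooled mean uses weights `1/(vᵢ+τ²)` with a normal-approximation
95 % CI (multiplier 1.96; no Knapp–Hartung correction, matching the
mean-and-CI presentation convention of the clinical literature). A group
with a single study returns that study's mean with τ² = 0. τ² is
estimated separately within each group by default; `tau2_share='modality'`
instead estimates one τ² from all of a parameter's studies and applies it
to every group (both readings of "variance pooled by subtype" are
defensible; per-group is the default because it never borrows
heterogeneity across unrelated subtypes). Groups totalling fewer than 2
patients after combination are omitted.

Subgroup comparison treats each pooled mean as an observation with known
SE: `Q_between = Σ w_g (μ_g − μ̂)²`, `w_g = se_g⁻²`, referred to χ²(G−1).
Pairwise contrasts use `z = (μ_a−μ_b)/√(se_a²+se_b²)` with the Tukey HSD
adjustment from the studentized range at `|z|·√2` with G groups and
infinite degrees of freedom — summary estimates carry no residual df, so
the large-sample range is the only defensible reference distribution.

The *target region* for a classification threshold is the open interval
between the nearer 95 % CI edges of the pooled low-grade and high-grade
estimates (for ADC the low-grade group sits higher; for nCBF lower); it is
flagged empty when the CIs overlap.

The bundled `data/table1.csv` transcribes the published study list — study
identifiers, measured parameters and per-study patient totals (14 studies;
290 ADC patients, 252 CBF patients) — but its per-subtype splits and all
mean/SD values are synthetic stand-ins on clinically realistic scales,
because the literature reports subtype-level point estimates only
graphically. Patient counts sum `n` over unique (study, subtype) pairs
within a parameter family, so a study reporting both ADC parameters is
counted once.

## CBF and ADC quantification

CBF uses the consensus single-compartment, single-PLD model

    CBF = 6000 λ ΔM exp(PLD/T₁bl) / (2 α T₁bl M₀ (1 − exp(−τ/T₁bl)))

with defaults λ = 0.9 ml/g, α = 0.85, T₁bl = 1.65 s, labelling duration
τ = 1.8 s, PLD = 1.5 s. ΔM is the already-averaged control−label
difference (repetition handling is upstream); background suppression is
not modelled beyond α. Voxels whose M₀ falls at or below 10⁻⁶ of M₀'s
99th-percentile maximum are marked NaN rather than divided through — a
robust floor keeps air voxels out while tolerating M₀ outliers. Negative
ΔM (hence negative CBF) is retained and logged; ROI maxima are unaffected.

ADC maps are either fitted from a two-point acquisition
(`ADC = ln(S₀/S_b)/b`, default b = 1000 s/mm²) or ingested from scanner
exports and rescaled to mm²/s. The `auto` rescaling picks the power-of-ten
factor moving the median (in-mask) value closest to 10⁻³ mm²/s on the log
axis, constrained to land in [10⁻⁴, 10⁻²]; a median equidistant between
two factors raises an ambiguity error rather than guessing.

## Square-ROI sampling

A nominal area A mm² becomes an h×w voxel footprint by rounding
`√A/spacing` per in-plane axis, floored at one voxel; the realised area is
logged since anisotropic spacing rarely hits A exactly. ROIs are planar
(single axial slice), matching clinical placement on axial images; a 3D
mode is deliberately not provided. All placements lying wholly inside the
tumour mask are enumerated in scan order (slice, row, column); block sums
come from per-slice integral images, so the exhaustive search over a
64×64×16 grid takes milliseconds. The reported ROI mean is recomputed
directly from the selected block so it is exactly consistent with the ROI
minimum. Ties break by scan order (first placement wins) and placements
containing non-finite voxels are disqualified, making every output
deterministic.

ADC and CBF ROIs are placed independently (lowest-mean and highest-mean
locations respectively; they need not overlap). ADC_ROI-min is the
minimum voxel of the ADC ROI; CBF_ROI-max is the maximum voxel of the CBF
ROI — the max-voxel reading keeps the automated measurement consistent
with the manual protocol's "maximum value from the CBF ROI".
Normalisation divides by mean grey-matter CBF on the axial slice at
`floor((first+last tumour slice)/2)` — the floor convention makes the
"mid-point" deterministic for even extents — with grey-matter voxels
overlapping the tumour excluded; if nothing is eligible an explicit error
invites a manual contralateral reference instead.

A note on the ROI-size sweep (25/50/75/100 mm²): the intuition that the
best min-mean can only rise with area is a theorem only when the smaller
footprint tiles the larger (a 4×4 block mean is an average of its 2×2
tile means). For non-tiling pairs — 4×4 into 5×5, i.e. 75 vs 100 mm² at
2 mm spacing — voxel noise can violate the ordering by a noise-scale
margin (observed ~0.7 % at SD 0.05×10⁻³ mm²/s). The monotonicity tests
therefore check the full chain on noiseless phantoms and the tiling chain
on noisy ones.

## Agreement statistics

ICC is the two-way random-effects, absolute-agreement, single-measure
form ICC(A,1), computed from the two-rater mean-squares decomposition —
appropriate when readers are interchangeable and systematic offsets should
count against agreement; a consistency form is available by flag. The
reproducibility coefficient is 1.96 × the sample (n−1) SD of the paired
differences. Percentage bias averages per-pair relative differences
`100(a−b)/b` against the gold-standard series; a pooled alternative
(`100·mean(a−b)/mean(b)`) is available since the literature's "%" is
ambiguous about the denominator. Bias is left unset for reader–reader
pairs.

## Grade classification

ROC analysis orients each biomarker by its clinical direction (low ADC /
high nCBF ⇒ high grade), computes AUC by the tie-corrected Mann–Whitney
rank formula, and selects the threshold maximising Youden's J over
midpoints between adjacent distinct observed values (accuracy as the
configurable alternative; remaining ties break toward higher accuracy,
then the smallest candidate). Midpoint placement generalises more
symmetrically than cutting at an observed value and makes ties
reproducible.

The flowchart applies the published thresholds — 0.95 × 10⁻³ mm²/s
(ADC_ROI-mean), 0.82 × 10⁻³ mm²/s (ADC_ROI-min), 1.45 (nCBF_ROI-max) —
with equality kept as low grade (the conservative, less aggressive call;
configurable). Diffuse midline glioma, whose ADC/CBF values mimic
low-grade tumours, is excluded from fitting and ROC by default and earns
a caveat flag in flowchart output.

The combined model is a standard two-predictor logistic regression
(grade ~ ADC + nCBF) fitted by IRLS from zero coefficients — fully
deterministic. ADC is rescaled to 10⁻³ mm²/s units internally for
conditioning and coefficients are reported on the input scale. Complete or
quasi-complete separation — which a cleanly separable cohort produces, and
which sends ML coefficients to infinity — is detected by a diverging
coefficient norm or a perfect training split without convergence, and
triggers a Jeffreys-prior (Firth) refit whose penalised estimates are
finite, keeping the p = 0.5 decision boundary well-defined; the model is
flagged `penalised`. Fewer than 3 records per class is refused.

## Synthetic data

Generators are pure functions of spec + seed (`numpy.random.default_rng`;
no global state), so reruns are bit-identical.

- **Study tables**: study means drawn as
  `μ_g + N(0, τ²) + N(0, sd²/n)` with n uniform in [5, 50] and reported SD
  a uniform 15–35 % of |μ_g| — the range of cohort sizes and relative SDs
  seen in the pooled literature. The CI-coverage simulation uses 9 studies
  per group (the per-parameter scale of that literature) and τ = 0.08×10⁻³;
  measured coverage is ≈91 %, slightly below nominal, which is the known
  small-k behaviour of the DL moment estimator, not an implementation
  artefact.
- **Phantoms**: 64×64×16 grids of 2×2×4 mm voxels (small enough for the
  full pipeline to run in seconds) holding an ellipsoidal tumour
  (background ADC 1.1×10⁻³ falling to a 0.6×10⁻³ cold focus; CBF 40 rising
  to a 120 hot focus), a grey-matter shell at 60 ml/100 g/min, M₀ = 1000
  a.u., and a ΔM volume built by algebraically inverting the CBF model so
  re-quantification reproduces the noiseless CBF map to machine precision.
  Optional i.i.d. Gaussian voxel noise is the only artefact modelled — no
  ghosting, distortion, or partial-volume structure — so passing tests
  demonstrate correctness of the measurement chain, not robustness to real
  acquisition artefacts.
- **Reader pairs**: `a = t(1+bias)+ε₁`, `b = t+ε₂` with independent
  Gaussian noise; for equal-noise readers RPC → 1.96·√2·σ, the identity
  the recovery tests exploit.
- **Cohorts**: 13 low- and 12 high-grade tumours by default — the scale of
  a single-centre validation cohort after excluding diffuse midline glioma
  — with class-conditional bivariate-normal (ADC, nCBF) at clinically
  plausible means and a mild negative within-class correlation. The
  synthetic phantom batches give the low-grade class a near-tissue ADC
  focus (1.05±0.05 ×10⁻³) and modest perfusion (50±8) and the high-grade
  class a markedly low ADC focus (0.62±0.06 ×10⁻³) and hot perfusion
  (115±12), emulating the separation the clinical cohorts show.

## Known limitations

- The bundled study table's subtype-level means are synthetic; pooled
  subtype estimates from it are demonstrations of the machinery, not
  reproductions of published point estimates (only the study/patient
  counts are faithful).
- Registration, segmentation, repetition-level ASL processing and
  molecular subtyping are out of scope; masks and co-registration are
  trusted as given.
- ICC confidence intervals and significance tests on bias are not
  computed.
- Training-set accuracy is reported for the logistic model; no
  cross-validation is performed (two predictors on ~25 cases would make
  such estimates noisy, and the clinical use is descriptive).
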