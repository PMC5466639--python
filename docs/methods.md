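# Methods

`polrpe` analyzes polarimetric multimodal retinal imaging for intraretinal
RPE migration in AMD. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Polarimetric model

Each A-scan sample is a two-channel complex field (E₁, E₂) from a
Jones-matrix (polarization-diverse) OCT. Stokes parameters are computed per
voxel and repeat as S₀ = |E₁|² + |E₂|², Q = |E₁|² − |E₂|²,
U = 2 Re(E₁E₂*), V = −2 Im(E₁E₂*). The V sign convention is fixed so that
(E₁, E₂) = (1, i)/√2 maps to V = +1; it is pinned by test.

The degree of polarization uniformity (DOPU) is the resultant length of
Stokes vectors pooled over a kernel of 3 transverse × 3 depth pixels within a
B-scan, across the 4 repeated acquisitions at each location (36 samples).
Two estimators are exposed:

- **Corrected (pipeline default)** — sum-then-normalize with additive-noise
  subtraction: DOPU = ‖(ΣQ̃, ΣU, ΣV)‖ / ΣS̃₀ with S̃₀ = S₀ − (n₁+n₂) and
  Q̃ = Q − (n₁−n₂). The noise energies n₁, n₂ are the mean per-channel
  energies of a signal-free vitreous band (`estimate_noise`). Subtracting
  mean noise energy from S₀ and Q removes the dominant additive-noise bias:
  noise inflates the denominator (and Q through the channel-energy
  difference) but contributes only zero-mean terms to U and V.
- **Uncorrected (classic)** — per-sample normalization (q,u,v) = (Q,U,V)/S₀
  followed by the norm of the mean. At low SNR the normalized vectors are
  randomized by noise, biasing DOPU downward; `dopu_bias_experiment`
  measures both estimators on a uniformly polarized target as a function of
  SNR (at SNR = 1 the classic estimator reads ≈ 0.37 while the corrected one
  stays within ≈ 0.05 of 1.0).

Numerical choices: the kernel is cropped at volume borders (no padding — no
fabricated data); the denominator is floored at ε = 10⁻¹² × max S₀; results
are clamped to [0, 1] with the pre-clamp overshoot count kept on the result
object. A voxel is **valid** only if its kernel's ΣS̃₀ exceeds
`validity_factor` (default 2.0) × kernel sample count × (n₁+n₂); noise-only
voxels would otherwise show spurious low DOPU and masquerade as
depolarization. Invalid voxels are flagged, never filled. With
`include_repeats=False` DOPU is computed per repeat and averaged (provided
for diagnostics; pooling is the default estimator).

## En-face products and PS-SLO

Minimum-DOPU projections take the per-column minimum over valid voxels,
either over the whole depth or restricted to z strictly anterior to the RPE
segmentation line (half-open: z < line). The anterior restriction removes
the physiologic depolarization of the RPE band and choroid, so intraretinal
depolarizing foci become the only low-DOPU structures. Composite B-scans
overlay DOPU < 0.8 (strict inequality; equality is not flagged) in red on
the log-compressed structural image, on valid pixels only. Intensity display
uses 20·log₁₀(S₀/max S₀) windowed over [−40, 0] dB — standard OCT display
practice.

The PS-SLO depolarized light image is the per-pixel minimum of the
crossed-detector frame over all input polarization angles: the
polarization-preserving crosstalk is sinusoidal in the input angle (period
π) and is removed by the minimum, while depolarized light returns an
angle-independent floor. Display rescale maps min→0 and max→255 with
rounding half away from zero; a constant raw image maps to all zeros.

## Lesion quantification

B-scans (log-compressed, repeat-averaged S₀) are binarized at Shanbhag's
automatic threshold — the gray level minimizing the absolute difference of
the fuzzy information measures of the background and foreground classes,
scanned exhaustively over the populated gray range; ties resolve to the
lowest level, with a 10⁻⁹ tolerance because the criterion is piecewise
constant between populated bins and plateau members differ only by float
round-off. Degenerate (single-level) histograms are rejected.

The study's manual HRF selection is replaced by two reproducible sources:
truth-guided selection (binary foreground ∩ ground-truth focus masks; used
for validation) and per-B-scan polygon ROI files (for user data). HRF volume
uses the printed voxel pitch product 11.7 × 23.5 × 3.6 µm³ per voxel — the
pitches are stored independently of grid counts (6.0 mm/512 = 11.72 µm, but
the printed 11.7 is what enters all volume arithmetic). PED volume follows
the Cavalieri principle: B-scan spacing (default the printed 23.5 µm) times
the summed cross-sectional areas between the elevated RPE line and its
baseline depth.

## Classification

Observer judgment is replaced by thresholded scores. Per focus:
minimum DOPU over its (valid) voxels, plus z-scores of the footprint mean
against a local background annulus (25–150 µm from the footprint, excluding
all focus footprints; computed via a distance transform in physical µm) for
the PS-SLO, NIR-AF and SW-AF images. A focus is labeled **migration** iff
min DOPU < 0.8 AND psslo_z ≥ 2 AND nir_z ≥ 2 AND sw_z ≥ 2. The z-thresholds
are surrogates for subjective "hyper-AF/depolarization present" readings; a
second grader for kappa experiments is realized by jittering the thresholds.

**Hard-exudate exclusion.** Connected low-DOPU components (26-connectivity)
of ≥ 200 voxels whose en-face footprint falls within 2×1 pixels of a focus
footprint exclude that focus from classification. Two restrictions keep this
clause meaningful: (1) the mass search runs strictly anterior to the RPE with
a 3-voxel guard band (z < line − 3) — the RPE band and choroid depolarize
physiologically, and the 3×3 kernel bleeds their low DOPU one voxel above
the line, so a search that crossed the line would flag every eye; (2) voxels
whose kernel support touches a focus voxel set are not mass candidates —
otherwise the low-DOPU halo the kernel smears around a large depolarizing
focus would count as a "mass" and every large focus would exclude itself.
The lateral dilation in the overlap test compensates for the focus
displacing the mass's own voxels in exactly its own columns.

Eye-level tallies use migration precedence: an eye with any migrating focus
counts only in the migration column, eyes whose foci are all excluded count
in neither. This keeps the two columns mutually exclusive, consistent with
per-group totals.

Cohen's kappa is computed from the rating contingency as
(p_o − p_e)/(1 − p_e); the degenerate case p_e = 1 (both raters constant and
identical) is defined as 1.0.

## Cohort statistics

Percentages are rounded to one decimal, half away from zero (matching the
published table formatting). Group-vs-rest comparisons use the Pearson
chi-square on the 2×2 table without continuity correction (exposed as a
flag); each-vs-rest is the default grouping, combined-groups-vs-rest is
available. Mann–Whitney U uses midranks, with the p-value exact by
enumeration of all group assignments when n₁+n₂ ≤ 12 (valid under ties) and
the tie-corrected normal approximation otherwise; Kruskal–Wallis applies the
tie correction, with identical-everywhere data defined as (H, p) = (0, 1).
Pearson correlation reports r, R² and the two-sided p from
t = r√((n−2)/(1−r²)); constant inputs are rejected rather than returning an
undefined coefficient.

## Synthetic data: what it emulates

The phantom is a retinal slab (reflectivity 1.0, polarization-preserving)
over a 3-voxel RPE band (reflectivity 4.0, depolarizing) and choroid (1.5,
depolarizing), with a vitreous noise-only band above. Speckle follows the
fully developed model: preserving voxels are a complex circular-Gaussian
scalar on a fixed Jones vector (constant normalized Stokes direction);
depolarizing voxels carry two independent circular-Gaussian channels, whose
normalized Stokes directions are provably uniform on the Poincaré sphere.
Detector noise is additive circular-Gaussian per channel, independent across
repeats (default energy 0.05 per channel; "high-SNR" validation cohorts use
10⁻⁴). A `speckle=False` mode draws deterministic per-voxel energy while
keeping random depolarized directions; it exists because exact volumetry
recovery is only testable without intensity speckle (exponential intensities
put some focus voxels below any threshold).

PED domes are elliptical Gaussian elevations of the RPE line, quantized to
voxels; the true volume is known both as the voxelized sum and as the
analytic (error-function) integral over the scanned area. Defaults: serous
height 70–130 µm with σ 375–525 µm; drusenoid 35–70 µm with σ 250–400 µm —
only the relative sizes matter for the correlation experiments. In the
serous group the focus load is coupled to the dome height (count rate =
h/30, radius ~ U(h/4, h/4+12) µm), a mechanical-stress reading of RPE
shedding from the PED apex; the coupling strength is set so that the true
HRF–PED volume correlation is detectable at the study's serous group size
(n = 24) for most seeds, with R² ≈ 0.3.

Foci are ellipsoids in physical µm with independent melanin / lipofuscin /
melanolipofuscin flags; ground-truth migration ≡ (melanin AND lipofuscin) OR
melanolipofuscin. Per-group focus rates and flag probabilities are shaped to
mirror the published per-group migration frequencies. AF images are
background 60 + Gaussian blob (amplitude 70, σ = focus radius) per focus
where the pigment flags call for it, plus σ = 3 pixel noise, 8-bit. PS-SLO
frames are an angle-independent floor (base 4.0 + 1.5 per depolarizing
intraretinal voxel in the column; the uniform RPE/choroid return is folded
into the base) plus a period-π sinusoidal crosstalk term (amplitude 20,
offset 1.0) and σ = 0.5 noise. All modalities share the (x, b) grid —
registration is by construction, and only a pixel-offset transform is
supported for user data.

Grid sizes: the generator's defaults keep the instrument geometry
(512 × 256 × 128 × 4 repeats; depth configurable to 583). Validation
cohorts and the demo pipeline use a 96 × 48 × 128 × 4 grid — the package's
chosen desk-scale working point that preserves every structural relation
(vitreous band, retina thick enough for 17–45 µm foci, dome headroom) at a
few seconds per eye.

**What passing tests do not show about real data:** no birefringence (nerve
fiber layer), no motion artifacts, no wave-optics rendering or spectral
dependence, no segmentation error (the truth RPE line is used), no optic
media opacity, and observer thresholds replace human judgment. Recovery of
ground-truth labels on this generator validates the pipeline's internal
consistency, not clinical sensitivity/specificity.

## Known limitations and open choices

- The classification operates on generator-provided focus voxel sets
  (truth-guided localization); automatic HRF detection is out of scope, as
  the study also localized HRF manually.
- The hard-exudate exclusion interprets "corresponding axial locations" as
  en-face column overlap (with the small dilation described above); depth
  correspondence is not otherwise constrained.
- Whether an eye can appear in both count columns is resolved by migration
  precedence; the alternative (independent columns) is a one-line change in
  `classify_eye`.
- The published study reports two different values for the serous HRF–PED
  correlation in different sections; the pipeline reports only its own
  computed r, R² and p and does not privilege either printed value.
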