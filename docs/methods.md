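# Methods

This note documents the models, estimators, and numerical choices behind
`focistat`, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real microscopy.

## Break-number model

A guide RNA matching `n_sites` genomic locations can cut each allele of
each site at most once. Cells in G1 carry 2 alleles per site; cells in G2,
having replicated, carry 4. The per-allele probability of having been cut
by time `t` (hours after guide delivery) is modelled as a lagged saturating
exponential

    F(t) = 0                                   for t <= t_lag
    F(t) = p_max * (1 - exp(-(t - t_lag)/tau)) for t >  t_lag

The functional form is a modelling choice; its anchors are empirical:
breaks first become detectable around 2 h after guide delivery, and about
half of all target alleles are cut by 8 h. The defaults `t_lag = 2 h`,
`p_max = 1`, `tau = 6/ln 2 ≈ 8.656 h` satisfy both exactly
(`F(8) = 1 - exp(-ln 2) = 1/2`). All three parameters are overridable.

Expected foci per nucleus in a population with G1 fraction `f_G1` and G2
fraction `f_G2` is

    E[foci](t) = background + n_sites * (2 f_G1 + 4 f_G2) * F(t)

Spontaneous background foci (mean 3 per nucleus, the count observed in
guide-free controls) are assumed additive with induced breaks; possible
spatial coincidence of a background focus with an induced one is ignored.
Alleles cut independently.

The Monte-Carlo simulator (`simulate_break_events` / `mc_concurrent_foci`)
discretises time into steps of `step` hours; an allele's cut time is the
first grid time at which `F` exceeds its uniform draw, so cut times respect
the lag and the grid. Repair times add an exponential lifetime. With repair
disabled the concurrent-focus count converges to the closed form above;
this dual route (simulator vs algebra) is asserted in the tests at
n = 10,000 cells within 3 Monte-Carlo SE.

## Repair lifetimes

Focus lifetimes are exponential. The IR (γ-irradiation) mean of 1.0 h is a
model assumption — no absolute repair half-time is asserted; only the
*difference* matters for the package's comparisons. The Cas9 mean is the IR
mean + 2.0 h, reflecting the observation that Cas9-induced breaks persist
roughly two hours longer than radiation-induced ones (plausibly because
Cas9 remains bound to cut ends). Both means are parameters of
`RepairModel`.

## Image synthesis

`generate_field` renders a two-channel field:

* **Nuclei** — axis-aligned ellipses, semi-major axis drawn from
  `nucleus_radius_range` (default 26–34 px), eccentricity ≤ 1.5, edges
  softened with a Gaussian of σ = 1.5 px. A fraction `overlap_fraction` of
  nuclei are placed as touching pairs (centre distance 1.2–1.6× the mean
  radius) to exercise watershed splitting; remaining nuclei keep a 2.4×
  max-radius clearance. Pixels claimed by two touching ellipses go to the
  nearer centre, so ground-truth masks are disjoint. Placement failure
  after 500 attempts raises a `PlacementError` naming the offending
  parameter.
* **Foci** — isotropic 2D Gaussians of σ = 2.2 px (≥ 20 px above
  half-maximum, comfortably clearing a 16-px area criterion) and amplitude
  500 a.u., planted inside the 80%-scaled nucleus ellipse. The default
  spacing floor is 5σ: at the default amplitude, the connected-pixel
  criteria themselves cannot separate pairs closer than roughly the
  above-threshold footprint diameter (~8–9 px ≈ 4σ), so a 4σ floor would
  sit exactly at the resolution limit — pairs at that distance merge in
  *any* faithful implementation of the criteria, including the brute-force
  oracle. Crowded nuclei relax the spacing progressively rather than fail;
  close pairs may then be detected as one merged focus, as in a real image.
* **Channels and noise** — DAPI = 100 a.u. background + 1000 a.u. nuclear
  plateau; marker = background + a dim nucleoplasmic plateau (0.1× the
  DAPI plateau) + foci. Each channel is Poisson-sampled (photon noise) and
  Gaussian read noise of σ = 10 a.u. is added. The geometry keeps the
  focus/nucleus area ratio realistic: with much smaller nuclei the planted
  foci and the DoG edge response of the plateau dominate the robust
  background estimate and the 2-fold criterion degenerates.

Everything is a pure function of `(spec, seed)` via
`numpy.random.default_rng`.

What the generator does **not** emulate: optical PSF blur of nuclear
texture, chromatin heterogeneity, photobleaching, stage drift, uneven
illumination, 3D sectioning, mitotic figures, or camera-specific noise
calibration. Passing recovery tests therefore demonstrate correctness of
the counting machinery under a controlled substrate, not performance on
arbitrary real images — on real data the detection parameters are expected
to need per-experiment tuning, exactly as the underlying protocol
prescribes.

## Segmentation

Median filter (square window of half-width `median_radius`, default 2,
window clipped at image edges — corner pixels use their in-image
neighbourhood only), Otsu threshold by default (`fixed` override for
reproducibility), strict `>` foreground. The watershed runs on the negated
Gaussian-smoothed Euclidean distance transform with seeds at its local
maxima (`min_distance = max(3, 2σ)`); components below `min_nucleus_area`
(default 200 px) are discarded and labels are made contiguous and
4-connected. The smoothing default σ = 2.0 px was chosen because σ = 3
occasionally leaves deep-overlap pairs (1.2× radius) unsplit while σ = 2
splits all touching pairs tested without oversplitting large nuclei. A
constant image under Otsu yields an empty label map with a logged warning.

## Focus detection

The marker channel is band-passed with a Difference of Gaussians
(σ = 2 and 6 px, reflective boundaries). Per nucleus, the "background
signal" is the median of the filtered in-nucleus values and its spread the
MAD-based robust SD (1.4826 × MAD); the image-wide reference spread is the
median of per-nucleus spreads. A candidate pixel in nucleus *j* must
satisfy

    filtered > median_j + fold_k * SD_ref      (fold_k default 2)
    filtered > abs_min

with `SD_ref` the image-wide median SD by default (the per-nucleus SD is
available behind `use_per_nucleus_sd`, the alternative reading of the
2-fold rule). Candidates group 8-connected; groups are kept only when
strictly larger than `min_focus_area` (default 16 px — a 16-px group is
rejected, 17 kept). `abs_min=None` derives the 95th percentile of the
extranuclear filtered signal; that floor is near the noise ceiling and
suits sparse foci. The test suite and the reproduction script instead fix
`abs_min = 80` a.u. (≈ 16% of a default focus's peak filtered response,
≈ 25× the filtered noise SD), which bounds each focus's footprint well
below the planted spacing — this mirrors the manual per-experiment tuning
of the absolute-minimum criterion in the underlying protocol. A literal
pixel-by-pixel implementation of the two criteria is kept in the test
suite as an oracle; the vectorised detector is asserted pixel-identical to
it on 200 seeded fields.

## Tracking

Greedy nearest-neighbour linking: all (active track, detection) pairs
within `max_displacement` are sorted by distance (ties: lower detection
index) and assigned; unmatched detections open tracks; a track with no
match ends — there is no gap closing, so a one-frame blink splits a track.
Retention is `n_frames × frame_interval`: a single-frame appearance counts
one full interval, and no interpolation is applied. The synthetic
time-lapse defaults to 0.5 h frames over 24 h; the window is long relative
to the Cas9 lifetime tail because right-truncation at ~10 h visibly biases
the Cas9−IR retention difference (≈ −0.15 h). Cohort comparison reports
the difference of mean retentions with a seeded 2,000-resample bootstrap
95% CI.

Note that the observed retention difference estimates the difference of
*conditional* lifetime means (foci visible in at least one frame); with
0.5 h frames the two conditioning corrections nearly cancel
(+0.26 h vs +0.27 h), so the estimand stays within ~0.01 h of the
configured 2.0 h gap.

## Cell-cycle cohorts and estimators

`simulate_tracks` draws, per cell: phase at damage (default 40/40/20%
early-G1/late-G1/G2 — an assumption, as phase proportions at transfection
are not measured), a baseline entry time, and damage responses:

* damaged G2 cells enter mitosis at baseline + a delay drawn from
  Uniform(4, 6) h, the observed magnitude of the single-break G2 delay;
  with the checkpoint abrogated the delay is scaled by
  `abrogated_delay_factor` (default 0.1, "drastically shortened");
* a fraction of damaged G1 cells (default 0.2, embodying the observed
  ~20% drop in 24 h S-phase entry) arrest and never enter S within the
  horizon (default 24 h); the early/late-G1 label is carried for
  bookkeeping but the default model arrests a flat fraction;
* cells that enter mitosis within the horizon divide and acquire a
  micronucleus with probability 0.02 (checkpoint intact) or 0.10
  (abrogated). The absolute baselines are assumptions chosen to embody the
  observed five-fold increase; only the ratio is compared anywhere.

The default baseline mitotic-entry time is Uniform(10, 14) h
post-transfection — a residual G2 duration of 2–6 h beyond the 8 h
observation start, consistent with a ~4 h G2 phase. For S-phase cohorts
the baseline should be set explicitly (the calibration runs use
Uniform(2, 20) h so baseline entry completes within the 24 h window).

Estimators: cumulative entry curves put censored cells in the denominator
permanently; times are reported relative to `t0` (default 8 h, when
mitotic-entry scoring starts). The delay between curves is the difference
of first crossings of a quantile (default 0.5) with linear interpolation
between grid points; if either curve never reaches the quantile the result
is NaN — explicitly not estimable, never silently 0. Entry reduction at
`t` is `100 (control − treated)/control`. The micronucleation fold uses
per-division frequencies with Fisher's exact test; a zero-count control
yields a not-estimable fold with a Clopper-Pearson-based one-sided lower
bound rather than infinity. Group tests are Welch's t (pairs) and one-way
ANOVA with all-pairs Welch comparisons under Bonferroni adjustment
(`p_adj = min(1, p·m)`); two groups that are both constant at the same
value return p = 1 with a degeneracy flag instead of a 0/0 statistic.

At the cohort scale of the live-imaging experiments (~150 cells), the
median-crossing delay estimator has a sampling SD of ≈ 0.25 h and is
unbiased; the acceptance test for ±0.5 h recovery therefore checks the
median of five independent replicate cohort pairs, since any single
replicate fails a ±2 SD band about 5% of the time by construction.

## Indel classification

Signed indel sizes partition into NHEJ products {+1, +2, −1, −2, −3, −4},
resection-dependent deletions (≤ −5), and a remainder (size 0 = unedited,
reported separately; insertions > +2). Fractions over all reads always sum
to 1; `nhej_of_repair`/`resection_of_repair` renormalise over repair
products only, the denominator used when quoting "fraction of repair
products". The default generator mixture allocates 0.30 to the NHEJ
classes and 0.70 to resection classes.

## Problem sizes in the standard runs

The shipped test suite and `scripts/acceptance.py` use: 200 fields of
64×64 px for oracle equivalence; 13 fields of 640×640 px (nuclei of radius
46–52 px) for the 0–25 foci/nucleus linearity sweep; 100 two-nucleus
fields for watershed splitting; 10,000 cells for Monte-Carlo/closed-form
agreement; 152 nuclei (19 fields) for the end-to-end mean-count
calibration; 500 foci per arm for retention; 150–2,000 cells per cohort
for the cell-cycle estimators; and 100,000 reads for the indel classifier.
These sizes keep every standard run at interactive speed while leaving all
stochastic checks inside 3-SE tolerances.

## Known limitations

- No declumping of merged foci: the counting criteria are applied exactly
  as specified, so foci closer than the above-threshold footprint merge.
- No sub-pixel localisation, colocalisation across marker channels, or
  intensity bleaching correction.
- The FUCCI simulator is phenomenological (draws delays and arrest
  outcomes directly); it contains no signalling-state model, so it cannot
  answer questions about checkpoint mechanism, only calibrate estimators.
- Exponential repair lifetimes are a convenience; real repair-time
  distributions are heavier-tailed for complex breaks.
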