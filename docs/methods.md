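# Methods

## Study design carried by the data model

One monitoring record is a single monthly measurement of one analyte
(arsenic, antimony or selenium) in one well, in μg/L. The reference design is
35 open dug wells across four land-use areas (24 residential, 5 commercial,
4 industrial, 2 agricultural), each sampled in 3 months of the wet season and
3 of the dry season — 210 well-months. Concentrations below the instrument
detection limit are recorded as 0 and flagged `nondetect`; the two encodings
are kept equivalent by construction.

Two conventions follow from how the source tables are built, and are applied
consistently everywhere:

* **Zeros are data.** Non-detects enter every mean as zeros; no ½-LOD or
  other substitution is applied (the per-well overall means in the packaged
  fixture are reproducible only under this convention). Detection frequency
  is therefore "fraction of wells whose mean is above zero".
* **The overall per-well mean is the unweighted mean of the two seasonal
  means.** Under the balanced 3 + 3 monthly design this equals the pooled
  mean of the six monthly values. SDs use the sample (n−1) convention.
* **Claims count wells, not samples.** Exceedance and detection fractions
  are over the 35 wells (26/35 = 74.3% etc.); this is the only reading under
  which the published percentages reproduce.

The area assignment of the 35 fixture wells follows the published tables'
footnotes, which mark four industrial wells; the accompanying text says
three, but the published area-mean concentrations only reproduce with four.

## Guideline exceedance

A well exceeds a limit when its scope mean (overall, wet or dry) is strictly
above it; an `inclusive` (≥) variant exists because one well sits exactly on
the 40 μg/L selenium limit in the dry season and the published 31.4%
dry-season figure counts it. Exceedance is non-increasing in the limit, and
the inclusive count can never be below the strict one.

## Seasonal comparison

Wells are identical across seasons, so the wet-vs-dry comparison is a
**paired** two-sided t test on per-well (dry − wet) seasonal means with
df = n − 1, at α = 0.05, alongside the wet/dry Pearson correlation. If the
paired differences are an exact constant the t statistic is degenerate: a
zero constant yields t = 0, p = 1; a nonzero constant is reported as p = 0
with a warning rather than an exception. Across-area comparisons use the
classical one-way ANOVA decomposition (SS_between + SS_within = SS_total,
enforced to ~1e-12 relative in tests); all-constant input is rejected as
undefined rather than reported as F = 0/0.

On the fixture, antimony and selenium are significantly higher in the dry
season (low precipitation concentrates the groundwater); the selenium result
is reported as the test yields it, without forcing agreement with any prior
narrative. Arsenic, detected in only 6/35 wells and only in the dry season,
shows no significant seasonal shift.

## Risk cascade

ADD = DW·C/BW, HQ = ADD/RfD, HI = Σ HQ over the three analytes, per land-use
area × cohort (adult 2.0 L/day at 50 kg; child 1.0 L/day at 20 kg — so the
child/adult HQ ratio is exactly (1/20)/(2/50) = 1.25 for every analyte and
area). The cascade is linear in C and additive over analytes. RfDs: As
0.0003, Sb 0.0004, Se 0.005 mg/kg/day. No exposure-frequency, duration or
averaging-time factors are applied: the dose model is the steady-state
drinking-water form above.

**Concentration rounding.** The reference risk table prints its
concentration column rounded half-up to 3 significant figures and then to
2 decimal places in μg/L (so 0.64625 → 0.65; 13.35 → 13.4). `risk_table`
applies this "printed" convention by default so its output is comparable
digit-for-digit with the published table, and offers `c_rounding="none"` for
full floating precision; the two differ by ≲1% in any HI. The rounding is
done in decimal arithmetic to avoid binary-float half-way artefacts.

Both the HQ > 1 screen (adverse effects possible) and the more conservative
HQ > 2 flag are reported without interpretation.

## Ordination

* **Prevalence order** ranks analytes by total concentration mass across
  wells (ties broken alphabetically and flagged). On the fixture:
  antimony > selenium > arsenic.
* **PCA** eigendecomposes the correlation matrix (default; covariance
  optional) of the 35 wells × 3 analytes matrix of overall means. Loadings
  are orthonormal with each component's first nonzero entry positive;
  variable biplot coordinates are loadings scaled by √eigenvalue. A
  zero-variance column under standardization is rejected by name. The
  explained-variance split this default produces (46.6% / 32.2% / 21.3%) is
  reported but deliberately not asserted anywhere: the original analysis
  does not state its input matrix orientation or scaling.
* **Correspondence analysis** takes the SVD of the standardized Pearson
  residuals S = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2) of the row/column profiles;
  total inertia Σσ² = χ²/n, invariant to scaling the matrix by a positive
  constant. All-zero rows are filtered and reported; row/column principal
  coordinates satisfy the usual transition formulas (checked in tests).

## Synthetic campaigns

The simulator draws each well × season × month × analyte independently from
a zero-inflated lognormal: detection is Bernoulli(p) per analyte × season,
and a detected magnitude is LogNormal(log GM + log area-multiplier, log GSD).
This matches the qualitative structure of the reference data — non-negative,
right-skewed, many non-detects, strongly season-dependent detection — while
ignoring, by design, spatial autocorrelation between wells, per-well random
effects (a single variance component) and any geochemical transport
mechanism. Passing tests on simulated campaigns therefore demonstrate the
pipeline's statistical correctness under these assumptions, not fidelity to
every feature of real groundwater series.

`fixture_calibrated_config()` estimates the parameters from the packaged
fixture per analyte × season: p is the fraction of wells with a nonzero
seasonal mean (wet-season arsenic: 0; dry-season antimony: 1), and
log GM/log GSD are the mean/SD of the log of detected seasonal means
(dry-season antimony GM ≈ 47 μg/L). Area multipliers default to 1: the
fixture shows no consistent area effect beyond two high-arsenic commercial
wells. Seeds are mandatory (numpy `default_rng`); identical seeds give
byte-identical campaign CSVs.

Closed forms used for validation: E[conc] = p·exp(μ + σ²/2) per stratum,
hence E[area mean], E[HI] (the cascade is linear) and the Monte-Carlo SE of
the HI estimate by independence across wells and analytes. The
simulation-based checks run at 48× the study's well count (1,680 wells,
~10,000 well-months, a couple of seconds end to end): detection probabilities are
then recovered within ±0.02, log-GMs within 3 standard errors, and pipeline
HIs sit within 4 MC standard errors of their expectations.

## Numerical and I/O choices

* Concentration unit is μg/L everywhere except inside the risk module
  (mg/L, converted exactly once by c/1000).
* Result CSVs are written with 6 significant digits; JSON at full precision;
  round-trip tables use shortest round-trip float repr. Reruns are
  byte-identical — the pipeline is a pure function of (input bytes, config).
* The packaged fixture is checksum-verified (SHA-256) at load;
  transcription corrections are listed in `src/gwtrace/data/PROVENANCE.md`.
* CLI exit codes: 0 success, 1 internal error, 2 input/validation error.

## Known limitations

* Non-detects as zeros biases means downward relative to ½-LOD or MLE
  censoring estimators; it is retained as the reference convention.
* The risk model is the point-estimate drinking-water route only: no
  carcinogenic slope factors, no dermal/inhalation routes, no uncertainty
  propagation on RfDs.
* Per-well seasonal SDs in the fixture are carried but not used in
  inference, since the underlying monthly values are not published.
* The simulator's independence assumptions understate the variance of area
  means under spatial clustering of contamination.
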