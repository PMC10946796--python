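# Methods

## The analysis model

MALDI imaging MS acquires one MS1 spectrum per ablation pixel; in
positive mode each lipid appears as singly charged protonated, sodiated,
potassiated or dehydrated ions, plus single-¹³C isotopologues. The
package treats the analysis as five stages with explicit contracts:
shared-target binning, ROI feature extraction with background filtering,
Pareto-scaled multivariate modeling, zone-wise univariate testing, and
adduct-aware annotation. Every stage logs its parameters and output
digests to a JSON-lines provenance file, and every source of randomness
flows from one integer seed, so a run is reproducible bit for bit.

## Binning and lock mass

Targets are built by partitioning all observed peaks into half-open bins
`[k·w, (k+1)·w)` with origin 0 (default w = 0.04 Da; drift time, when
present, is crossed in with its own bin width, default 100 units). Each
non-empty bin becomes a target at the intensity-weighted mean m/z of its
members. This left-closed convention is a declared dialect of this
package: vendor software does not document its internal tie rules, so we
fix one deterministic choice and test it. Re-binning assigns each peak to
the nearest target within a tolerance (ties go to the lower-m/z target),
sums co-assigned intensities and counts dropped peaks.

Lock-mass correction is multiplicative and per sample, not per pixel:
the most intense feature of the sample-mean spectrum within a ppm window
of the spiked standard — deuterated PC (15:0/18:1(d7)), [M+H]⁺ =
753.6134, computed here from the composition C41H73D7NO8P with exact
cation-minus-electron charge-carrier masses — defines the factor
`reference/observed` applied to all m/z values. If no candidate is found
the sample is left uncorrected with a logged warning.

## ROI features, normalization and the matrix filter

ROI values are pixel means of binned intensities. Two row normalizations
are provided and chosen per design:

- **TIC** (atlas design): divide each row by its total; appropriate for
  visual comparability and tissue contrasts. TIC is compositional — a
  genuine increase in one abundant ion depresses all other shares — so it
  is deliberately *not* the default for genotype contrasts.
- **Internal standard** (genotype design): divide each row by the spiked
  standard's bin. The standard is deposited uniformly with the matrix
  spray, so this removes acquisition scale without compositional
  coupling. This mirrors the role of an intersample-normalization
  pipeline in the original workflow; if the standard bin cannot be
  located the code falls back to TIC with a warning.

The matrix-ion filter excludes ion j iff
`mean_matrix(j) − 2·SD_matrix(j) > mean_tissue(j) + 2·SD_tissue(j)`,
with matrix statistics over the off-tissue ROIs and tissue statistics
pooled over all tissue ROIs. All SDs in the ROI module are population
SDs (ddof 0) — the convention is arbitrary but fixed and tested. The
filter can never remove an ion whose tissue mean exceeds its matrix
mean. Whether to filter before or after log scaling is not externally
constrained; the canonical order here is extract → normalize → filter →
log₂, recorded in provenance. Log scaling uses
`log2(prescale·x + pseudocount)` with pseudocount 1; the pipeline sets
prescale 1e4 so TIC fractions return to a count-like range before the
pseudocount is added.

## OPLS-DA and the S-plot

Pareto scaling (centre, divide by √SD) is the compromise between raw
covariance and unit variance that the commercial S-plot workflow uses;
zero-variance columns are centred only and flagged. The OPLS-DA follows
the orthogonal-signal-correction PLS formulation: with class vector y
coded ±1 and centred,

```
w ∝ Xᵀy;  repeat n_orth times:
    t = Xw;  p = Xᵀt/(tᵀt);  w_o ∝ p − (wᵀp)w
    t_o = Xw_o;  X ← X − t_o p_oᵀ;  w ∝ Xᵀy
finally t = Xw (one predictive NIPALS component)
```

With `n_orth = 0` this is exactly one-component PLS1 (verified against
an independent NIPALS implementation to 1e-8). The predictive score is
oriented so the group coded +1 has positive mean. S-plot statistics are
computed against the Pareto-scaled matrix that entered the fit:
`splot_cov_j = cov(t, x_j)` with denominator n−1 and `splot_corr_j` the
Pearson correlation; they share sign by construction. R²Y comes from the
predictive component; Q² is leave-one-out, off by default in pipeline
runs because it is O(n) refits.

Panels select ions with |statistic| ≥ threshold. The default axis is the
covariance with threshold 0.04, with the correlation axis available —
which statistic a given commercial S-plot labels "p1" is ambiguous, so
both are exposed. Note the covariance axis is data-scale-dependent; on
the clean synthetic phantoms the default threshold is permissive and the
panel is large, which is expected: after TIC normalization almost every
ion carries genuine (compositional) tissue information. Manual
"visual inspection" removal of false positives is supported only as an
explicit exclusion list that is logged, never automated. Hierarchical
clustering runs on column z-scores with correlation distance and average
linkage (configurable; conventional for z-scored omics heat maps).

## Zone-wise testing

Within each growth-plate zone, each ion gets an unpaired two-sided Welch
t-test between genotypes on log₂ ROI values ("multiple t test" leaves
the variance assumption open; unequal variances is the safer default and
pooled variance is available). p-values are Benjamini–Hochberg adjusted
*within the zone*; the FDR variant is configurable and recorded. Fold
change is `2^|Δmean log₂|` — the ratio of geometric means — with the
direction carried separately; significant sets are `q < 0.05` split by
sign, optionally gated at FC > 1.5. ROIs are the replication unit, as in
the source workflow; they are pseudo-replicates within animals, so an
`aggregate_by` option collapses to per-animal means first. Zero-variance
ions get p = q = 1 and a flag. Volcano tables floor q at 1e-300 (cap 300
on the −log₁₀ axis).

## Annotation

Theoretical m/z = neutral monoisotopic mass + adduct delta, with deltas
stored to six decimals as cation-minus-electron masses (proton 1.007276,
Na⁺ 22.989218, K⁺ 38.963158, dehydration −18.010565 only in combination
with protonation, ¹³C +1.003355 on any base adduct). Matching keeps
every (target, lipid, adduct) pair within the ppm tolerance — 100 ppm by
default, sized for calibration drift across long acquisition campaigns —
and never forces uniqueness: ambiguous putative IDs are reported, not
resolved. Tier scoring encodes database evidence as booleans (the exact
numeric "high score" cutoff of the upstream search engine is not
published, so it arrives as a flag in the library file): manual ID →
tier i with precedence over all other indicators; LipidMatch∩LipidBlast
→ ii; high-scoring LipidMatch without LipidBlast → iii; otherwise iv
(excluded) with explicit reasons (low score, odd total fatty-acid
carbons, implausible adduct pattern). Consensus library bins are
half-open 0.2-Da m/z bins with retention time discarded.

## The phantom generator

The generator emulates the study design, not the anatomy: a rectangular
grid with an off-tissue margin (chemical matrix only) and horizontal
tissue bands, the growth plate as three adjacent zones. Each ground-truth
lipid has a mean log₂ intensity per region; pixel intensity is
`2^(μ + σZ)` (+ optional additive baseline), i.e. log-normal
multiplicative noise, which matches positive, TIC-normalizable data and
the downstream log step. Defaults: 64×64 grid (thousands of pixels,
seconds of runtime), pixel-level σ(log₂) = 1.0 — within-tissue biological
variance is not quantified in the literature for this tissue, so it is a
free parameter with a realistic default rather than an asserted value —
and an adduct profile of 60% protonated, 15% sodiated, 10% potassiated,
5% dehydrated, with ¹³C satellites at a fixed 0.3 of the monoisotopic
intensity (enough to exercise isotope-aware matching without a full
isotope-pattern model). The default panel reproduces the study's
qualitative spatial structure: LPC/PC species enriched in the growth
plate, ether-PCs and long-chain polyunsaturated phospholipids in marrow,
sphingomyelins in articular cartilage, PE/PA in cortical bone, flat
background lipids, and low-mass matrix-only ions dominant off tissue.
Genotype effects multiply growth-plate-zone means for flagged lipids
(folds 1.5–3× by default). Masses are computed from class composition
rules, so adduct arithmetic is exact; note PC(c) and PE(c+3) are
isomeric by composition, so a few truth lipids legitimately share a bin.

A ROI-level fast path (`simulate_feature_matrix`) draws the identical
intensity model directly at the ROI level (pixel draws averaged within
the ROI, then log₂) for Monte Carlo calibration studies — the
false-discovery-rate and recovery properties are measured over 100 and
20 seeded replicates respectively in seconds. What passing these
synthetic checks does *not* show: robustness to chemical-noise spectra,
realistic isotope envelopes, ion-mobility physics, spatial intensity
gradients within a tissue, or batch effects across acquisition days —
none of which the generator emulates.

## Numerical and design choices

- Bin convention half-open/left-closed at origin 0; midpoint ties in
  re-binning go to the lower-m/z target.
- Peak reduction keeps intensities strictly greater than the threshold,
  then the top N with ties broken toward lower m/z; the operation is
  idempotent.
- The internal tabular dialect round-trips bit-exactly (17 significant
  digits); imzML export is continuous mode with float64 m/z and
  intensities (≤1e-6 relative m/z round-trip error, intensities exact).
- Drift time is carried, never interpreted.
- Problem sizes in tests and the acceptance script (32–64 pixel grids,
  200–300 ions, 10 ROIs per group, 20–100 Monte Carlo seeds) were chosen
  as the smallest sizes at which the statistical properties under test
  are stable.

## Known limitations

No raw vendor-format reading, profile-mode spectra or centroiding; no
MS2 matching (manual MS2 evidence enters as the `manual_id` flag); no
mixed-effects models for the pseudo-replication beyond the
animal-aggregation option; no cross-validated choice of the number of
orthogonal components; the S-plot covariance threshold is
scale-dependent and should be tuned per dataset when used outside the
default pipeline.
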