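# Methods

This note documents the statistical model behind the pipeline, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer should know.

## Screen model

Each library well depletes one candidate gene by siRNA; expression of three
p53 target transcripts (CDKN1A, BBC3, TP53) is measured by RT-qPCR under two
treatments (DMSO vehicle; 100 µM etoposide as a p53-activating DNA-damage
stimulus) and divided by the reference transcript LMNA measured from the
same well-set. The central object is therefore a gene × 6-condition matrix
of non-negative, dimensionless expression ratios, with the six columns in
fixed order (CDKN1A, BBC3, TP53) × (DMSO, etoposide). Per-gene roles
distinguish library wells from dedicated nontargeting, TP53 and MDM2 control
wells that recur on every plate.

## Quantification

The relative standard curve method converts Ct to relative template amount:
an OLS line Ct = b + m·log10(q) is fitted to a dilution series (≥ 3 points,
≥ 2 distinct quantities), and samples are inverted through it,
q = 10^((Ct − b)/m). Amplification efficiency is E = 10^(−1/m) − 1; a
perfect doubling per cycle gives m = −1/log10 2 ≈ −3.3219 and E = 1. A
non-negative fitted slope is chemically nonsensical and is flagged rather
than silently used.

Replicates (triplicate by design) are averaged **on the quantity scale**,
not the Ct scale: quantity space is where the method reports, and averaging
log-scale Ct values would introduce a small convexity bias. Replicate
Ct SD > 0.5 cycles, or fewer than 2 replicates, sets a QC flag but never
excludes data — no exclusion rule is part of the design, and flags keep the
pipeline auditable. A missing or non-positive reference amount (e.g. a
lethal knockdown) yields a missing normalized value with a reason code
rather than an exception, so single dead wells cannot crash a screen.

## Hit calling

Standard scores are computed per condition column: z = (X − μ)/θ with μ the
mean and θ the **sample** SD (ddof = 1) over the library siRNAs'
non-missing values. Dedicated control wells are excluded from μ/θ by
default — they repeat on every plate and would bias the population
statistics — but still receive z-scores against the library statistics
(`include_controls=True` exposes the alternative convention). The library's
own TP53 entry is a library member and is scored like any other target.

A cell is a hit when |z| is **strictly** greater than the threshold
(default 2): values exactly on the boundary belong to the non-hit window.
Direction semantics: knockdown lowering a readout (z < −τ) ⇒ the targeted
gene is a positive regulator of that readout.

Classification rules:

- **joint** — same-direction CDKN1A and BBC3 hits in the same treatment;
- **CDKN1A- / BBC3-specific** — a hit for one readout in a treatment where
  the partner readout is not a hit, for genes that are not joint in any
  treatment (a treatment-level rule: a gene hit for CDKN1A in both
  treatments without a BBC3 partner stays CDKN1A-specific);
- **TP53-specific** — any TP53-readout hit, assigned independently, so a
  gene may be joint *and* a TP53 regulator (a knockdown acting upstream
  through TP53 transcription shows exactly that profile).

Hit calls are invariant under positive affine rescaling of a column, and
lowering the threshold can only add hits — both are asserted as properties.

## Secondary validation and false-positive flags

The rescreen model follows the screening convention of a relaxed cut-off on
a smaller pool: z-scores are recomputed **within** the rescreened pool
(DMSO-only, CDKN1A/BBC3), and a primary regulator present in the pool is
confirmed when some readout it was originally a hit for shows |z| > 1 with
matching direction (direction agreement can be disabled). Present but
unconfirmed genes are putative false positives; absent genes stay
`not_retested`; TP53-only regulators are outside the rescreen design and are
untouched. Orthogonally, hit genes whose external expression value is
exactly 0 (not expressed in the assayed cell line) are flagged; this flag is
independent of secondary confirmation — a gene can reconfirm by siRNA yet
still be flagged, the signature of an off-target effect.

## Self-organizing map

The SOM is implemented from first principles as online Kohonen training.
Defaults: 5 × 5 hexagonal grid (25 clusters, numbered 1..25 row-major from
the top-left), 100 full passes over the data, bubble neighborhood, learning
rate decaying linearly 0.05 → 0.01 over all updates, neighborhood radius
starting at the 2/3 quantile of inter-unit grid distances and decaying
linearly to 0 (so it drops below the unit spacing of 1 and late updates act
on the best-matching unit alone). These mirror the documented defaults of
the classical screening-analysis implementation of this algorithm, since
only the grid size and pass count are fixed by the design. Codebook vectors
are initialized by sampling data rows without replacement under the seed;
presentation order is reshuffled per pass from the same generator, making
training fully deterministic given (seed, config, data).

Profiles are clustered **as-is** (no per-column standardization), matching
the use of normalized expression values as the SOM input; a scaling option
exists for exploration. Genes with any missing condition are excluded and
reported. Assignment ties break to the lowest unit id. Every update is a
convex combination of prototype and data point, so the codebook can never
leave the data bounding box — asserted as an invariant. Training usually
(not monotonically) reduces mean quantization error; the suite asserts
improvement on ≥ 90% of 50 seeded runs with data clearly exceeding the unit
count. Cluster membership of a real screen is *not* reproducible without the
original training seed; only the map geometry (25 clusters) and the training
rules are guaranteed.

## Screen QC

The Z′-factor 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| (sample SDs) summarizes the assay
window between positive (TP53 knockdown) and negative (nontargeting)
controls; it never exceeds 1 and is undefined for coinciding means. Control
behavior across plates is tested per role × condition with a two-sided
Welch t-test (no equal-variance assumption, Welch–Satterthwaite df) of
per-plate control means against per-plate library averages; Welch was chosen
because per-plate control means (n per plate small) and screen averages have
unequal variances by construction. A paired-by-plate variant is available
since plate pairing is plausible; unpaired Welch is the documented default.

## Synthetic screens

The generator emulates the study conditions: 589 library genes (the first
being TP53 itself) plated across 7 plates with 2 nontargeting, 2 TP53 and
2 MDM2 control wells each; baseline expression ratios near 1 with
etoposide-elevated CDKN1A (×4) and BBC3 (×3) baselines and nearly unchanged
TP53 (×1.2) — placeholder induction magnitudes in the physiological range,
configurable and never asserted as measured values. Planted effects:

| parameter | default | meaning |
|---|---|---|
| `fractions` | 0.02 per category | share of genes per regulator category (~10% total, in line with targeted screens' ~10–15% hit rates) |
| `effect_log2` | 1.5 | planted \|log2 fold-change\|; puts regulators near \|z\| ≈ 3 under default noise — detectable but not trivial |
| `condition_of_effect` | `mixed` | each regulator acts under DMSO, etoposide or both (uniformly); the three fixed settings are also supported |
| `noise_cv` | 0.15 | CV of multiplicative lognormal technical noise (unit mean) |
| `plate_effect_sd` | 0.05 | SD of the per-plate log-scale offset |
| `tp53_knockdown_log2` | 2.5 | depth of the TP53 library-entry/control knockdown on all readouts |
| `mdm2_effect_log2` | 1.0 | MDM2-control elevation of basal CDKN1A/BBC3 only (MDM2 acts on p53 protein stability, so TP53 mRNA is untouched and induced levels are saturated) |

Noise is multiplicative lognormal because qPCR ratio errors compound
multiplicatively and ratios must stay non-negative. With `emit_ct`, the
matrix is inverted through planted per-amplicon standard curves (perfect
efficiency, amplicon-specific intercepts, 5-point 4-fold dilution series as
a stand-in for the unspecified real series) into triplicate Ct rows plus
standard-curve rows, with an independent per-well reference amount that
normalization must cancel — at zero cycle noise the quantification pipeline
reproduces the matrix to float tolerance, which is asserted end-to-end.

What the generator does **not** model: siRNA off-target effects,
transfection-efficiency gradients, plate edge effects, readout covariance
beyond shared plate factors, or non-lognormal outliers. Passing recovery
tests therefore demonstrate that the statistics are implemented correctly
and calibrated under the stated noise model, not that real screens of this
design achieve those precision/recall figures.

The secondary-screen simulator redraws a random library subset (default 81
genes) under DMSO only with fresh noise, optionally deleting chosen genes'
effects to create planted false positives. Note that regulators planted
with etoposide-only effects cannot reconfirm in a DMSO-only rescreen — the
validation-rate properties are therefore stated over DMSO-active regulators.

## Numerical conventions and edge cases

- Sample SD (ddof = 1) everywhere; negligible at n ≈ 589 but stated.
- Strict inequality at the hit threshold; boundary values are not hits.
- Missing values never create hits, never enter μ/θ, and round-trip through
  the CSV formats as `NA` (empty fields also read as missing).
- A condition column with zero spread, or 1 usable value, is a hard error;
  a column with no data at all (a DMSO-only rescreen's etoposide columns)
  is skipped and stays missing.
- Identical groups in a t-test return t = 0, p = 1 by convention; constant
  groups with different means return p = 0 with infinite t.
- CSV/TSV values are written at full precision (`%.17g`); read/write
  round-trips preserve values, gene order and missingness.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical screens, maps and manifests.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use 40–200-gene screens for
mechanics, 589/600-gene screens (20 seeds) for recovery and calibration,
and 3 null screens for the threshold-calibration estimate — sizes at which
the binomial/Monte-Carlo error of the asserted quantities is comfortably
below the asserted tolerances.

## Known limitations

- No ΔΔCt quantification, multi-reference normalization, B-score/median
  polish, multiple-testing correction or redundant-siRNA scoring — these are
  deliberately outside the design being modeled.
- The expression-based false-positive filter is only as good as the external
  table's gene symbols; matching is case-insensitive but synonym-blind.
- The SOM quantization-error improvement is an empirical, not per-step,
  guarantee; online Kohonen training does not monotonically minimize any
  global objective.
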