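# Methods

`soilmetals` implements the standard index arithmetic of heavy-metal
biomonitoring surveys — contamination factors, pollution load indices,
interval classification, translocation and plant/soil concentration ratios,
regulatory screening, and the accompanying paired-test / correlation
screening — together with a seeded synthetic-study generator whose
closed-form expectations make every stage testable without field data.

## Data model

All measurements live in one long-format schema: one row per
`(site, plot class, medium, tissue, parameter, replicate, value)`.
Plot class (`test` / `control`), not the site label, decides which side of
the comparison a site belongs to; `"control"` is just another site label.
Units are fixed by parameter — pH unitless, electrical conductivity (EC) in
µS/cm, metals (Pb, Hg, Cd, Cu, Zn) in mg/kg dry weight — and are never
stored per row, because a survey reports a single unit system.

Because published surveys rarely release replicate-level values, a second
loader ingests pre-aggregated summary tables (`n, mean, SD, min, max` per
group) and marks them `pre-aggregated`; everything downstream of the
summary stage accepts either source. Validation flags rather than repairs:
a summary row whose minimum exceeds its maximum (a transposition typo seen
in real tables, including one Cd row of the bundled dataset) is a warning
that preserves the printed numbers, while negative concentrations, pH
outside [0, 14], soil rows carrying a tissue label, and duplicated record
keys are errors. Wide per-metal layouts are out of scope for the reader;
the column-name dialect map only renames headers of long tables.

## Indices

For metal *i* at a site,

    CF_i = C_sample,i / C_background,i
    PLI  = (CF_1 · CF_2 · … · CF_n)^(1/n)

with *n* the number of metals (5 here). The background defaults to the
control-plot mean of each metal but accepts any user table. Sample standard
deviations use the n−1 denominator throughout.

The bundled Lacatusu-style classification maps CF and PLI values to verbal
classes through ordered intervals. The printed table needed normalization:
its first row (`<1`) overlaps every later contamination row and is read as
`<0.10`; intervals are treated as contiguous with closed right endpoints;
and the gaps left by printing rounded bin edges (0.25–0.26, 1.00–1.10,
2.0–4.1, …) are closed by extending each interval's upper bound to the next
interval's lower bound. After normalization every non-negative value maps
to exactly one label and classification is monotone. One printed PLI (8.3)
is described in the source survey's prose as "very severe" although the
table places it in the severe band; the table is the defined scheme and
wins here.

Translocation factor and plant/soil ratio follow the arithmetic that
reproduces the survey's own printed tables exactly:

    aerial = leaf + fruit + stem          (tissue means, mg/kg)
    TF     = aerial / root
    ratio  = mean(root, leaf, fruit, stem) / soil

The TF denominator is the root concentration — the survey's prose mentions
soil, but every printed row is aerial/root (e.g. 128.4/51.4 = 2.498,
printed 2.49) and the table's internal consistency settles the definition.
Both ratios are invariant under a common rescaling of concentration units.

Regulatory screening compares group means against each applicable
`(authority, medium, parameter)` limit: `exceeds` above the upper limit,
`below` under the lower one, `within-range` inside a range limit (ranges
occur, e.g. the WHO mercury limit for plants, 0.05–0.5 mg/kg). Parameters
without a limit are listed, not raised.

## Inferential statistics

The paired t-test uses the textbook statistic t = d̄/(s_d/√n) with n−1
degrees of freedom (delegated to `scipy.stats.ttest_rel` in the
non-degenerate case); zero-variance differences are resolved explicitly
(t = 0, p = 1 when all differences vanish; t = ±∞, p = 0 otherwise).
Because these surveys have a single control plot, the default per-site
pairing matches each of the seven test-site means against the control
composite mean — the pairing is a configuration choice, since the source
survey reports n = 7 without stating one. Pearson correlations come from
`scipy.stats.pearsonr` (two-sided p, t transform with n−2 df); the
soil-by-tissue screen correlates every (parameter, tissue) series with
every soil parameter across sites (28 × 7 cells for the full design), at
α = 0.05 with no multiple-testing correction by default, matching field
practice; a Holm step-down adjustment is available (`adjust="holm"`, via
statsmodels). The published correlation matrix and t values cannot be
recomputed — the per-site raw data were never released — so these stages
are verified by hand-formula oracle equivalence, null uniformity of
p-values, and synthetic recovery rather than against printed values.

## Synthetic-study generator

The generator emulates the sampling design only: a set of polluted test
sites plus one control, three plant stands per site, soil and four tissues,
five metals plus pH and EC. Concentrations are median-parameterized
lognormals:

    soil(site, stand)  = median_m · enrichment_m · exp(σ·Z)
    tissue(t)          = soil · slope_m · w_t · exp(ν·Z)

with enrichment 1 at the control, tissue partition weights w averaging 1,
and independent standard-normal Z. Parameterizing by the median keeps the
center fixed when the dispersions σ (`lognormal_sigma`) and ν
(`noise_sigma`) change; the lognormal mean factor e^(σ²/2) therefore
appears explicitly in `ground_truth` wherever it does not cancel:
expected CF = enrichment (the factor is common to test and control soils),
expected TF = (w_leaf + w_fruit + w_stem)/w_root (all per-plant factors
cancel), expected plant/soil ratio = slope · e^(ν²/2).

Defaults are pinned to the bundled survey's scale: control soil medians
(21.9, 17.1, 4.7, 5.4, 3.2 mg/kg for Pb, Hg, Cd, Cu, Zn), enrichments
(3.4, 2.2, 4.3, 10.4, 14.9) equal to the survey's test/control mean ratios,
transfer slopes equal to its plant/soil ratios, and partition weights
(0.90, 1.07, 1.01, 1.02) giving an expected TF of 3.44, typical of its TF
column. The survey publishes no variance components, so the default
dispersions (σ = 0.2, ν = 0.1) were chosen once to sit near the middle of
its printed SD/mean ratios and are otherwise arbitrary. The generator has
no spatial autocorrelation, no temporal dynamics, no censoring at detection
limits, and independent residuals across tissues — so passing recovery
tests demonstrate correctness of the index arithmetic under the stated
model, not robustness to the correlation structure of real field data.

## Verification strategy and problem sizes

Deterministic stages are checked against the published tables bundled with
the package: the PLI row recomputed from the printed contamination-factor
matrix (five of seven sites match exactly at 1 dp; the two sites whose CFs
are most distorted by 1-dp rounding match within one 0.1 step), the
translocation table (±0.01 against printed 2-dp values, which mix rounding
and truncation), and the plant/soil ratio section (±0.002, with the
ordering Hg > Cu > Pb > Cd > Zn exact). Stochastic checks run at desk
scale on one CPU: p-value null uniformity with 2000 simulated studies of
7 pairs (Kolmogorov–Smirnov at α = 0.01), and parameter recovery at 200
test sites, σ = 0.3, over 20 fixed seeds, asserting each metal's CF, TF
and ratio within 3 empirical Monte-Carlo standard errors of ground truth.
Hypothesis property tests run derandomized.

## Known limitations

- Three cells of the published tables cannot be reproduced from the
  printed numbers themselves and the corresponding checks intentionally
  record the discrepancy: the Cd plant/soil ratio (0.6071 from printed
  means vs 0.605 printed, likely computed from an unrounded soil mean) and
  the claim that Cu and Zn tissue means exceed their WHO limits (the
  printed means, 37–41 and 20–26 mg/kg, are below the printed limits of 73
  and 100 mg/kg).
- The printed t values and correlation matrix are not reproducible without
  the unpublished raw data; the statistics modules make no claim to match
  them.
- Pre-aggregated inputs cannot feed the correlation screen (it needs
  per-site series); the pipeline skips that stage when only summaries are
  available.
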