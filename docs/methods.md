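# Methods

This note documents the models behind `lipsmr`, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. The LiP-MS protection screen

### Model

In a limited-proteolysis experiment, lysates treated with compound or
vehicle are exposed to a broad-specificity protease (proteinase K) under
native conditions and then fully digested with trypsin. Ligand binding
locally restricts proteinase K access, so peptides covering the binding
site change abundance between conditions — some fragments become more
abundant (protected from the first cut) and neighbouring fragment forms
less abundant (their generating cut is blocked), producing *opposite-
direction shifts at the same or adjacent sequence positions*. The screen
operationalizes this in three steps:

1. **Peptide-level differential abundance.** Intensities are analysed on
   the log2 scale. Raw linear tables are log2-transformed and each
   sample's median is mapped to the global median (median centring),
   removing loading differences while preserving scale. Each peptide is
   tested with a two-sided Welch two-sample *t* (unequal variances,
   Welch–Satterthwaite df) on its non-missing replicates,
   pairwise-complete, no imputation; peptides with fewer than two usable
   replicates in either condition are excluded and logged. p-values are
   BH-adjusted in one batch across all tested peptides. A peptide is
   `up`/`down` when `q <= alpha` (default 0.05) and `|log2FC| >= lfc_min`
   (default 1.0), else `ns`. Welch rather than a moderated (empirical
   Bayes) statistic: at n = 3 per condition the moderated test's gains
   depend on assumptions the synthetic benchmark deliberately controls,
   and the Welch form is exact under the generative model used here.

2. **Mapping.** Exact string matching of peptide sequences against the
   protein database, all occurrences, 1-based inclusive coordinates.
   No Ile/Leu equivalence. Peptides matching multiple proteins are
   flagged `shared` and participate in screening for every protein they
   match — a conservative choice that can propose homologs (exactly the
   situation of identical gene family members encoding one protein) and
   is therefore marked in the output rather than silently resolved.

3. **Directional conflict.** For each protein with at least one
   significant up and one significant down peptide, all (up, down)
   location pairs with interval gap `<= G` are enumerated
   (`gap = max(0, max(start1,start2) - min(end1,end2) - 1)`, so 0 means
   overlap or abutment). Proteins with at least one such pair are
   candidates, scored by `-log10(p_up) - log10(p_down)` of their best
   pair; ties break by smaller gap, then lexicographic ids, making
   output order fully deterministic. `G` defaults to 10 residues:
   "adjacent" is taken to mean within about one short tryptic fragment;
   it is configurable and results are monotone in it (candidates can
   only be gained as `G` grows).

### Synthetic data and its calibration

The generator draws proteins as i.i.d. uniform sequences over the 20
standard residues, digests them with trypsin (cleave after K/R except
before P; peptide length window 7–35; 0 missed cleavages by default),
gives every peptide a baseline log2 intensity uniform on [18, 30], and
adds N(0, sd²) replicate noise in both conditions (sd = 0.25, 3
replicates each). Planted peptides shift by ±delta (default 2) in the
compound condition only. Measurements go missing independently with
probability 0.05. Half-tryptic fragments are not modelled: the screen
consumes only peptide direction and position, so signed shifts on
tryptic peptides overlapping the site are the minimal generative
structure that exercises it.

Protein classes: **targets** carry a protection footprint spanning the
longest run of mutually adjacent retained peptides (at least 8),
alternating up/down so neighbouring peptides always conflict;
**far decoys** carry 2 up and 2 down peptides at opposite ends of the
protein with every cross pair farther apart than `G` (they pass the
both-directions filter but must be rejected by the adjacency rule);
**same-direction decoys** carry co-located same-direction shifts; the
rest are null. A sequence that cannot support its class is redrawn from
the same per-protein stream, so the structure guarantees hold on every
dataset (and are asserted programmatically after generation).

Protein lengths default to 70–110 residues (~5 retained peptides each,
~1000 peptides for 200 proteins). This, and the ≥8-peptide footprint,
were fixed by a prospective power analysis: with n = 3, a Welch p-value
cannot fall much below ~1e-4, so BH across a realistically large peptide
universe (thousands) makes a single planted up/down pair unrecoverable
at any effect size; the benchmark is therefore scaled so that the
planted signature is recoverable with sensitivity ≈ 0.9 at delta = 2,
sd = 0.25, alpha = 0.05, lfc_min = 1 — the screen's intended operating
point. Seeding is hierarchical: one top-level seed, child streams per
protein, so enlarging a simulation never reshuffles existing proteins.

What this synthetic benchmark does **not** emulate: realistic proteome
composition and shared peptides between homologs, intensity-dependent
missingness, correlated peptide noise within a protein, half-tryptic
fragments, and protein-level abundance changes that move all peptides in
one direction. Passing tests demonstrate that the screen's logic and
statistics behave as specified under the stated generative model, not
that the thresholds are optimal for any particular instrument or
organism.

## 2. SMR and HEIDI

Per gene, the exposure is expression with per-SNP effects `b_x` and the
outcome is disease log-odds with effects `b_y`, both with standard
errors on the standardized scale. The instrument is the SNP with maximal
`z_x^2` among those with eQTL `p < 5e-8`; if none qualifies the verdict
is `no_instrument`. The causal estimate is the Wald ratio
`b_SMR = b_y/b_x` with

    T_SMR = z_x^2 z_y^2 / (z_x^2 + z_y^2)  ~  chi^2(1),

`se_SMR` from the first-order delta method (equal to `|b_SMR|/sqrt(T)`
when `b_y != 0`; the delta form is also defined at `b_y = 0`), 95% CI
normal on the log-odds scale and exponentiated to an odds-ratio scale.
`T_SMR <= min(z_x^2, z_y^2)` always and is symmetric in the two z's.

HEIDI instruments are the SNPs (top excluded) with eQTL `p < 1.57e-3`
and `r^2` with the top SNP in [0.05, 0.9], capped at the 20 strongest;
with fewer than 3 such SNPs the HEIDI p-value is absent and the gene is
*not* discarded. For each instrument, `d_i = b_i - b_top` with the
covariance of the `d` vector from the first-order delta method using the
summary SEs and the LD correlations. The statistic is
`T = sum (d_i / sd_i)^2`; under the null it is a correlated quadratic
form whose distribution is approximated by Satterthwaite moment
matching on the eigenvalues of the correlation matrix of `d` (scaled
chi-squared matching the first two moments) rather than exact Davies
inversion — adequate at the 0.01 decision threshold, which the
simulation-based tests verify (single-causal-variant discard rate well
below 5%). Genes with `p_HEIDI < 0.01` are labelled
`pleiotropy_discarded`, applied after the BH adjustment of `p_SMR`
across genes. Allele harmonization is upstream responsibility; the
generator emits harmonized data.

### Synthetic loci

Each locus has `m = 30` SNPs with AR(1) LD (`r_ij = rho^|i-j|`,
rho = 0.6, always positive semidefinite; verified at construction). The
causal eQTL sits in the middle with marginal effect 0.15 sd/allele
(|z| ≈ 27 at the default eQTL sample size); marginal effects at other
SNPs are the causal effect propagated through LD. Causal genes have
`b_y = beta_xy * b_x` (default beta_xy = -0.1); pleiotropic genes add a
second variant two SNPs away with a direct outcome effect of 0.04
log-odds (|z| ≈ 7 at the default GWAS size — a clearly detectable
secondary association, the situation HEIDI exists to catch, with sign
opposing beta_xy so local Wald ratios disagree); null genes set
beta_xy = 0. Estimation noise is LD-correlated, as for real summary
statistics, with `se = 1/sqrt(n)`; the default effective sample sizes
(31,684 eQTL; 32,941 GWAS) mirror a large blood eQTL meta-analysis and
a case-control GWAS of comparable size. At these defaults each gene
yields 4 HEIDI instruments (LD neighbours at distance 1–2 on each side;
distance ≥3 falls below the r² window).

Known approximations: `p_SMR` is slightly conservative because
`T_SMR < z_y^2` at finite instrument strength (the null rate sits just
below 0.05), and delta-method CIs are accurate because the instrument
is strong; both behaviours are measured by the acceptance checks. LD is
simulated, not estimated from genotypes.

## 3. Assay metrics

Trapezoidal AUC over strictly increasing times, total area by default;
an optional baseline-subtract flag computes incremental area (first
value as baseline; may be negative). Respiration metrics from a
phase-labelled OCR trace with contiguous phases in injection order
baseline → oligomycin → FCCP → rotenone/antimycin A:
`non_mito = min(rot_aa)`; `basal = last(baseline) - non_mito` (the last
pre-injection measurement, not the mean, per mito-stress reporting
convention); `atp_linked = last(baseline) - min(oligomycin)`;
`maximal = max(fccp) - non_mito`; `spare = maximal - basal` exactly.
Adding a constant to a whole trace shifts only `non_mito`. An optional
scalar protein content divides the trace (per-well normalization).

## 4. Numerical conventions and edge cases

- Coordinates 1-based, ends inclusive, everywhere.
- Missing intensities are NaN in memory and `NA` on disk, never zeros;
  linear-scale intensities must be strictly positive.
- Welch df computed in a scale-invariant form (weights `v_i/(v1+v2)`)
  so denormal variances cannot underflow; both-groups-zero-variance
  peptides report the limit p (0 for unequal means, 1 for equal) and a
  `degenerate` flag.
- BH is the step-up rule `q_(i) = min_{j>=i} m p_(j)/j`, capped at 1,
  order-preserving; `q >= p` always.
- Screen scores floor p at 1e-300 so degenerate zero p-values keep a
  finite, maximal score.
- Ranking ties break deterministically (gap, then ids); re-running any
  export is byte-identical.
- The Wald-ratio SE uses a hypot form to survive extreme effect sizes.
- Generators are pure functions of (config, seed); identical seeds give
  byte-identical outputs.

## 5. Problem sizes used by the checks

The acceptance script and tests use: 50 simulated screens of 200
proteins for recovery; 20 global-null simulations of 5000 peptides for
FDR calibration; 1000 null and 1000 causal genes for SMR calibration,
recovery and coverage; 200 pleiotropic and 200 single-variant genes for
HEIDI discrimination; 100 random annotated tables against the
brute-force screen oracle. These sizes give Monte-Carlo standard errors
comfortably below the decision margins while keeping a full run under a
minute on one CPU.
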