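# Methods

## Scope and data model

The package models a quantal tumorigenicity assay: graded cell doses are
transplanted subcutaneously into immunodeficient (NOG) mice, which are
palpated weekly over a 16-week horizon. The atomic records are
per-animal outcomes (dose, tumor yes/no, first palpable week), caliper
measurements, and per-specimen teratoma grades; per-line summaries
(integer incidence percent, minimum latency) feed the downstream
correlation stage. Animals tumor-free at the horizon count as
non-responders; the horizon is a per-record field defaulting to 16
weeks.

## Spearman–Kärber TPD50

All computation is on the log10-dose scale. For groups on an equally
spaced grid (spacing d, tolerance 1e-9 on spacing equality) with
response proportions p_i and sizes n_i:

- log-median dose: `m = x_k + d/2 − d·Σ p_i`, summed over all groups
  including dummies. This closed form equals the trapezoid (area) form
  `Σ (x_i + x_{i+1})/2 · (p_{i+1} − p_i)` whenever p_1 = 0 and p_k = 1;
  the equivalence is property-tested over random series.
- variance: `Var(m) = d²·Σ p_i(1 − p_i)/n_i` with divisor n_i (not
  n_i − 1). The n_i divisor reproduces all three bundled reference CIs
  exactly after integer rounding; n_i − 1 does not (e.g. it widens the
  clump-series CI to 177–2617).
- CI: `m ± z·√Var(m)` with z = 1.96, exponentiated base 10. Estimates
  and CI bounds are reported raw and rounded to integer cells (halves
  away from zero).

**Dummy-dose extension.** The estimator requires the design to span
0%→100% response. When the lowest tested dose shows responders, one
dummy group is prepended at dose/10 with 0% incidence; when the highest
dose shows non-responders, one dummy is appended at dose×10 with 100%.
Dummies inherit the adjacent group's n_i; since their p ∈ {0,1} they
never contribute variance, so the inherited size is bookkeeping only. At
most one step per side is ever added — a prepended group has p = 0 and an
appended one p = 1 by construction, so one step always suffices.
Dose-0 control groups are excluded before the grid is built (log 0
undefined; controls carry no information about the median).

Degenerate inputs: a single dose group cannot yield a spacing and is
rejected; a series not spanning the full response range raises rather
than silently extending inside the estimator (extension is an explicit,
flagged step). Non-monotone response series are accepted — the estimator
is defined for them and the closed form still equals the trapezoid form.

## Histology statistics

Teratomas are graded 0–3 by immature neuroepithelium content
(O'Connor–Norris); grade 0 is classified mature, anything above
immature. Grades across lines are compared with the Kruskal–Wallis test
on midranks with the tie-correction factor `1 − Σ(t³−t)/(N³−N)`. The
chi-square approximation (df = groups − 1) is the default, matching
practice at these group sizes and cross-checked against
`scipy.stats.kruskal`; an exact permutation p (exhaustive up to N = 14
pooled observations, seeded Monte-Carlo beyond) is available because
teratoma assays produce very small groups. Singleton groups are retained
(the statistic is defined for n_j = 1); empty groups are dropped with a
warning; an all-constant pooled sample is defined as H = 0, p = 1. Note
the chi-square p can deviate from the exact p by more than a few percent
in heavily tied, mid-range-p configurations at N ≈ 12; the permutation
option exists for exactly those cases.

## Probe selection

The cascade is strictly nested: present-filter ⊇ ANOVA-filter ⊇
selection.

1. **Detection calls.** A probe is kept only when called present (`P`)
   in all samples; marginal (`M`) counts as absent. This mirrors
   microarray "absolute analysis" practice where only consistently
   detected probes are informative.
2. **ANOVA.** One-way fixed-effects ANOVA of intensity on cell line
   (default 10 groups × 3 replicates), retain at p < 0.05. Intensities
   are analyzed on the normalized scale as provided (MAS5-style, target
   intensity 500); a log2 transform is deliberately not applied by
   default. Constant probes are eliminated with a logged note.
3. **Correlation.** Replicates are collapsed to per-line arithmetic
   means (n = 10 lines) — correlating at n = 30 with repeated per-line
   variable values would overstate the effective sample size. Spearman
   rho uses midranks (both variables are heavily tied); p-values use the
   two-sided t approximation with df = n − 2 by default, with a seeded
   permutation alternative. A probe is selected when p < 0.01 against
   **both** latency and incidence, either sign.

At n = 10 the t approximation is anti-conservative near the decision
boundary relative to the exact permutation distribution; the rejection
agreement between the two is logged by the test suite rather than
asserted, because planted benchmark probes concentrate exactly at that
boundary (see below).

## Variant triage

A record survives when all of: VAF > 0.09 (strict — "more than 9%" is
the reliability floor of the sequencing depth used), depth ≥ 40
(inclusive), impact ∈ {HIGH, MODERATE} (the classes predicted to alter
the protein), gene in the curated cancer-gene list (case-normalized
symbols, hyphens preserved), and at least one variant-level COSMIC id.
COSMIC membership is variant-level, not gene-level: a listed gene with
an unlisted variant does not pass. When a variant carries several
transcript annotations the highest-impact one represents it; records
without a gene symbol are dropped with a warning. Relaxing any threshold
can only grow the surviving set (monotonicity is property-tested). VCF
ingest splits multi-allelic sites into one record per alt allele and
takes VAF from FORMAT AF or the AD-derived ratio.

## Synthetic generators

All generators are pure functions of (parameters, seed), emitting the
exact plain-text formats the analysis stages read.

**Dose–response.** One-hit model `P(tumor|D) = 1 − exp(−ln2·D/TPD50)` —
the single-parameter, mechanistically standard model for clonogenic
tumor initiation (P = 0.5 exactly at the TPD50); a logistic-in-log-dose
alternative exists. Default design: 10-fold doses 1e1–1e4. First
palpable weeks for tumor-bearing animals are uniform on 4–9 weeks, the
span observed across the ten reference lines. Because the one-hit curve
is not symmetric on the log grid, the Spearman–Kärber estimand under
this design ("design-discretized target", the closed form applied to the
expected proportions) sits ~0.08 log10 below the true TPD50 at 631; the
recovery benchmark therefore targets the estimand, not the raw truth.

**Expression.** Default 2000 probes, 100 planted, 10 lines × 3
replicates, baseline 500 (the normalization target intensity), within-
line SD sigma = 50 (10% CV, a realistic replicate noise level), planted
effect 3 sigma per unit latent score. The latent tumorigenicity score is
the standardized mean of rank(−latency) and rank(incidence), so planted
probes track both selection variables. Null probes are called present
independently at rate 0.96 per sample (so roughly a third survive the
all-30-samples rule, matching the order of retention seen on real
arrays); planted probes are always present, modeling genes genuinely
expressed in every line.

What the generator does **not** emulate: probe-level mean–variance
dependence, cross-probe correlation, batch effects, or call/intensity
dependence. Passing benchmarks therefore demonstrates the correctness of
the selection machinery under idealized noise, not its power on real
arrays.

**Known limitation — marginal recall.** With the ten reference lines'
variables, the noiseless Spearman correlation of the latent score with
incidence is 0.799 (the printed incidences contain two 4-way ties),
barely above the ≈0.765 needed for p < 0.01 at n = 10. The planted-probe
recall benchmark at effect 3 SD consequently sits right at its 0.9
threshold (about 0.91 on average across seeds, always limited by the
incidence arm, never latency). This is a property of the assay's real
tie structure, not of the implementation.

**Variants.** Records are built arm-by-arm: each `fail_*` arm violates
exactly one criterion and satisfies the rest, so surviving counts equal
the requested `pass_all` counts by construction. VAF is Beta(2,5)
rescaled to the required side of 0.09; depth is Poisson(150) clipped to
≥ 40 for passing records. For records built to fail the depth gate the
depth is drawn uniform on [5, 40): a Poisson(150) conditioned below 40
has mass ~1e-24 and cannot be sampled meaningfully, and a uniform
shallow depth models off-target capture sites. Default per-line pass
counts are drawn from 61–77, the range typical of COSMIC-confirmed
high/moderate-impact variants per line in such screens. A synthetic
613-symbol gene list generator stands in for a curated Cancer Gene
Census-style list (labelled synthetic; only size and set semantics
matter downstream).

## Problem sizes and numerical choices

Test and benchmark sizes are chosen to characterize the methods at desk
scale: 2000-probe matrices for selection rates, 500-record tables for
triage equivalence, 1000 random series for the closed-form/trapezoid
identity, and 500 replicates at 200 animals/dose for estimator recovery.
Grid-equality tolerance is 1e-9 in log10; permutation p-values use the
add-one Monte-Carlo estimator; rounding of reported doses and percents
is half-away-from-zero. Randomness always flows from a single
`numpy.random.default_rng(seed)` per generator invocation.

## Pipeline and provenance

`teratopd run` executes the configured stages in a fixed order; every
output carries the package version and a SHA-256 prefix of the
configuration, so identical config + seed re-runs are byte-identical.
Malformed input rows are reported with file and row number; the only
silent-looking drops (missing gene symbols, empty specimen groups) are
logged.
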