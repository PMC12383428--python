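# Methods

## Scope and model

`mrscreen` implements a proteome-wide two-sample Mendelian randomization
(MR) screen with downstream mediation, network and enrichment stages. The
causal model is the standard instrumental-variable DAG: genetic variants G
affect a plasma protein X (relevance); G is independent of confounders of
X and the outcome Y (independence); and G affects Y only through X
(exclusion restriction). For mediation, a second path X → M → Y through an
immune-cell trait M decomposes the total effect θ_total into a direct part
θ_dir and an indirect part β₁β₂.

All estimation is summary-level: the package consumes per-variant
(beta, se, EAF, p, N) tuples, never genotypes. Binary-outcome effects are
log-odds per unit exposure and reported as odds ratios.

## Instrument selection

Defaults follow common pQTL-MR practice: genome-wide significance
p < 5×10⁻⁸ for forward instruments (5×10⁻⁵ for the rare outcome in the
reverse direction), greedy LD clumping to pairwise r² < 0.001, and
exclusion of instruments with F < 10, where R² = 2·EAF·(1−EAF)·β² and
F = R²(N−2)/(1−R²). Boundary semantics are strict (`p < threshold`,
`F < 10` excluded, `r² ≥ cutoff` discarded), so survivors satisfy the
published inequalities verbatim. All orderings are canonical (ascending
p-value, ties by variant id), making selection a pure function of its
inputs. The LD matrix is supplied by the user or the simulator; no
reference-panel retrieval is performed, since the clumping algorithm — not
the panel — is the computation of interest. EAF and N are taken from the
exposure table itself.

## Harmonization

The outcome record of each shared variant is aligned to the exposure's
effect allele: matching pairs pass through, swapped pairs negate the beta
and complement the frequency, and non-palindromic pairs that only match
through strand complement are complemented first. Palindromic variants
(A/T, C/G) cannot be resolved from alleles; when the exposure EAF lies in
0.5 ± 0.08 (band configurable) they are dropped as ambiguous, otherwise
orientation is inferred by frequency concordance. This is the conservative
default of mainstream two-sample MR tooling; the band is a design choice,
as the source analysis does not describe its harmonization.

## Estimators

Wald ratio for one instrument; fixed-effect IVW for two or more, with the
single-instrument case routed to the Wald ratio. The Wald SE uses the
first-order delta method (exposure-side noise ignored), matching dominant
practice. IVW weights are β̂_X²/se_Y², equivalent to the intercept-free
WLS slope of β̂_Y on β̂_X with weights 1/se_Y² (the test suite asserts
this equivalence against an independent WLS fit on every simulated
dataset). Cochran's Q and its χ² p-value are always reported for n ≥ 2; a
multiplicative random-effects mode inflates the SE by √max(1, Q/(n−1)) and
is off by default. P-values are two-sided normal throughout, consistent
with the OR/CI/p round-trips of published rows.

## Reverse screen and its known failure mode

Reverse causation is screened by running MR in the outcome→protein
direction using outcome instruments at p < 5×10⁻⁵ and flagging proteins
with reverse p < 0.05 (flag threshold a design choice; the source is
qualitative). A genuine limitation, reproduced deliberately: a
forward-causal SNP can reach the outcome instrument threshold through the
forward path and then flag its own protein, because the naive screen
cannot orient a SNP associated with both traits. Steiger-style
directionality filtering would resolve this but is intentionally out of
scope; users should treat reverse flags as conservative exclusions, which
is how the mediation stage consumes them.

## Mediation

indirect = β₁β₂, direct = total − indirect (exact by construction up to
one ulp), proportion mediated = indirect/total. SE of the product by
first-order delta method (β₁²se₂² + β₂²se₁²); the exact product-normal
term se₁²se₂² is available behind a flag. A zero total effect yields a
flagged result with a null proportion rather than an exception;
sign-discordant and out-of-[0,1] proportions are flagged, not suppressed.
The scan gates each triple on total p < 0.01 and step p < 0.05 (defaults,
configurable) and ranks unflagged results by |proportion mediated|.

Step-2 (mediator→outcome) instruments exclude SNPs genome-wide significant
for the exposure: shared exposure instruments would otherwise contaminate
β₂ with θ_dir/β₁. For the same identification reason the simulator
includes mediator-specific instrument SNPs; without them the mediator has
no valid instruments whenever θ_dir ≠ 0.

## Simulator: what it emulates, and what it does not

`simulate_study` draws true pQTL effects from N(0, sd²) (default sd 0.1,
a realistic plasma-pQTL scale), null SNPs at zero, and estimated effects
as truth plus N(0, se²) noise with the analytic SE
1/√(2·maf·(1−maf)·N). The binary outcome uses the effective case-control
size n_eff = 4/(1/n_cases + 1/n_controls); defaults mirror the real data
the screen targets (protein GWAS N = 35,553; outcome 633 cases / 427,278
controls, n_eff ≈ 2,528). LD is emulated with tag blocks: tags share the
head SNP's frequency, true marginal effects scale by r = √r², and
sampling noise is correlated at r — the standard result for z-statistics
of variants in LD. Identical configs are bit-reproducible.

Not emulated: haplotype-level LD, population stratification, sample
overlap between the two samples, winner's-curse-free discovery (selection
on the simulated exposure does impose a small regression-dilution bias,
visible as ~1% attenuation at default settings), and non-collapsibility of
the odds ratio. A green recovery test therefore establishes correctness of
the estimators under the stated sampling model, not robustness to those
real-data features.

### Power-analysis choice of the mediation test world

The recovery checks for mediation use β₁ = 0.5, β₂ = 0.6, θ_dir = 0.15
(proportion mediated 2/3) at n_exp = n_med = 50,000. These values were
fixed by power analysis before freezing the tests: the scan conditions on
its significance gates, so the total effect must be near-fully powered
(z ≈ 7 at the rare-outcome SE ≈ 0.065) for a median-recovery check to
measure the estimator. An underpowered world (β₁β₂ ≈ 0.15, z ≈ 2.3) makes
the conditional median reflect winner's curse at the gate — an artefact of
the gate, not an estimator property.

## Numerical choices

- Floats are serialized with `repr`, so table round-trips are bit-exact.
- P-values are clipped into (0, 1]; `2·Φ(−|z|)` can round to 0 only beyond
  float range.
- The additivity identity direct + indirect = total is exact except for
  one ulp of the largest operand (catastrophic cancellation when
  |indirect| ≫ |total|); tests assert at that precision.
- BH adjustment is delegated to statsmodels; the hypergeometric tail to
  scipy. Both are cross-checked against exhaustive enumeration on small
  universes in the test suite.
- The enrichment universe defaults to the union of gene-set members and
  the query, overridable; the adjustment method (BH) is a field-default
  choice, as the source names only "adjusted p".
- Pipeline reports avoid timestamps so identical (inputs, config, seed)
  runs are byte-identical.

## Known limitations

Single-mediator decomposition only (no multivariable MR); no pleiotropy-
robust estimators (Egger, median, mode) — pleiotropy in the simulator is
additive-random and InSIDE-satisfying, used only to stress the IVW; no
proxy-SNP lookup or kb-window clumping; INDELs unsupported; the reverse
screen's directionality blind spot described above.
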