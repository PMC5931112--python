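# Methods

## Model and estimator

The package implements two-sample summary-data MR. Exposure-SNP effects
b_zx (in SD units of a standardised quantitative trait, or log OR for a
binary exposure) and outcome-SNP effects b_zy (log OR of a case-control
outcome) come from non-overlapping studies and are combined per SNP into
Wald ratios b_xy = b_zy/b_zx, with first-order delta-method variance
se_zy²/b_zx² + b_zy²·se_zx²/b_zx⁴. The pooled causal effect is the
generalised-least-squares solution under the ratio covariance
C_ij = r_ij·se_xy,i·se_xy,j, where r_ij is the allelic LD correlation. This
covariance is a first-order approximation that treats the exposure effects
as well estimated; it becomes exact as instrument strength grows, which is
the regime instrument QC is designed to ensure (per-SNP |Z| well above the
genome-wide threshold of 5.45). With identity LD the estimator collapses to
the inverse-variance-weighted mean — a reduction that the test suite checks
against an independently coded IVW oracle to 1e-10.

The model assumes each instrument affects the outcome only through the
exposure. Violations (horizontal pleiotropy) are screened by the
HEIDI-outlier test: with reference SNP ref chosen as the top exposure
association, each deviation d_i = b_xy,i − b_xy,ref has variance
se_xy,i² + se_xy,ref² − 2·r_i,ref·se_xy,i·se_xy,ref and d_i²/var(d_i) is
referred to χ²₁; SNPs below the removal threshold (default P < 0.01) are
excluded in a single pass before re-estimation. Iterating removal to a
fixed point is available (`iterate=True`) but off by default, matching the
single exclusion round reported for the glioma analysis.

Two properties of reference-based HEIDI worth knowing: the reference SNP
itself can never be flagged, so pleiotropy located on the top associated
variant escapes the filter; and because every deviation shares the
reference SNP's sampling error, deviations are positively correlated — an
unlucky reference draw occasionally produces several simultaneous flags in
a panel with no true pleiotropy. Both behaviours are visible in the
synthetic-study tests and are inherent to the method, not defects of the
implementation.

## Instrument QC

Selection filters exposure records at P ≤ 5×10⁻⁸ (inclusive boundary), then
prunes to pairwise r² < 0.01 by a greedy strongest-first rule. "Strongest"
is a total order: smallest exposure P, then largest |beta|, then
lexicographic SNP id — making selection deterministic and
input-order-invariant; the unit tests verify the greedy output against an
exhaustive rank-minimal maximal-independent-set search on a 10-SNP panel.
SNPs absent from the LD matrix may be routed through proxy SNPs; proxies
substitute LD rows only, never association statistics. Harmonisation
re-signs outcome effects onto the exposure effect allele, complements
alleles across strand flips, resolves palindromic (A/T, C/G) SNPs by allele
frequency only when the minor-allele frequency is below 0.42 in both
studies and the frequencies agree after orientation (within 0.2), and drops
them otherwise — a conservative default for a decision the underlying
studies rarely document.

Instrument strength is summarised as PVE = Σ 2p(1−p)b² (assuming unit trait
variance, hence undefined for binary exposures) and the first-stage
F-statistic ((n−k−1)/k)·(PVE/(1−PVE)).

## Evidence evaluation

Power for a binary outcome uses the non-centrality
λ = |ln OR|·√(N·PVE·φ(1−φ)) with both rejection tails, so power at OR = 1
equals α exactly. The Monte-Carlo cross-check in the tests simulates Wald
tests on ratio estimates drawn from the same asymptotic model; it validates
the analytic formula's algebra, not the asymptotics themselves.

Null results are graded by the Wakefield approximate Bayes factor
BF = √((V+W)/V)·exp(−Z²W/(2(V+W))), the ratio of the marginal likelihood of
the estimated log OR under the null to that under a N(0, W) alternative.
W is calibrated so that a stated "maximum likely OR" — the largest effect
reported observationally, defaulting to 2 where none exists — is the 97.5th
prior percentile: W = (ln OR_max/1.96)², with protective ORs entering
through |ln|. The minimum prior probability of association keeping
BFNP = 1 − BFDP above τ (default 0.1) is π = τ·BF/(τ·BF + 1 − τ). Applied
to the published all-glioma ORs and CIs, this reproduces eight of the ten
published minimum priors to 2 dp; the HDL and triglycerides rows (0.66 vs
0.64 and 0.61 vs 0.60) are sensitive to the 2-dp rounding of their very
narrow printed CIs, and the published values were evidently computed from
unrounded estimates, so those two rows are reported but not asserted.

## Synthetic studies

The generator draws effect-allele frequencies uniformly (default 0.1–0.9),
per-SNP true effects with magnitudes uniform on [0.5, 1.5] × scale and
random signs, the scale set so the panel PVE hits its target; observed
effects add noise with the standard errors 1/√(2p(1−p)·n) (exposure) and
1/√(2p(1−p)·N·φ(1−φ)) (case-control outcome, case fraction φ), correlated
across SNPs by the same block-LD matrix used for pruning — this shared
structure is what makes HEIDI's covariance term meaningful. Planted
pleiotropic SNPs receive a direct log-OR offset (one-sided or
sign-balanced). All randomness flows through one seeded generator.

Defaults mirror the glioma study design: 12,488 cases and 18,169 controls;
an exposure study of 200,000 (consortium scale — the source meta-analyses
range from tens of thousands to several hundred thousand); panel PVE 5%,
mid-range of the published panels (0.7–15%). The magnitude floor of 0.5
keeps every instrument strong (per-SNP F ≫ 10), matching the published
observation that weak instruments were confined to the WHR panel; the
generator therefore does not exercise weak-instrument bias, and passing
recovery tests say nothing about that regime. Other features of real data
deliberately not emulated: genome-wide LD beyond constant-r blocks, allele
frequency mismatch between studies, sample overlap, winner's curse in
instrument discovery, and population stratification.

The multi-trait run writer (`write_run`) produces a 10-trait × 3-outcome
study shaped like the glioma analysis (one outcome plus two subtype
outcomes sharing true effects with independent noise) and deliberately
exercises every exclusion path: each panel carries one correlated SNP pair
(pruned), the first trait's last SNP is absent from the outcome files, the
second trait sits at the significance boundary (per-SNP |Z| ≈ 5.5, so part
of its panel fails the 5×10⁻⁸ filter), and the fourth trait is flagged
binary.

## Numerical choices

- CI multiplier fixed at 1.96; evidence tiers at P ≤ 0.05 (potential) and
  P ≤ α/(traits × outcomes) (significant), the Bonferroni divisor computed
  from the run configuration (0.05/30 ≈ 0.0017 for the 10×3 design).
- The GLS solve uses a Cholesky factorisation; a condition number above
  1e12 raises a singularity error advising a stricter pruning threshold.
- LD matrices must be symmetric within 1e-8 and PSD within −1e-8 on the
  smallest eigenvalue; |r| may exceed 1 only by 1e-12 (clipped).
- Simulated P values are floored at 1e-300 to stay within (0, 1].
- Wald P values for the pooled estimate use the standard normal; HEIDI
  P values use χ²₁.
- Test problem sizes (500 replicates for recovery/calibration, 200 for
  HEIDI detection, 30-SNP panels) give Monte-Carlo error comfortably below
  the asserted tolerances while keeping the suite fast.

## Known limitations

- Single-reference HEIDI as described above; no multi-reference or
  model-averaged variant.
- No MR-Egger, weighted-median or mode-based sensitivity estimators, no
  multivariable MR, no Steiger filtering.
- The ratio-covariance approximation ignores second-order terms in weak
  instruments; the estimator is not debiased for winner's curse.
- LD must be supplied (or proxied); the package does not compute it from
  reference genotypes.
- rsID merge histories are not resolved; instruments are matched by
  identifier string only.
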