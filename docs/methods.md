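# Methods

## Model

A fixed universe of *n* annotation terms is given (the package never
queries an ontology; the caller decides which terms are in play, e.g. all
GO terms of one level of one ontology). For a pair of feature lists, each
term independently falls into one of four joint-enrichment states with
probabilities p = (p11, p01, p10, p00), p00 = 1 − (p11 + p01 + p10); the
observed table (n11, n01, n10, n00) is a single Multinomial(n, p) draw.
The independence-across-terms assumption is an idealisation — real GO
terms overlap through the DAG and through shared annotations — and is
exactly what the simulation engine emulates; passing simulations therefore
validate the test's calibration under the multinomial model, not under
arbitrary real-world term dependence.

The dissimilarity is d_S(p) = 1 − 2p11/(2p11 + p10 + p01) ∈ [0, 1],
which ignores p00. d_S = 0 iff the discordant mass vanishes (with
p11 > 0); d_S = 1 iff p11 = 0.

## Estimation and asymptotics

The plug-in estimator uses p̂_ij = n_ij/n. By the delta method,
√n (d̂_S − d_S) → N(0, σ²_S) with

σ²_S = 4 p11 (p01 + p10)(p11 + p01 + p10) / (2p11 + p01 + p10)⁴,

estimated by substituting p̂. The implementation normalises critical
values to the positive convention: the one-sided upper limit is
d_u = d̂_S + z_{1−α} σ̂_S/√n, numerically identical to subtracting the
negative lower α-quantile. Confidence limits are reported **unclipped**
(d_u may exceed 1, the two-sided lower limit may be negative) because the
equivalence decision compares d_u with d0 on the real line; a clipped
display variant exists (`confidence_interval(..., clip=True)`).

Degenerate tables: when n11 = 0 (d̂ = 1) or n10 + n01 = 0 (d̂ = 0), the
variance estimate is zero and the studentized statistic does not exist.
`sorensen_estimate` still returns the point estimate, flagged
`degenerate`; both test routes raise the typed `UndefinedSorensenError`,
which the bootstrap and simulation layers catch, excluding the replicate
and decrementing their effective counts. When every enrichment cell is
zero, d_S itself is a 0/0 form and the error is raised immediately.

## Equivalence test

H0: d_S ≥ d0 vs H1: d_S < d0. Normal flavour: p(d0) = Φ(t), with
t = √n (d̂_S − d0)/σ̂_S; reject iff p ≤ α, which coincides with the
interval-inclusion rule d_u < d0 except on the probability-zero boundary
t = z_α, where both are derived from the same statistic so the two
routes can never return different decisions.

d0 has **no default** — it is a scientific choice. The ρ-calculus
(`d0_from_rho` / `rho_from_d0`) converts a lower bound on the
concordance ratio into a limit: d_S = 1/(1+ρ) for ρ = 2p11/(p01+p10)
("double", mirroring the index's double-counting of p11) or
d_S = 1/(1+2ρ) for ρ = p11/(p01+p10) ("single"). The bounds 10/8 and
10/9, borrowed from bioequivalence practice, give 0.4444/0.4737 and
0.2857/0.3103 respectively.

## Studentized bootstrap

B tables are resampled from Multinomial(n, p̂) in a single vectorized
pass of one seeded generator (so discarding invalid replicates cannot
perturb the stream of the rest), and the studentized values
√n (d_S(p̂*) − d_S(p̂))/σ̂*_S are retained where defined
(B_effective ≤ B). Resampling at the full size n makes the bootstrap
statistic the exact plug-in analogue of the original statistic; the
two-stage alternative (ν* binomial, then a conditional multinomial split)
is provided as `generate_table_twostage` and is property-tested to be
distributionally identical to the one-shot draw.

Conventions, chosen so that the p-value and quantile routes are *provably*
the same decision:

- p-value: (#{stats ≤ t_obs} + 1)/(B_eff + 1) — the standard conservative
  bootstrap p-value, never exactly zero;
- quantile: the m-th order statistic with m = floor(α (B_eff + 1)).
  Then p ≤ α ⇔ t_obs < stats_(m) ⇔ d_u < d0 exactly, ties included.
  An interpolated (type-7) quantile would differ from the p-value route in
  an O(1/B) boundary band, so it is not used for the decision. If m = 0
  (α below the bootstrap resolution, α < 1/(B_eff+1)), the test cannot
  reject and d_u is +∞.

Resampling the underlying gene lists themselves (rather than the table) is
out of scope: it would re-run the entire enrichment pipeline per replicate.

## Multiple lists

`pairwise_tests` runs all s(s−1)/2 pairs or the s−1 comparisons against a
reference, then adjusts raw p-values by Holm's step-down (default; FWER
control under arbitrary dependence, uniformly better than Bonferroni) or
Benjamini–Hochberg for large families. Reject flags derive from
p_adj ≤ α. Pairs with undefined statistics are excluded from the family
size h and reported separately — the alternative (counting them as
non-rejections) would silently shrink every adjusted p-value's meaning.
Ties in p-values are broken by stable input order.

`mantel_correlation` compares two triangular matrices of test outputs
(e.g. upper confidence limits from two methods over the same lists):
Pearson correlation of the vectorized lower triangles, with a two-sided
permutation p-value over list relabelings — random with the
(hits+1)/(perms+1) convention, or exact over all s! relabelings for
small s.

## ORA front-end

Per term, the one-sided hypergeometric tail P(X ≥ a) for the overlap a
between the list and the term's annotated genes inside an explicit,
caller-supplied universe (no organism default; a convenience flag uses the
union of GMT annotations). Adjustment across the collection's terms is
Bonferroni by default (BH optional) with cutoff 0.05 on the adjusted
p-value. This is deliberately a plain, reproducible ORA: tool-specific
refinements (gene-set size filters, q-value estimation) found in
enrichment suites are not replicated, so incidence matrices produced here
need not match any particular annotation snapshot of those tools.

## Simulation engine

Scenarios cross n, (p01, p10), d0 and a target dissimilarity; p11 is
derived from the target via p11 = (1 − d_S)(p10 + p01)/(2 d_S), the exact
solution of the index equation, so scenarios sit exactly on (type-I
error) or off (power) the boundary. E(ν) = n(p11+p01+p10), the expected
enriched-term count, is the effective sample size that governs asymptotic
accuracy and is reported with every result row.

Default scales, chosen to keep a full check desk-sized while leaving
Monte-Carlo error well below the effects of interest: 10⁵ replicates for
normal-test scenarios (MC SE ≈ 0.0007 at rates near 0.05) and
2×10³ simulations × 2×10³ bootstrap replicates for bootstrap scenarios
(MC SE ≈ 0.005). The normal path is fully vectorized (one multinomial
call for all replicates); the bootstrap path vectorizes within each
replicate. Grids expand one master seed into per-scenario child seed
sequences (spawn-key indexed), so results are reproducible and
independent of scenario order, and per-scenario failures are recorded in
an `error` column without aborting the sweep.

The synthetic gene-list generator plants a known incidence pattern: each
planted term takes `round(effect_strength · term_size)` of its genes from
the target list(s) and fills up from genes outside both lists; null terms
draw entirely outside both lists. With the defaults (universe 2000,
lists of 100, terms of 20, effect 0.75) planted terms carry overwhelming
hypergeometric evidence and recovery is essentially deterministic — the
generator exercises the pipeline end-to-end with known truth, it does not
emulate the marginal annotation-frequency structure of a real ontology.

## Known limitations

- Both flavours are intrinsically asymptotic in E(ν): with very sparse
  enrichment the normal test over-rejects and the bootstrap tends to
  conservatism; neither is an exact small-sample test.
- The multinomial model treats terms as independent; real ontology terms
  are not.
- Enrichment status inherits every upstream decision (universe, cutoff,
  adjustment), which adds un-modelled uncertainty to the table itself.
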