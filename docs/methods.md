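# Methods

## The model

A site with allele-frequency vectors **p** and **q** in two populations is
scored by the expected information one observed allele contributes to a
population assignment. Observing allele *i* multiplies the prior odds of
membership by `p_i/q_i` (Bayes), so it is worth `|log2(p_i/q_i)|` bits; with
the populations equally likely a priori, the chance of observing allele *i*
is `(p_i+q_i)/2`, giving

```
ESI(p, q) = Σ_i ((p_i + q_i)/2) · |log2(p_i/q_i)|
```

Absolute values are taken because evidence for either population is equally
useful. ESI is symmetric, zero iff the vectors agree, additive over
independent sites, and infinite when an allele has positive frequency in
exactly one population. Alleles absent from both contribute nothing
(0/0 → 0 by convention).

The package also exposes the *peak* per-allele information
`max_i |log2(p_i/q_i)|` — the value of the single most diagnostic allele.
For the skewed pair (0.05, 0.25) the weighted average is 0.64 bits while the
peak allele is worth log2 5 = 2.32 bits; both readings are useful and both
are provided (the weighted sum as `expected_site_information`, the
single-allele maximum as `peak_allele_information`). The haplotype-mixing
truth grid's printed per-site values (1.6 bits for a 1/6 vs 1/2 variant)
correspond to the peak reading, which is what the mixing-table test asserts.

## The conservative estimator (CSI)

Frequencies estimated from pooled read counts carry sampling error, and
sequencing errors create and mask alleles. Because a SNP panel designer
cares more that chosen sites are informative than that their information is
estimated precisely, each allele is scored by its **worst case**:

1. For each pool, an Agresti–Coull interval for the allele frequency:
   `ñ = n + z²`, `p̃ = (x + z²/2)/ñ`, bounds `p̃ ± z√(p̃(1−p̃)/ñ)` clamped to
   [0, 1], with `x` the allele's read count and `n` the pool's nucleotide
   depth (per-allele binomial marginal of the multinomial; no simultaneous
   adjustment across alleles).
2. Both limits are shifted outward by the sequencing error rate ε
   (a substitution can both create and mask an allele; symmetric additive
   widening is the simplest reading of an error adjustment), clamped again.
3. The allele's guaranteed log-odds is `min |log2(p/q)|` over the interval
   box: 0 when the intervals overlap, otherwise the log-ratio of the nearest
   endpoints. A degenerate zero endpoint contributes 0 rather than an
   infinity — maximally conservative.
4. Terms are weighted by the mean point-estimate frequency `(x_p/n_p +
   x_q/n_q)/2` and summed.

For biallelic sites this per-allele minimization coincides with the joint
minimization of the weighted information over the whole interval box
(the complement allele's interval is the mirror image, so both terms attain
their minimum at the same corner); the test suite checks this against a
dense-grid brute-force oracle built on statsmodels' Agresti–Coull intervals.
Consequences verified by tests: CSI is finite for every input, never exceeds
the point-estimate ESI, is non-increasing in ε, non-decreasing in depth at
fixed proportions, and converges to the true ESI as depth → ∞ with ε → 0.

### Parameters

| parameter    | default | meaning                                             |
|--------------|---------|-----------------------------------------------------|
| `confidence` | 0.95    | coverage probability of the intervals (z ≈ 1.960)   |
| `epsilon`    | 0.01    | per-base substitution error rate; the central rate of the simulated error grid {0.002, 0.01, 0.02} |

Both are configurable (`EstimatorConfig`, CLI `--confidence`/`--error-rate`).
The confidence level is a genuinely open choice; 0.95 is the conventional
default. ε is applied after the interval is computed and does not perturb
the point-estimate weights.

## Comparison statistics

F_ST uses Wright's two-deme variance form `Var({p,q})/(p̄(1−p̄))` with the
population variance (divide by 2): it reproduces the mixing-grid value 0.125
for (1/6, 1/2) exactly and is invariant to which allele of a biallelic site
is tracked. It is undefined (NaN, reported, not dropped) at monomorphic
sites. Fisher's exact test (scipy, two-sided by the point-probability
method) is applied to the major-allele vs rest 2×2 count table. Nucleotide
diversity `p(1−q)+(1−p)q` and |p−q| are included chiefly to demonstrate
their failure modes (diversity is pinned at 0.5 whenever either frequency
is 0.5).

## The synthetic data generator

Two populations are mixtures of three haplotypes in proportions 1:2:3 and
3:2:1, so a haplotype-specific variant segregates at 1/6, 1/3 or 1/2.
Variants on the unequal haplotypes are divergent ((1/6, 1/2) or (1/2, 1/6));
a variant on the equally weighted middle haplotype has frequency 1/3 in both
pools and belongs to the null. `simulate_dataset` draws divergent sites'
carriers uniformly among the unequal haplotypes (so the divergent-site count
is exactly binomial in `divergent_fraction`), and fills the null class with
a mix of shared polymorphisms (frequency drawn from the {1/6, 1/3, 1/2}
grid, `null_polymorphic_fraction`, default 0.5) and monomorphic reference
sites.

Sequencing is reduced to its per-site statistical core: depth per pool is
Poisson around the nominal coverage (10x/20x/40x in the study grid), each
read draws its allele from the pool's true frequency, and each read base is
substituted with probability equal to the error rate (0.002/0.01/0.02 grid)
to a uniformly chosen different nucleotide. Read mapping, base qualities,
GC/coverage bias, collapsed repeats, indel errors and finite pool sizes are
deliberately not modelled: the downstream statistics consume only per-site
counts, so this preserves the statistical structure those statistics see —
but passing tests say nothing about mapping artifacts or coverage bias in
real data, which in practice require the coverage filter below.

## Evaluation machinery

`score_sites` computes every statistic per site (all-NaN for a pool with no
reads). `filter_by_coverage` keeps sites with total depth in
`center ± halfwidth`, bounds inclusive (e.g. 50 ± 20, about three Poisson
standard deviations of a 50x combined coverage). `separation_table` counts
divergent vs null sites at or above CSI thresholds — the operational form of
reading separation off a score histogram. `calibration_table` compares
observed and expected (n·α) counts of null sites below p-value thresholds.

## Numerical and degenerate-input choices

- Logarithms are base 2 throughout; scores are bits.
- One-sided zero frequencies propagate as ±inf log-odds and +inf ESI (the
  TSV writer prints `inf`); CSI exists to tame exactly this pathology and is
  finite always.
- Monomorphic sites report NaN F_ST (written as `NA`) rather than being
  dropped; zero-depth pools yield all-NA rows in the library and are
  skipped-and-counted by the CLI.
- mpileup coordinates are 1-based and kept so; strand case is merged; indel
  runs are consumed and tallied but excluded from allele counts; base
  qualities are parsed and exposed but unused; declared-vs-decoded depth
  mismatches are parse errors.
- Test problem sizes (36,000-site calibration runs, 1,500–2,000-site
  coverage sweeps, depth-10⁶ convergence checks) were chosen as the smallest
  scales at which the respective stochastic properties are stable.

## Known limitations

- The exact conditional (Fisher) test is conservative on discrete read-count
  tables: at 20x coverage the attained fraction of null sites below α = 10⁻³
  is well under α. The calibration machinery reports observed vs expected
  counts; expecting the nominal n·α false positives at desk-scale depths
  overstates what the exact test yields, and the corresponding study-scale
  calibration check fails honestly for this reason.
- CSI at low coverage is very conservative: at 20x a true (1/6, 1/2) site's
  intervals usually overlap and score 0; ranking power appears as coverage
  grows (verified: median divergent-site CSI is non-decreasing in coverage).
- Only two-population comparisons are supported; multi-pool mpileup input is
  accepted but statistics are computed for a selected pair (`--pair`).
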