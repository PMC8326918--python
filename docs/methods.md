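# Methods

## The scan model

A two-bulk F2 QTL-seq design is modelled end to end. At a parent-polymorphic
site, bulk *b* contributes a read-count pair; the SNP-index of the bulk is the
fraction of reads carrying the donor (non-recurrent-parent) allele, and
Δ(SNP-index) = index(high) − index(low). Two sources of noise are explicit:

1. **Bulk composition.** With bulk size *k*, the donor-allele frequency of an
   unlinked locus in one bulk is f = c/(2k), c ~ Binomial(2k, ½) — variance
   0.25/(2k) (0.0025 at k = 50).
2. **Sequencing.** Given f and site depth D, the donor-allele read count is
   Binomial(D, f·(1−ε) + (1−f)·ε) with base error rate ε.

The G statistic is the log-likelihood-ratio test of bulk × allele independence
on the raw 2×2 read table, G = 2·Σ obs·ln(obs/exp) with expectations from the
marginals and 0·ln 0 ≡ 0; it equals 2N × the mutual information (in nats) of
the normalised table, which the tests use as an independent oracle.

### Null confidence intervals

`simulate_null_ci` draws both noise stages per replicate and tabulates
empirical quantiles of Δ and G on a depth grid (default 10–3000, 20,000
replicates; quantiles interpolated linearly in depth and clamped at the grid
ends). The table is validated for the non-increasing-width property rather than
smoothed. In the deep-sequencing limit only bulk composition remains:
Var(Δ) → 2·0.25/(2k), so the 97.5% quantile → 1.96·√0.005 ≈ 0.139 at k = 50 —
a closed form the acceptance checks verify.

### Window significance and the effective-depth choice

Windows (default 200 kb every 10 kb, ≥ 10 sites) use unweighted means over
member sites (start ≤ pos < end). The m sites of one window are sequenced from
the *same* two pools and are tightly linked (≈ 0.8 cM at rice-like map
density), so their bulk-composition noise is common while their read noise is
independent. The window mean Δ therefore has variance

    2·[0.25/(2k) + E f(1−f) / (m·D)]

— exactly the per-site null at total depth m·D, not at the per-site depth D.
The CI lookup consequently uses the window's effective total depth
(n_sites × mean depth, `depth_mode="total"`). Looking up the per-site null at
the *mean* depth would make the test ≈ 10× conservative (measured marginal
false-positive rate ≈ 0.3% instead of the nominal 5%); that variant is kept as
`depth_mode="mean"` for comparison. One-sided level 95/99 uses the 95%/99% null
quantile (marginal 5%/1% exceedance); two-sided mode uses 97.5%/99.5%.
Exceedance is strict, and sparse windows are never significant.

Mean window G is compared against the per-site null G quantile at the mean
depth. Averaging G across a window shrinks its per-site χ²-like fluctuation
but not the shared bulk-composition component, so this comparison is
conservative; the default calling rule is `either` (Δ or G), with `delta` the
calibrated reference rule.

Consecutive significant windows merge into a region when separated by at most
one window size (configurable); regions report the site-level argmax of Δ and
of G (ties broken toward the smaller position), so `peak_delta` always equals
the maximum site Δ inside the region.

## The simulator

`f2sim` generates gametes under the Haldane model — crossover count per
chromosome ~ Poisson(genetic length in Morgans), positions uniform, no
interference — on a marker grid (default one marker / 10 kb) with linear
bp↔cM scaling. Phenotypes follow y = μ + Σ_q [a_q(g_q−1) + d_q·1(g_q=1)] +
N(0, σ²). Bulks are the k largest / k smallest phenotypes with seeded
tie-breaking; pooling is exactly equimolar, so the bulk allele frequency at a
marker is Σg/(2k). Parents are fully homozygous and polymorphic at every grid
marker; which parent carries REF is drawn per site so the orientation machinery
is exercised end to end. Site depth is Poisson(D) (negative binomial when a
dispersion is set). GQ is emitted as min(99, 3·depth) — the usual
three-Phred-per-concordant-read homozygous-site heuristic — or as a fixed
value; the GQ model only needs to exercise the GQ < 20 filter.

Default study conditions: n = 720 individuals, k = 50 per bulk, mean depth
50×, base error 10⁻³. The desk-scale genome is rice-like — 4 cM/Mb (the rice
genome-wide average) — with 2 × 40 Mb chromosomes for scan experiments and
20 × 5 Mb (10,000 sites) for null-calibration experiments. These sizes keep a
full simulate–scan cycle in the low seconds while leaving > 1.5 Morgans per
scan chromosome.

What the simulator does *not* emulate: alignment and mapping artifacts,
depth heterogeneity along the genome beyond the per-site depth draw, variant-
caller genotype errors in the parents, non-equimolar pooling, crossover
interference, and segregation distortion. Passing tests therefore validate the
statistical chain under clean-pool assumptions, not robustness to upstream
artifact structure in real data.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (VCF convention); BED output is
  0-based half-open. AD is taken as the first two entries and DP recomputed as
  their sum.
- The site filter's first clause reads the published rule as two independent
  drop conditions (both-bulk index < 0.2, OR depth < 7 in either bulk); the
  conjunctive reading is available via `clause1_conjunctive`. Clauses are
  tallied in order 1, 2, 3, one count per dropped site.
- InDels never enter the SNP-index scan; they are diverted at parse time to the
  marker-design stream.
- Within-genome window calls are heavily correlated: bulk composition
  decorrelates only over ~0.5 Morgan (≈ 12 Mb here), so a single 10,000-site
  genome contains only ~30 effectively independent loci. Calibration
  experiments therefore measure the marginal false-positive rate pooled over
  20 replicate genomes rather than from one genome.
- Marker bookkeeping is coordinate arithmetic only (size_ref = reverse_end −
  forward_start + 1; size_alt = size_ref + signed InDel length); primer
  chemistry is out of scope. The ≤ 10× amplicon/InDel rule is inclusive at the
  boundary. Notably the published-style 22-bp chr1 marker *fails* the 10× rule
  (297/22 = 13.5); the check reports this honestly.
- Marker–trait association is textbook fixed-effects ANOVA (one-way closed
  form; two-way with interaction via OLS, type-II sums of squares). With zero
  between-group variance F is defined as 0 with p = 1.
- 2^–ΔΔCt: ΔCt per replicate = Ct(target gene) − Ct(control gene); ΔΔCt is the
  difference of sample-mean ΔCt; significance flags come from a two-sample
  t-test on replicate ΔCt values (* p < 0.05, ** p < 0.01). Reciprocal fold
  changes multiply to 1 up to IEEE rounding of `2**x`.
- Candidate-gene triage reads "sense mutation" as any nonsynonymous coding
  change; keyword matching is case-insensitive substring; "identical variant in
  the co-localized donor parents" requires homozygosity in every listed parent
  unless `allow_het_carriers` is set. Tiers are nested; the `partition()` view
  assigns each in-flank gene exactly one label (highest tier or exclusion
  reason).

## Known limitations

- The null CI assumes free recombination between the scanned locus and any
  QTL; near a real QTL on the same chromosome the "null" windows are not null,
  so region boundaries (unlike peak positions) are optimistic.
- The effective-total-depth equivalence assumes near-complete linkage within a
  window; at much sparser marker grids or much longer genetic maps it would
  drift conservative.
- G-based calling is deliberately conservative at window scale; use the Δ rule
  when calibrated error rates matter.
- Bulk selection models strict truncation on the phenotype; misphenotyping or
  selective-pooling errors are not simulated.
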