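# Methods

## The statistic

modhub analyses a *functional gene network*: a symmetric matrix `W`
over genes in which `w_gh ∈ [0, 1]` is the posterior probability that
genes *g* and *h* participate in the same cellular process in a given
cell type.  Given a gene module `M` (a gene set implicated in some
phenotype, e.g. a disease-vulnerability module), the connectivity of a
gene *g* to the module is summarized as a z-score:

    x̄_g = mean of w_gm over m ∈ M (g excluded if g ∈ M)
    μ_g, σ_g = mean and sample SD of w_gh over all h ≠ g
    z_g = (x̄_g − μ_g) / (σ_g / √n),   n = |effective module|

High `z_g` means *g* is more connected to the module than expected
from its own genome-wide connectivity distribution — the signature of
a candidate hub regulator.  Ranking all genes by `z` genome-wide gives
the hub prioritization; a per-pair query ranks one gene among all
partners of another by raw edge weight.

**Denominator.** The package defaults to the standard error `σ/√n`
and also implements `σ/n` (config `z_denominator: sd_over_n`; the two
differ by the factor `√n`, so rankings against a single module are
identical).  `σ/√n` is the variance-matched choice: when a module of
size `n` is drawn at random from the genes, the SD of `x̄_g` is
`σ_g/√n` up to the finite-population correction
`√((N−1−n)/(N−2))`, so `z` is approximately standard normal under the
null and comparable across module sizes.  The null-centering test
exercises exactly this property, using a module small relative to the
network (30 of 1,000) so the finite-population correction (~1.5%) is
negligible against its 10% band.  The choice of denominator is always
recorded in output metadata.

**Conventions.**

- σ uses the sample divisor (n−1) over the N−1 reference weights.
- Self-edges are stored as 1.0 but excluded from every statistic.
- Module genes absent from the network are dropped with a warning; an
  error is raised only below `min_module_size` (default 3).
- Ranks are 1-based competition ranks ("1, 2, 2, 4"); display order
  breaks ties by gene identifier so output is platform-independent.
- A gene whose weights have zero variance gets a `degenerate_sigma`
  flag (z undefined) rather than a silent z = 0; in a genome-wide
  ranking such genes are listed last, unranked, and never abort the
  run.

A caution on monotonicity: raising one module edge `w_gm` always
raises the numerator `x̄_g − μ_g`, but it also feeds `σ_g`, so `z_g`
itself can *decrease* slightly when the raised edge is already far
above `μ_g`.  The numerator, not `z`, is the monotone quantity.

## Validation statistics

These confirm a hub experimentally from a perturbation (silencing /
overexpression) experiment's differential-expression output:

- **DEG-connectivity rank-sum test** — one-sided Wilcoxon rank-sum
  comparing hub-edge weights between DEGs (default `padj < 0.05`) and
  non-DEGs, alternative "DEGs are more connected".  With both groups
  ≤ 20 the exact tie-aware permutation distribution of the rank sum is
  computed by a subset-sum counting recursion over doubled midranks
  (cost `O(N·n₁·ΣR)` instead of `C(N, n₁)` enumeration); larger
  samples use the normal approximation with tie and continuity
  corrections.  The switch point is recorded in the result.  The
  normal approximation is 0.01-accurate against the exact distribution
  at group sizes ≥ ~10 but not at the very smallest samples (e.g.
  2 vs 2: exact 1/6 ≈ 0.167 vs approx 0.123), which is why the exact
  path exists.
- **Fisher overlap test** — one-sided hypergeometric upper tail
  `P(X ≥ |A∩B|)` for two gene sets in an explicit universe; only the
  enrichment alternative is exposed.  The odds ratio is the sample
  `ad/bc`, with a Haldane 0.5 added to every cell (and flagged) only
  when a cell is zero.
- **Signed overlap** — between two DEG tables (e.g. in vitro and
  in vivo arms): Fisher tests for up∩up and down∩down, plus a
  combined concordant test whose 2×2 table puts the same-sign overlap
  in the "both" cell; genes significant in both tables with opposite
  signs are counted in the single-set cells and reported as
  discordant.  This keeps the table summing to the universe; it is a
  declared convention, slightly conservative for the concordant
  alternative.
- **Rank-enrichment curve** — genes ordered by hub-edge weight
  (deterministic tie-break by identifier); at each rank cutoff *k*,
  `fold(k) = (hits_k/k)/(m/N)`, precision among the top-k over DEG
  prevalence.  `fold(N) = 1` identically, and under random DEG
  placement `E[fold(k)] = 1` at every k (hits are hypergeometric).
  Every rank is evaluated up to N = 5,000; above that, 200 log-spaced
  cutoffs.  DEG positions are returned as a rug of competition ranks.
- **BH adjustment** — Benjamini–Hochberg step-up (statsmodels
  `fdr_bh` behind the package surface), used both to derive `padj`
  when a DEG table lacks it and inside the simulator.

Genes with missing `padj` are excluded from every universe (they are
untested, not null).  The nominal-p fallback (`threshold: pvalue`)
must be requested explicitly.  When a report contains several
validation statistics, each p-value is reported raw with its own
settings; no correction is applied across tests, and the rendered
report says so.

## The synthetic benchmark

The generator produces the study conditions every test runs under:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2,000 | network size |
| `module_size` | 100 | planted module |
| `background_beta` | (1, 9) | background edges, mean 0.1 |
| `module_beta` | (4, 6) | module-internal edges, mean 0.4 |
| `hub_beta` | (6, 4) | hub→module edges, mean 0.6 |
| `de_intercept` (b0) | −3 | baseline DE logit (~4.7% DE at w = 0) |
| `de_slope` (b1) | 6 | DE logit per unit hub-edge weight |
| `lfc_de` | (2.0, 0.5) | mean, SD of \|log2FC\| for DE genes |
| `lfc_null_sd` | 0.25 | null log2FC noise |
| `p_de_exponent_range` | (2, 10) | DE p = 10^(−U(2,10)) |

Beta-distributed edges respect the `[0, 1]` posterior semantics; the
hub sits *outside* the module by default, emulating a regulator of a
module rather than a member.  DE labels follow
`P(DE) = logistic(b0 + b1·w(hub, g))`, so `b1 = 0` is the calibration
null in which labels are independent of connectivity.  P-values are
drawn directly rather than simulated from read counts: the pipeline
consumes differential-expression *output*, and what the validation
statistics respond to is the label/connectivity coupling, not the
count model.  A paired table (for the signed-overlap test) shares
truth labels and signs but has independent noise, with a configurable
fraction of DE genes reverted to null (default 0.5) to emulate a
weaker second assay.

One integer seed drives everything through
`SeedSequence(seed).spawn(3)`: a network stream (module/hub placement
and edge weights), a label stream (DE labels and signs) and a noise
stream (p-values, fold changes).  Same seed ⇒ bit-identical outputs.

**What the simulation does not emulate:** correlated edge estimates
(real posteriors are built from shared genomic evidence and are far
from independent), degree heterogeneity beyond the planted structure,
multiple interacting modules, p-value/log2FC dependence on expression
level, and batch structure.  Passing the benchmark therefore shows
the statistics are implemented correctly and calibrated under the
stated model — not that real networks carry as clean a signal.

## Test and calibration problem sizes

- Oracle equivalence: random networks ≤ 50 genes, universes ≤ 30,
  rank-sum totals ≤ 12, against exhaustive enumeration (1e-12 for z;
  exact for discrete tails).
- Planted-hub recovery: 100 seeds at full defaults; ≥ 95 must rank
  the planted hub first among non-module genes.
- Null centering: 1,000-gene i.i.d. network, 1,000 random 30-gene
  modules.
- Type-I calibration: one fixed 500-gene network, 2,000 label/noise
  replicates at `b1 = 0` (the null conditions on the network, so the
  network is not regenerated); rejection at 5% must land in 4–6% and
  the p-value KS distance from uniform below 0.05.
- Enrichment-curve null: universe 200, 20 DEGs, 1,000 placements.

## Numerical notes

- Row mean/SD for the genome-wide ranking are computed two-pass
  (deviations from the row mean), matching naive per-element
  recomputation to ~1e-15 even at 2,000 genes.
- Dense-matrix and DEG-table parsing use round-trip float precision so
  write→read reproduces values bit-exactly; edge lists serialize at 6
  decimals (posterior-probability precision) and round-trip to 5e-7.
- Doubled midranks make the exact rank-sum recursion integer-valued;
  counts stay below 2^53 for the group sizes where the exact path is
  used, so double-precision counting is exact.
- Affine maps `w → a·w + b` (a > 0, range kept inside [0, 1]) shift
  x̄ and μ equally and scale σ by a, leaving z unchanged; this is
  verified to 1e-9.

## Known limitations

- The analysis consumes a network; it never infers one.
- No GSEA-style weighted statistic; the enrichment curve is the
  precision/prevalence fold defined above.
- Gene identifiers are matched as opaque strings; no ortholog or
  symbol mapping.
- The exact rank-sum path is quadratic in the pooled sample size and
  is deliberately capped at group size 20.
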