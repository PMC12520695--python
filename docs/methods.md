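# Methods

## In vivo enrichment ranking

### Model and procedure

The in vivo screen compares each metastatic lung's guide library with the
pre-injection input baseline. The analysis is intentionally simple — no
count model is fitted — and proceeds in five steps:

1. **Low-coverage exclusion.** A guide with fewer than `min_lung_reads`
   (default 50) raw reads in a lung sample is excluded from that mouse's
   analysis. The filter acts on raw counts, per lung sample, before
   normalization; normalization always uses full-column totals.
2. **Total-count normalization.** Every sample is scaled to
   `normalization_scale` total (default 1e6, reads-per-million).
3. **Per-mouse fold change.** `FC = (lung_RPM + pc) / (input_RPM + pc)` with
   a symmetric pseudocount `pc` (default 0.5 RPM). The pseudocount exists to
   keep fold changes finite for guides absent from the input; at typical
   input abundances (hundreds of RPM) it perturbs values by well under 1%.
4. **Cross-mouse averaging.** See below.
5. **Best-guide gene ranking.** Each gene is scored by its most enriched
   surviving guide; genes are sorted by descending average fold change,
   ties broken by gene symbol, rank 1 = most enriched. Genes with no
   surviving guide are omitted; guides retained in no mouse are reported in
   a side list.

### Why the average runs over all metastatic mice

Two readings of "average fold change across mice" are possible when a guide
is excluded from some lungs: average over only the mice where the guide was
retained, or divide the summed fold changes by the number of metastatic
mice (so absence contributes zero evidence). Both are implemented
(`InVivoConfig.mouse_denominator = "metastatic" | "retained"`); the default
is `"metastatic"`, and the choice is consequential. A bottlenecked lung is
founded by a few hundred clones, so a typical no-effect guide that happens
to seed one lung lands there at hundreds of times its input abundance — a
fold change of 20–50 in that single mouse is routine. Under retained-only
averaging such singletons populate the top of the ranking and bury true
drivers (in the package's default recovery experiment, retained-only
averaging recovers the seeded drivers in the top 10 in 0 of 20 simulated
screens; the all-mice denominator recovers them in 20 of 20). Dividing by
all metastatic mice instead rewards reproducibility across animals, which
is the property that distinguishes a driver from a jackpot. Geometric
averaging (optional) always uses retained mice only, since a zero term
would annihilate the product.

## Candidate triage

Enriched genes (top-N or an inclusive fold-change floor — the cutoff is a
free parameter echoed in the output metadata) are intersected with one or
two protein lists. Symbols are uppercased at every I/O boundary and matched
by string equality; no alias or ortholog mapping is attempted. The overlap
preserves screen-rank order, and exclusive Venn-region counts always sum to
the union size.

## Sorted-screen scoring

### Guide score

`score = log2((low_RPM + pc) / (high_RPM + pc))` between the two gate
samples. By default enrichment in the ratio-low gate scores positive — the
hit sense for a screen whose reporter ratio tracks substrate stability and
whose hits destabilize it (e.g. a kinase-loss screen on a stabilized
substrate). `direction="high"` flips the sign for the opposite design. This
is a deliberately transparent statistic: no variance model, replicates are
averaged upstream.

### alpha-RRA

Guides are ranked by descending score; tied scores receive average ranks
(avoiding input-order dependence), normalized to `r = rank/n ∈ (0, 1]`.
For a gene with `g` guides, sorted ranks `r(1) ≤ … ≤ r(g)`, and selection
set `{k : r(k) ≤ alpha}`,

`rho = min_k I_{r(k)}(k, g − k + 1)`,

the minimum over selected positions of the probability that the k-th order
statistic of `g` uniform variables is ≤ `r(k)`. Genes with no selected
guide receive `rho = 1`. Defaults: `alpha = 0.25`, 10,000 permutations —
implementation defaults surfaced in the config, not field constants.

The permutation null preserves the per-gene guide count: for each gene size
`g`, subsets of `g` ranks are drawn without replacement from the observed
normalized-rank pool (so tie structure is preserved), and
`p = (1 + #{null rho ≤ observed}) / (N + 1)`, which floors p at `1/(N+1)`.
Null draws are shared across genes of equal size; the computation is
vectorized and chunked to bound memory. BH FDR
(`q(i) = min_{j≥i} p(j)·m/j`, clipped at 1) is computed by the package's own
step-up implementation, cross-checked in the test suite against an
independent reference implementation.

Calibration note: with `alpha < 1`, every gene with no guide in the top
alpha fraction gets `rho = 1` and hence `p = 1`; under a null with 3-guide
genes and `alpha = 0.25` that is ~42% of genes, so the p-value distribution
has a large atom at 1 and cannot be two-sidedly uniform. This is a property
of the statistic, not a bug; the package's uniformity check therefore runs
at `alpha = 1`, where rho is continuous and the same permutation machinery
yields uniform p-values (KS distance ≈ 0.02 at 1,000 genes).

## Guide quantification

Reads are `constant vector prefix + 20-nt protospacer`; the prefix is
removed either by fixed length or by scanning for an anchor sequence, and
the following 20-mer is matched **exactly** (case-insensitively, forward
orientation only) against the library. No mismatch tolerance, no
reverse-complement search, no quality filtering: a single-base error sends
a read to the unmatched tally, and per-sample accounting guarantees
`matched + unmatched = total`. Exactness keeps counting conservative,
deterministic, and round-trip testable; orientation and adapter trimming
are the library prep's responsibility.

## Synthetic data generator

The generator emulates the screens' statistical structure so every stage can
be exercised end to end without sequencing data.

* **Library:** `GENE000001…` symbols, 3 distinct random 20-mers each;
  full-scale default 23,430 genes / 70,290 guides.
* **Input baseline:** per-guide log-normal abundance skew
  (`abundance_dispersion`, default sigma 0.5), an integer cell pool at
  `input_coverage_cells_per_guide` (default 500 cells/sgRNA), and a
  multinomial read draw at the configured depth (default 500 reads/guide).
* **Lungs:** each of `n_mice` (default 18) mice is metastatic with
  probability `metastasis_penetrance` (default 0.5, i.e. ~9 of 18). A
  metastatic lung is founded by `clones_per_mouse` (default 200) cells drawn
  with probability ∝ input abundance × the gene's seeding weight
  (`driver_genes`); clone sizes get log-normal growth noise (sigma 0.5);
  reads are multinomial at the lung depth. `clones_per_mouse=None` disables
  the bottleneck (lungs resampled straight from the input distribution),
  which is how the null-calibration scenario is built. The clone-founding +
  independent-expansion structure is the minimal generative model that
  reproduces the screens' qualitative behavior: sparse, jackpotted lung
  libraries with driver enrichment. It does not model tumor growth dynamics,
  guide-level activation efficiency differences, or PCR/sequencing error.
* **Sort gates:** one guide per cell (uniform), cell log-ratio
  `Normal(effect(gene), sigma)` with sigma default 1.0, exact top/bottom
  quantile gates (default 5%/5%, sizes `floor(fraction × n_cells)`), and a
  multinomial read draw per gate. Fluorescence is reduced to one scalar per
  cell; spectral compensation and sorter impurity are out of scope.
* **FASTQ emission:** exactly `count` copies of `prefix + protospacer` per
  guide in seeded shuffled order with constant quality, so quantification
  recovers the matrix exactly.

### Desk-scale scenarios and what passing shows

The bundled scenarios are scaled for interactive runs and CI: 500 genes ×
3 guides, 8 metastatic mice, 200 clones/mouse, 5 drivers at weight 20, 1e6
reads/sample (in vivo); 1e5 cells, 5 effect genes at −2 sigma, 5e5
reads/gate (sorting). Full-scale configs (23,430 genes, 18 mice, 2e7 cells)
exist but are not exercised by the test suite. Recovery tests show the
algorithms separate strong, reproducible effects from bottleneck/sort noise
under this generative model; they do not certify performance on real
screens, where guide efficacy varies, effects are smaller and correlated,
and library composition drifts during culture.

## Numerical choices and degenerate inputs

* Filters compare raw integer counts (`>=` threshold, so "fewer than 50"
  excludes exactly counts 0–49); normalization divides by exact column sums
  and refuses zero-sum columns by name.
* Ranking ties break lexicographically (genes by symbol, guides by id) so
  outputs are byte-reproducible; permutation invariance to row/column order
  is tested.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; multi-stage simulations split seeds with `SeedSequence.spawn`.
* Empty FASTQ, all-zero lung columns, zero-penetrance runs (warning + empty
  lung set), single-clone bottlenecks, and count tables missing manifest
  guides (zero-filled with a warning) are all defined behaviors with tests.

## Known limitations

* The in vivo stage emits a ranking only — no p-values — matching the
  design it implements; significance enters only at the sorted-screen stage.
* Exact matching undercounts at realistic sequencing error rates (~1%/base
  implies ~18% of 20-mers carry an error); a mismatch-tolerant mode is a
  possible extension, not present.
* The gene-level RRA treats guides as exchangeable; guide-specific efficacy
  is not modeled.
* Interactome matching is symbol-equality only; identifier mapping between
  proteomics and library nomenclature must happen upstream.
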