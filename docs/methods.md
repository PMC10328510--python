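# Methods

## Scope and model

`popgensim` simulates neutral sequence variation on chromosome-scale
contigs for species described by a curated parameter catalog.  The model
is the structured coalescent with recombination: a sample of `n` genomes
is traced backwards in time as a set of lineages, each carrying the
genomic intervals ancestral to the sample, until every position has found
its most recent common ancestor.  Demography is piecewise constant —
instantaneous population-size changes, pastward population splits, and
backwards migration at per-lineage rates — with no continuous growth
epochs (the worked species models in the catalog are all step models, and
growth would complicate the epoch-advance logic for no present gain).

Event rates while `k_p` lineages reside in population `p` of current size
`N_p`:

* coalescence within `p`: `k_p (k_p - 1) / 2 × 1 / (ploidy × N_p)` per
  generation.  The `ploidy` convention is stated explicitly because it is
  easy to get silently wrong: pairwise rate `1/(2N)` for diploids — so
  that expected pairwise diversity is `θ = 4 N μ` — and `1/N` for
  haploids/bacteria.
* migration: per lineage in `p`, the current backwards rate to each
  destination.
* crossover: per lineage, the recombination-map mass over the lineage's
  *breakable span* — the interval from its leftmost to its rightmost
  ancestral coordinate.  Breakpoints are drawn within that span in
  proportion to the local map rate; a breakpoint that fails to separate
  material (it can fall exactly at the left edge) is logged as drawn but
  ineffective, so the effective per-lineage rate reduces to the classic
  Hudson rate over internal breakpoints.
* gene-conversion initiation: per lineage, initiation rate × breakable
  span length, with the initiation site uniform on the span.

Waiting times are competing exponentials.  At every demographic boundary
(size change, split, migration change) the clock advances to the boundary
and all waiting times are redrawn; this is exact by memorylessness of the
exponential.  Simultaneous events have probability zero; float ties are
resolved by a fixed category priority (coalescence, migration, crossover,
gene conversion).

### Non-crossover recombination

Two configurations share one mechanism:

* **Eukaryotic gene conversion**: the catalog stores the fraction `f` of
  recombination-class events that are conversions and the mean tract
  length.  The initiation rate is `r × f / (1 − f)` where `r` is the
  crossover rate; the crossover rate itself is never reduced.  With
  `f = 0.83` this yields conversion and crossover draws at 83:17, which
  the event log lets you audit directly (`gc_fraction_drawn`).
* **Bacterial mode** (`non_crossover_only`): crossover is disabled and
  the chromosome's recombination rate is interpreted as the initiation
  rate of a recombined tract (for the E. coli entry, 8.9×10⁻¹¹ per bp per
  generation with 542 b mean tracts).

Tract lengths are geometric on {1, 2, …} with success probability
1/mean — the memoryless discrete distribution is the natural choice when
only an average tract length is specified.  Tracts extend rightward from
the initiation site and are truncated at the span end.  Initiation is
restricted to the breakable span; initiation across the whole contig
would only add draws that cannot touch ancestral material.  Conversion
events whose tract misses the lineage's material (or swallows all of it)
are logged drawn-but-ineffective.  Gene conversion is off unless
explicitly enabled (it multiplies event counts roughly six-fold at
`f = 0.83`); bacterial mode is always on for `non_crossover_only`
contigs, where it is the only recombination class.

### Ancestry tables

Lineages carry sorted disjoint segments, each mapped to an output node
and annotated with the number of sampled genomes beneath it.  A
common-ancestor event merges two segment lists; overlapping pieces create
a new node and two edges each, and a piece that becomes ancestral to the
entire sample is retired.  Merges without overlap simply pool material
and create no node, so marginal trees contain no unary nodes.  The result
is a node table (times) plus an edge table (parent, child, genomic
interval) from which the marginal tree at any position is reconstructed
by selecting covering edges.

## Mutation

Mutations are layered after ancestry from an independent, named RNG
substream of the same root seed (so the ancestry and mutation layers are
reproducible independently).  Sites are discrete integer positions: per
edge, the mutation count is Poisson with mean
`μ × span_bp × branch_generations`, positions uniform within the edge
interval, times uniform on the branch.  Collisions are retained, so a
site can carry recurrent mutations and segregate more than two alleles.
Derived states follow the Jukes–Cantor kernel — uniform over the three
non-current nucleotides, with "current" determined by applying older
mutations along the path above, processed oldest-first per site.
Ancestral states are uniform over {A,C,G,T} (JC stationary), with a
fixed-'A' mode for deterministic fixtures.  Genotypes are propagated
root-to-tip: a sample's state is the derived state of the youngest
mutation on its path, else the ancestral state.

Because sites are finite, the classic infinite-sites identities
(`E[π] = θ`, `E[S] = θ a_{n−1} L`, `π ≈ θ_W`) hold only up to multi-hit
corrections of order the per-site θ.  The calibration tests therefore run
at per-site θ ≤ 0.004 where the bias is well inside Monte-Carlo error; at
θ = 0.015 (the A. gambiae diversity) the JC saturation deficit is ≈ 2%,
which still rounds to the target 0.015 at three decimals.

## Catalog and demography conventions

* Only parameters with a documented published source are embedded in the
  built-in entries; chromosome lengths are never embedded and come from
  `chrom.sizes`/`.fai` files or catalog text.  Fields with no citable
  value (e.g. the D. melanogaster crossover rate, the E. coli default Ne)
  hold a deliberately implausible placeholder and must be overridden.
* Unknown keys in catalog or model files are hard errors: these files
  hold citable constants, and a typo must not silently disappear.
* Time is in generations before sampling (0 = present), events sorted
  ascending pastward.  Population size is a right-continuous (pastward)
  step function: exactly at an event time, the older epoch's size
  applies.
* A demographic model may override the species mutation rate (to match
  the rate its inference assumed) but deliberately not the recombination
  rate; the QC audit reports the resulting discrepancy instead
  (`rate_discrepancy_percent`, rounded half-to-even for the
  human-readable form).
* Pseudo-chromosome assembly groups contigs by first-fit-decreasing bin
  packing against the target lengths, ties broken by input order — a
  deterministic heuristic for approximating a species' expected
  chromosome lengths; overflow is warned about, never dropped.
* Gene-conversion fraction must be strictly below 1 (fraction 1 has no
  finite crossover-relative initiation rate).

## QC by comparison

Catalog entries are validated by having a second person re-implement the
model from the primary sources and mechanically diffing the two
specifications.  `compare_models` aligns events by (type, populations
involved), pairs them in time order, compares numeric fields at a
relative tolerance (default 1e-6 — these are transcribed constants, not
computed quantities; the tolerance is our documented choice) and reports
structural mismatches unconditionally, each with a dot-separated path.

## Verification strategy

* **Closed-form oracles**: E[T₂] = ploidy × Ne; E[TMRCA] =
  2 × ploidy × Ne × (1 − 1/n); the exact labeled-topology distribution
  for n = 4 obtained by enumerating all equally likely merge histories;
  the geometric tract pmf; Poisson mutation counts on fixed genealogies.
* **Independent implementations**: pairwise coalescence-time
  distributions are cross-checked against msprime (two-sample KS);
  written VCFs are re-parsed with cyvcf2 (htslib) and Newick with
  dendropy.
* **Structural invariants**: a single rooted tree over all samples at
  every genomic position, conservation of ancestral material across
  crossover/conversion splits, disjoint per-parent-child edge intervals,
  drawn ≥ effective event counts, byte-identical output under a repeated
  seed.

Monte-Carlo problem sizes (e.g. 500 replicates of a 100 kb, n = 10
conversion run; 1,000 replicates of the 10 kb diversity calibration;
2,000 replicates for TMRCA means) were chosen to put 3-standard-error
bands a few percent around the expectations while keeping the whole suite
in a couple of minutes.

## What the simulations do and do not show

The generator produces neutral, constant-rate, piecewise-constant-
demography data.  Passing calibrations show the engine's rates and the
mutation layer are correctly implemented; they say nothing about
selection, rate heterogeneity along the genome, gene flow with varying
gene content (bacterial plasmid transfer), overlapping generations, or
any feature of real data outside the model class.  Known limitations, by
design: no selection or DFEs, no forward-time mode, no exponential
growth, no per-model recombination override, no binary tree-sequence
output.  The built-in catalog carries only the parameters needed here;
published multi-epoch models whose full parameter tables live in external
supplements are represented by schema-compatible illustrative fixtures,
clearly labelled, not by the published values.
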