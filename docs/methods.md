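# Methods

## Input model and assumptions

The package consumes node-level PSI tables of the kind written by
event-level splicing quantifiers (Whippet-style): one row per gene, node and
sample with coordinates (`chr:start-end`, 1-based inclusive), strand, node
type (CE/AA/AD/RI), a PSI value in [0, 1] or NA, and the number of reads
supporting the quantification. Samples are *cell pools*: same-cell-type
cells grouped before quantification so that junction coverage is usable.
Pooling here shuffles cells within each cell type with a seeded RNG and
chops them into consecutive groups of `pool_size` (default 5); a non-empty
remainder becomes its own smaller pool, because discarding remainder cells
would systematically bias rare cell types. Users who pooled upstream (e.g.
pseudobulk alignment per pool) can feed per-pool tables directly; the
package does not re-derive PSI from reads.

An entry enters the matrix only if it is quantified and supported by at
least `min_reads` reads (default 10, boundary inclusive). Duplicate
(node, pool) rows abort assembly rather than being silently overwritten:
they indicate a corrupted upstream merge. Nodes with no surviving entry are
dropped and reported.

## The compressed two-sided index

Per node, the mean μ and standard deviation σ of PSI over quantified pools
are computed and stored. Each quantified pool is assigned by its deviation
ΔΨ = Ψ − μ with threshold τ ∈ (0, 1), default 0.2:

| condition | destination | stored value |
|---|---|---|
| ΔΨ > τ | above side | 100·ΔΨ |
| ΔΨ < −τ | below side | 100·\|ΔΨ\| |
| \|ΔΨ\| ≤ τ | near-mean mask | — |

The inequality is strict: a deviation of exactly τ goes to the mask. With
continuous PSI, "equal to the mean" is measure-zero, so the mask is defined
as *quantified but within τ of the mean*; its job is to make near-mean
pools distinguishable from unquantified ones so that Ψ ≈ μ can be returned
for them. The 100× scaling puts stored magnitudes in (0, 100].

**Positions.** Each side's pool positions (sorted, 0-based) are stored in
canonical Elias-Fano form: with m positions in universe U (the pool count),
each position keeps its l = max(0, ⌊log₂(U/m)⌋) low bits verbatim
(concatenated LSB-first) and the high parts are unary-coded gaps. Decoding
is exact for every input; the codec is the only place bit-level layout
matters and is property-tested against random sets up to U = 10⁶.

**Values.** The magnitudes of one node-side are quantized to b bits
(default 2, range 1–8): a log-normal is fitted by the mean/SD of
ln(values) (SD 0 allowed — degenerate distributions quantize exactly), cut
points are placed at the fitted quantiles k/2ᵇ, and a value's code is the
number of cut points ≤ value. Each bin's representative is the median of
the original values in it; an empty bin falls back to the fitted
distribution's median of its quantile band, and representatives are kept
non-decreasing. Above and below sides are quantized independently per node
— per-node fitting tracks the wide range of deviation scales across nodes.
Reconstruction returns μ ± representative/100 clamped to [0, 1] for encoded
pools, μ for mask pools, and missing otherwise; the error on an encoded
entry is bounded by its bin's value range, and on a mask entry by τ.

**Container.** One HDF5 file holds pools (ids, cell types, members), node
annotations, per-node stats, the two side groups and the mask. All per-node
byte payloads are concatenated into flat arrays with offset tables —
thousands of tiny datasets would cost more in container metadata than the
payloads themselves. A format-version attribute guards loads; load(save(x))
reproduces every field exactly.

## Queries and enrichment

A pattern is a set of (node, above|below) terms combined with AND or OR;
matching is set intersection/union over decoded positions. A pool where a
node is unquantified is simply absent from both sides and never matches a
term — no imputation. Enrichment of a pattern in a cell type uses the
exact hypergeometric upper tail P(X ≥ k) (inclusive of the observed k, the
reading consistent with testing *enrichment*), computed via
`scipy.stats.hypergeom.sf(k−1, N, K, n)`; tests cross-check it against
brute-force enumeration of all draws for every feasible configuration with
N ≤ 12. Raw p ≤ α (default 0.05) defines significance; Benjamini–Hochberg
correction is available but off by default, matching common practice for
this kind of screen where the stringent downstream filters carry the
error control.

## Pattern mining

**Markers.** For a target cell type, every (node, direction) pair is scored:
TP = target-type pools on the side, FP = other pools on the side,
FN = n_type − TP. Unquantified and near-mean pools of the target type count
as FN — a marker that cannot be observed in a pool has failed to detect it,
and this convention is what ties poor recall to quantification sparsity.
0/0 ratios score 0 (a never-detected node is a useless marker). Ranking is
by F1 descending, ties by precision (precision drives marker quality in
practice), then node label for determinism; inclusion and exclusion
directions compete in a single list.

**MXE pairs.** Candidates are within-gene ordered pairs whose mean-PSI sum
lies in 1 ± 0.1 (inclusive) and whose PSI SDs differ by < 0.1 (strict), both
computed from per-node stats over each node's own quantified pools. Both
orientations of the include-one/exclude-other AND pattern are tested for
every candidate. A pair is reported when ≥ 1 cell type is significant; it
is high confidence when some significant cell type shows the pattern in
≥ 50 % of its pools (inclusive) and a pairwise PSI difference ≥ 0.5, the
difference being computed from reconstructed per-pool PSI (the index is the
only data available at query time, so this quantity is approximate by
design). Cross-gene pairs are excluded — mutual exclusivity is a
within-transcript phenomenon. Adjacency (consecutive node ids) is reported
as a flag, not enforced.

**Blocks.** Genes are scanned 5′→3′. A run opens at a CE node and absorbs
the next node while its mean and SD each stay within ±0.1 of the averages
over current run members; on failure the run closes and the scan re-seeds
at the next CE node. Comparing against the run aggregate (rather than only
the previous node) prevents slow drift from chaining unrelated nodes; a
`compare_to="last"` switch restores the drifting behaviour, and a
`seed_node_types` switch restricts extension to CE-only. Non-CE nodes may
extend but never start a run. Closed runs of length ≥ 2 are tested for
joint inclusion and joint exclusion separately; node ids collapse to
distinct exons through a user-supplied node-to-exon table (fallback: each
node is its own exon, loudly logged) and blocks need ≥ 3 distinct exons.
High confidence requires the matching fraction to exceed 50 % strictly — the
MXE tier uses ≥ and the block tier uses >, deliberately asymmetric because
that is how the two screens are conventionally specified. Only maximal runs
are tested, not their prefixes.

## Synthetic data

The generator emulates the statistical shape of pooled single-cell splicing
data, not its read-level mechanics: per-node baseline inclusion from a
Beta(2, 2) (clipped to [0.05, 0.95]) so node means are spread and roomy for
planted shifts, truncated-Gaussian pool noise (default SD 0.05 — direct
control of the SD matters for the ±0.1 block-extension tolerance, which a
per-entry Beta would not give), independent per-entry missingness (default
5 %), and a read-support column in which a configurable fraction (default
5 %) falls below the 10-read cutoff. Genes carry 8–12 nodes by default,
mostly CE; datasets default to 10 cell types × 8 pools of 5 cells.

Planted patterns record their ground truth: markers shift one node by δ
(default studies use δ = 0.4, leaving ΔΨ ≈ δ(1 − 1/n_types) ≫ τ in the
target type); MXE pairs are generated complementary (Ψ_b ≈ 1 − Ψ_a in every
pool, roles 0.9/0.1 only in the target type) and are verified
post-generation to satisfy the candidate filters; block nodes share one
baseline and shift jointly, with flanking nodes pushed ≥ 0.2 away so the
scan terminates at the planted boundaries. Entries of planted nodes are
always confidently quantified: the generator guarantees recoverability *in
principle*, so a failed recovery indicts the detector, not the thinning.
Consequently, passing recovery tests says nothing about robustness to
missingness on the signal itself — that regime is exercised only by the
background nodes and is a known limitation. Other aspects of real data the
generator does not emulate: read-depth-dependent PSI noise, correlated
missingness within cell types (available as an option, off by default),
overlapping node coordinates, and batch structure.

## Numerical choices

* Node mean/SD use the population SD (ddof 0) over quantified pools.
* Values are kept as reals; the 0–100 range is scaling, not integer
  truncation, so a side never contains a 0 after rounding.
* Ties at τ go to the mask; ties in marker ranking break by precision then
  label; enrichment results sort by p then cell-type name.
* Degenerate inputs: all-missing node columns are dropped with a warning;
  empty sides round-trip as empty; constant value sets quantize with σ = 0
  and reconstruct exactly.
* Determinism: pooling and simulation are pure functions of their seed;
  index building is a pure function of (matrix, τ, b).

## Test and simulation scales

Property tests use matrices up to 200 pools × 5,000 nodes and codec
universes up to 10⁶. Recovery studies run 20 marker simulations and 10
pattern simulations (10 cell types × 8 pools, ~500 nodes, one planted
marker per type at δ = 0.4, three MXE pairs and three blocks per pattern
run) plus 5 null simulations; these sizes give binomial standard errors of
a few percent on recovery rates while keeping the default suite fast.

## Known limitations

* Absolute compression ratios depend strongly on sparsity and value
  distribution; only the direction (index smaller than a dense TSV) is
  asserted, on synthetic data.
* `delta_psi` for MXE confidence is computed from lossy reconstructed PSI;
  with 2-bit codes it can differ from the true difference by the within-bin
  range.
* The mean-sum/SD candidate filters use each node's own quantified pools;
  with very uneven missingness between the two nodes of a pair the filter
  can behave differently than if restricted to jointly quantified pools.
* Whether near-mean (mask) pools should count as false negatives for
  markers is a convention; counting them (the default) is what links poor
  recall to sparse quantification, and `near_mean_as_fn=False` switches to
  excluding them from the recall denominator.
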