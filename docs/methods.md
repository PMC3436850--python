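# Methods notes

This note records the model, the numerical conventions, the defaults
and the design decisions behind `splicequant`, in the order the pipeline
runs. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and gene models

All internal coordinates are 0-based half-open; the GTF reader/writer
converts to and from 1-based inclusive at the boundary, making the
conversion exactly invertible. Exon lists are held in transcription
order (descending genomic coordinates on the minus strand), so every
downstream stage — graph building, translation, feature mapping — can
ignore strand except when fetching sequence (reverse-complemented per
node). Only GTF is parsed for gene models; features must carry
`gene_id`/`transcript_id` (Ensembl-dialect attributes).

## Splice graphs

Sub-exon boundaries are the union of all exon start/end coordinates of
a gene's transcripts. Cutting every exon at every boundary it contains
yields partition cells that are pairwise identical-or-disjoint, which is
what guarantees the unique-location property for arbitrary overlapping
exon sets — the reason this construction was chosen. Edges between
consecutive path nodes are typed `adjacency` when both nodes derive from
the same annotated exon (they then necessarily abut) and `junction`
otherwise. Genes are processed independently; overlapping genes each
get complete graphs. Node IDs follow the composite-exon convention
`E<exon>[.<sub-exon>]`, where a composite exon is a maximal run of
genomically abutting sub-exons in transcription order.

## Tiling and alignment

Tile generation starts a depth-first traversal from every node at
offsets spaced by the step `S`, emitting all paths until `T` bases or a
graph sink. Defaults `T = 2R − 1` and `S = R − (2·h − 1)` (read length
`R`, minimum junction overhang `h = 4`) are the minimal choice for
which every R-window of every transcript path, at every junction
overhang ≥ 1, lies wholly inside some tile: a window starting at offset
`p` in a node is covered by the tile starting at `S·⌊p/S⌋` provided
`S ≤ T − R + 1`. Tiles identical in graph location are emitted once;
truncated tiles shorter than `R` at non-zero offsets are suppressed
(they can hold no read and are contained in the offset-0 tile).

Alignment is ungapped and substitution-only (Bowtie-v-style), default
≤ 2 mismatches, with `max_mismatch + 1` non-overlapping exact k-mer
seeds (k = 16) so the pigeonhole principle guarantees no in-budget hit
is missed for reads of length ≥ `(max_mismatch + 1)·k`. `N` never
matches anything, including reference `N`. Hits are collapsed by graph
footprint (the set of elements observed), not by tile, because
overlapping tiles deliberately contain the same locations; a read whose
collapsed hits still span more than one location — within or across
genes — is ambiguous and discarded outright. Fractional assignment is
deliberately avoided: it would reintroduce the isoform-disambiguation
problem the graph representation exists to sidestep.

A SAM produced by any external ungapped aligner against the exported
tile FASTA can be imported instead; records with indel/clip CIGARs are
rejected, and the same collapsing and ambiguity rules are applied per
read name.

### Footprint convention

A read observes every node it overlaps by ≥ 1 base and every edge
(junction or adjacency) it crosses with ≥ `h` bases on both sides,
with `h` the same minimum overhang used by the junction-observation
filter (default 4). Using `h` rather than 1 base at the counting stage
keeps the raw edge total consistent with the edge effective length used
in OPKM (below): the number of read start positions that cross validly
is then exactly `R − 2h + 1`, so edge OPKM estimates the per-position
read-start density without bias. Per-read junction overhangs are stored
regardless, so the observation filter can be re-applied at any
threshold.

## OPKM

`OPKM_e = O_e · 10⁹ / (L_e · N_aligned)`, with `L_e` the node length
for sub-exons and `R − 2h + 1` for both edge types. The gene-level
denominator is the graph's total sub-exon (union) length, well defined
thanks to the unique-location property. With `N_aligned = 0` all OPKM
values are defined as 0. Note that a node's raw total includes reads
overlapping it partially, so node OPKM carries an `(L + R − 1)/L`
edge-overlap inflation relative to per-position coverage; the quant
tests assert this exact relationship. Branch ratios in the traversal
compare edges with equal effective length, so the convention cancels
there. A conventional per-gene RPKM (each read counted once) can be
emitted for comparison.

## Event taxonomy

Events are pairs of internally node-disjoint paths between shared
anchor nodes, classified purely topologically (see the `events` module
docstring for the exact rules). The taxonomy covers exon skip, cassette
exons, alternate donor/acceptor, retained intron, mutually exclusive
exons, and alternate promoter/terminator via virtual SOURCE/SINK
anchors; working in transcription order makes donor/acceptor and
promoter/terminator labels strand-symmetric, which a property test
verifies by strand-flipping random genes. Paths mixing an anchor-exon
extension on *both* sides of a junction fall through to the
skip/cassette rule (counted by internal nodes) — a deliberate tie-break
that keeps classification strand-symmetric. Because the two paths of an
event are simple, internally disjoint and share both anchors, one
reported event cannot nest strictly inside another with the same
anchors; no extra decomposition pass is needed. Alternate
promoter/terminator events are anchored at the *first* shared node, so
convergences further downstream are not re-reported.

An event is **active** in a sample when every junction on both paths
passes the observation filter (≥ 2 reads with ≥ 4 bases into each
flanking exon, both configurable) and every internal node has at least
`min_exon_reads` (default 1) observations — exon reads confirming the
classification. Retained-intron and adjacency steps are not subject to
the junction filter, which is meaningful only where reads must bridge a
splice.

## Two-sample comparison

`SI = log2((O_A + c)/(G_A + c)) − log2((O_B + c)/(G_B + c))` with gene
totals `G` and pseudocount `c = 1` by default (`c = 0` allowed, making
expression-scaling invariance exact). The 2×2 Fisher table is element
reads versus remaining gene reads per sample — the only table formed
from the available counts that conditions out gene expression. The
two-sided p is the classical sum of all hypergeometric outcomes no more
probable than the observed one, computed over the support in exact
integer arithmetic (binomial weights), so ties need no floating-point
tolerance; tables with any zero margin return p = 1 and are flagged
untestable. FDR control is Benjamini–Hochberg across all testable
elements. Comparison rows are emitted for nodes and junction edges;
a gene is flagged differentially spliced when some element has
|SI| ≥ `si_min` (default 1.0), q ≤ `q_max` (default 0.05) and belongs to
an event active in at least one sample.

## Weighted traversal and protein prediction

Start-node weights are proportional to start-node OPKM (equal when all
are zero); at each branch, outgoing weight splits in proportion to
outgoing edge OPKM — length-normalized depth, because raw counts would
bias toward long elements. Traversal ends at graph sinks; partial paths
whose weight falls below `min_ratio` (default 1%, the pruning that keeps
enumeration sub-exponential) are pruned with their mass reported, so
reported weights + pruned mass = 1 to within 1e-9 by construction. A
gene with zero aligned reads returns its longest annotated isoform at
weight 1 with a `no-data` flag.

Translation uses the annotated CDS start of any reference transcript
whose start base lies on the path (the most upstream such start), else
the first AUG, then the standard genetic code to the first stop; a path
with no AUG yields an empty protein flagged `non-coding`. Features map
through their annotation transcript's CDS by codon arithmetic (amino
acid *i* ↔ CDS bases `3(i−1)…3i−1` in transcription order) and count as
present only when every coding base lies on the path, inside the
translated ORF, and in the annotation frame; otherwise they are lost,
sub-flagged `truncated` (partially on path), `frameshift`, or
`out-of-orf`. Features arrive pre-mapped to a transcript via TSV; no
remote annotation retrieval is performed.

## Synthetic data

The generator emulates multi-isoform loci: a base exon chain (default
4–7 exons of 120–300 bp, introns 80–250 bp) plus variants built by
internal-exon skipping, alternative first/last exons (distinct flanking
exons, so alternate starts/ends are true graph sources/sinks), and
5′/3′ boundary extensions of 12–48 bp; per-gene mixtures are Dirichlet(1);
strands are drawn at random and minus-strand loci are mirrored from the
same layout generator. Locus sequence is drawn uniformly at random and
re-drawn (up to 100 times) until every read-length window maps to a
single graph location within the locus, isolating quantitation accuracy
from repeat-induced ambiguity. Reads pick a gene uniformly, an isoform
by mixture, a start uniform over valid mRNA positions, and iid
substitution errors; names encode the origin so tests can verify
footprints read-by-read.

What the generator does *not* model — positional/GC bias, empirical
error profiles, paired-end fragments, expression differences between
genes, incomplete annotation — bounds what passing tests show: they
validate the graph/counting/traversal machinery under the stated
sampling model, not robustness to real-library artifacts. Reads are
drawn per-isoform by mixture (not length-weighted), so predicted ratios
estimate read fractions; isoforms of unequal length within a gene
therefore produce a modest, depth-independent bias in recovered
concentrations, which is visible in the benchmark error and is inherent
to depth-proportional traversal. Recovery error is expected to fall
with depth only down to that floor.

The standard benchmark is 20 genes, 2–4 isoforms, 2×10⁵ 75-bp reads,
0.5% error, five seeds — a desk-scale configuration chosen so the full
five-replicate chain completes in about a minute on one CPU;
`evaluate_recovery` matches predicted paths to truth by node-path
identity, scores mean |predicted% − true%| per gene, and averages over
genes, with unmatched predicted mass reported as residual.

## Degenerate inputs and tie-breaks

Zero-margin Fisher tables: p = 1, untestable. All-zero outgoing depth
at a branch: equal split. All-zero start depth with nonzero gene reads:
equal start weights, flagged. Empty read stream: all-zero counts,
OPKM = 0. Ties in path ordering are broken lexicographically; event
path pairs order the more-internal-noded path first. Determinism under
a fixed seed and config is asserted byte-for-byte on output files.

## Known limitations

Only known exons and splices are analyzed — novel-junction discovery is
out of scope by design. Alignment is ungapped; indel-bearing reads are
lost (or must be rejected on SAM import). Annotated end nodes that
retain outgoing edges are read through by the traversal rather than
treated as stopping points, since read depth cannot evidence a stop.
Comparison is strictly two-sample with no replicate dispersion model;
the Fisher test is conservative at low counts.
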