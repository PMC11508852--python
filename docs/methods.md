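# Methods

This note documents the models and procedures implemented in `nanoits`,
the defaults and why they were chosen, what the simulator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Read quality

All read-level quality statements use the probability-domain mean Phred
score: per-base Phred values are converted to error probabilities,
averaged, and converted back, `Q̄ = −10·log₁₀(mean_i 10^(−q_i/10))`.
This matches the convention of long-read quality filters and is always
at most the arithmetic mean of the per-base values (Jensen's
inequality), so a read with a few terrible bases is judged by its error
mass, not its median base. Quality bins are integer Phred values
assigned by round-half-up; the binning rule is a convention (the
alternative, flooring, shifts every curve by half a bin but changes no
conclusion) and is centralized in `preprocess.phred_bin`.

Two identities anchor the evaluation: accuracy = 100·(1 − 10^(−Q/10)),
and the radius–quality correspondence `phred_for_radius(r) =
round(−10·log₁₀ r)`. For the 2% radius of 98% OTUs this is Q17: below
it the expected per-base error rate exceeds the clustering radius, so
read-vs-read divergence is error-dominated and de novo unit counts
inflate.

## Primer handling

Reads are reoriented and trimmed by locating the forward primer near the
5′ end and the reverse-complemented reverse primer near the 3′ end
(banded semi-global alignment, IUPAC-aware, default budget of 3 edits
per primer; defaults are the ITS1F/ITS4 pair but fully configurable).
The orientation with the lower total primer edit distance wins, ties
favoring the given orientation. Reads lacking either primer are returned
as structured rejections with a reason code and are counted in the
attrition log — never silently dropped.

## Sequence identity and clustering

Identity between two sequences is matching columns divided by alignment
columns of an optimal global alignment, with terminal gaps excluded from
both counts. The optimal alignment is computed under unit edit costs
(banded bit-parallel algorithm via edlib) with a banded-distance
prefilter that rejects pairs that cannot reach the queried threshold
without computing a path. At the identities where thresholds act in this
pipeline (≥ 84%) the identity value is insensitive to gap-scoring
details; the test suite cross-checks it against an independent
affine-gap aligner. Terminal gaps must be *penalized* during alignment
and only excluded from the identity count afterwards: making end gaps
free would let any two references align only along their conserved core
and appear near-identical, which is not a usable notion of amplicon
identity.

Dereplication collapses identical sequences into zOTUs carrying
per-sample counts, sorted by decreasing abundance with lexicographic
tie-breaks (determinism). Greedy clustering processes zOTUs in that
order; each joins the *best-matching* existing centroid with identity ≥
t (ties to the larger, then lexicographically smaller centroid) or
founds a new centroid. Best-match rather than first-match assignment
costs a few more comparisons but removes order sensitivity among
near-equidistant centroids. At t = 1 the procedure reduces exactly to
dereplication.

## Chimera flagging

A zOTU is flagged as chimeric when two distinct parents, each at least
twice its abundance, admit a single crossover whose prefix-from-A +
suffix-from-B model differs from the query by at most 1 edit, while each
whole parent alone differs by at least 4 — i.e. the read is far better
explained by a junction of two abundant templates than by either one.
The per-parent difference profiles are projected from global alignments
onto query coordinates, so the breakpoint search is linear rather than
quadratic. The abundance-skew assumption (parents ≥ 2×) reflects that
chimeras form late in PCR from already-amplified templates; the
most-abundant unit can never be flagged. These thresholds are declared
conventions of this implementation, in the spirit of de novo chimera
detectors generally.

## Classification and the SH approach

The classifier is the SINTAX scheme: k = 8, and each of 100 bootstraps
draws 32 query k-mers with replacement and votes for the reference
sharing most of them (ties broken by a seeded uniform choice; a
bootstrap whose best hit shares nothing casts no vote). Rank confidence
is the voted fraction of all bootstraps for the modal lineage *prefix*
at that rank, which forces confidences to be non-increasing from domain
to species even when intermediate ranks are missing from some reference
lineages. Hyperparameters are the published defaults of the algorithm.

The classifiability filter is applied to species-rank confidence — the
rank where SH codes live, and therefore the rank at which a unit is
usable downstream: singleton zOTUs need c ≥ 0.95, multitons c ≥ 0.8.
The relaxation for multitons reflects that a sequence observed more than
once is unlikely to owe its identity to sequencing error. Retained
zOTUs are aggregated per SH by summing per-sample counts. Reads whose
zOTU fails the filter count as unclassified in rate curves.

User references absent from the reference database are added under dummy
SH codes (`SH0000001.10FU` pattern), validated for format and
uniqueness, and behave like any database taxon thereafter.

## LULU curation

Post-clustering curation consumes a match list (all ordered centroid
pairs at ≥ 84% identity) and walks daughters from least to most
abundant. A daughter merges into its best-matching more abundant parent
when the parent is present in ≥ 95% of the daughter's occupied samples
and the parent/daughter ratio in those samples is ≥ 1. These are the
published LULU defaults. Counts are conserved exactly; merges are
logged.

## The simulator and what it does (not) show

`nanoits.simulate` emulates a sequenced mock community: by default 16
ITS-like taxa of 600–800 bp (median near the ~709 bp typical of
full-ITS fungal amplicons), each a random sequence around a fixed 150 bp
conserved core shared by all taxa (the 5.8S analogue), with one
reference pair at 1.5% divergence — inside the 2% OTU radius, so de
novo clustering must merge it, exactly as happens to truly close
congeners. Near-pair partners are substitution-mutated copies with the
core left intact, sharing lineage down to genus but carrying their own
SH.

Reads copy one reference (or, at a configurable rate, a two-parent
chimera whose breakpoint is uniform in the middle 80% of the amplicon
and mapped to the homologous position of the second parent, as in
template switching), receive an integer quality string whose
probability-domain mean is within ±0.5 of the target, and have errors
injected between the primer flanks at each base's Phred-implied rate
`10^(−q/10)`, split 50/25/25 between substitutions, insertions and
deletions (a Nanopore-like convention; configurable). Primer flanks are
emitted error-free at the read's target quality so that primer
trimming is exercised deterministically rather than confounding the
quality stratification with primer-loss attrition. Reads are emitted in
both orientations; every read has exactly one ground-truth record.

Not emulated: signal-level/pore behavior, homopolymer-specific error
structure, quality-position correlation along the read, barcode hopping,
and — most importantly — undatabased diversity and contamination.
Passing tests therefore show that the *algorithms* behave correctly
under controlled error and divergence, not that any particular real
community will classify at a given rate; on real data classification
rates are bounded by database completeness, which the fully databased
mock deliberately removes as a factor.

## Evaluation design

Recovery curves subsample every integer-Phred bin to a common depth so
that differences across bins reflect quality alone, and replicate each
bin with seeds derived deterministically from the master seed (the
derivation is recorded in the output table). Per replicate the chosen
approach runs end to end — zOTU: dereplication; OTU: dereplication then
clustering; SH: dereplication, classification, filtering, aggregation —
and counts are recorded with and without singleton units, since
singleton exclusion is common practice but interacts badly with
error-rich long reads. Chimera removal is available as a flag and is
always on in the full pipeline driver; it is off by default in the
curve runner so that curves isolate the clustering/classification
response to quality.

Stabilization is operationalized as: the smallest Q\* such that every
consecutive-bin relative change within [Q\*, Q\*+window] is at most ε
(defaults: window 3 bins, ε = 0.05, and `max(mean, 1)` in the
denominator to keep near-zero curves finite). A loess smoother is a
plotting aid, not part of the decision rule — the windowed rule needs no
smoother hyperparameters and is exactly reproducible.

Problem sizes: the package defaults to 100 replicates per bin, matching
the replication a careful study would run. The bundled tests and the
acceptance script run smaller designs chosen up front as desk-scale
conditions — OTU inflation at depth 1000 × 10 replicates over Q18–Q28,
SH stability at depth 300 × 3 replicates over Q10–Q28, error-free limits
at depth 1000 × 3–5 replicates — sized so the whole suite completes on a
single CPU in minutes while keeping per-bin standard errors small
relative to the effects measured.

## Numerical and reproducibility conventions

All randomness flows through `numpy.random.Generator` seeded from a
single master seed; replicate seeds are fixed arithmetic derivations of
it. Classification tie-breaks consume the same stream, so a full
pipeline run is byte-reproducible: rerunning with the same seed produces
byte-identical tables, FASTA and logs (verified in the test suite).
Sorting keys everywhere include a lexicographic component so that equal
abundances cannot introduce platform-dependent order. FASTQ is Phred+33
with qualities validated into [0, 93]; quality strings in the simulator
are clipped to [2, 50] as basecallers do. Degenerate inputs (empty
quality vectors, empty tables, bins holding fewer reads than the
requested depth, queries shorter than k) raise errors naming the
offending record or bin rather than propagating NaNs.

## Known limitations

* Greedy clustering is O(zOTUs × centroids) alignments; the banded
  prefilter makes this fast at amplicon scale, but very low-quality,
  high-depth bins (tens of thousands of near-unique reads) get slow.
* The chimera detector considers only single-crossover, two-parent
  models, and its thresholds are conventions, not fitted values.
* The SINTAX implementation classifies against the full reference set
  in memory; it is not engineered for UNITE-scale databases (hundreds of
  thousands of references), where a disk-backed k-mer index would be
  needed.
* `--threads` is accepted for interface compatibility but processing is
  single-threaded.
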