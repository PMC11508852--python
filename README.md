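# nanoits

**Nanopore full-ITS metabarcoding tables, and the quality threshold they need.**

Long-read platforms can sequence the full fungal barcode region (the
internal transcribed spacer, ITS, ~250–1500 bp), but their per-base error
rates sit uncomfortably close to the identity thresholds metabarcoding is
built on. `nanoits` is a self-contained, simulator-backed re-implementation
of an eNano-style amplicon pipeline together with the evaluation framework
needed to answer the practical question: *what mean read quality (Phred
score) suffices before taxonomic-unit recovery stabilizes?*

It is aimed at mycologists and microbial ecologists processing Nanopore
amplicon data, and at anyone benchmarking quality-filtering policy for
long-read metabarcoding.

## What it computes

Given Phred+33 FASTQ reads and a SINTAX-formatted reference FASTA
(`>ID;tax=d:Fungi,p:...,s:SH0910702.10FU;`), the package builds:

* **SH tables** (reference-based): reads are dereplicated into zOTUs
  (zero-radius OTUs), classified with a SINTAX-style k-mer bootstrap
  classifier (k = 8, 32 k-mers × 100 bootstraps), filtered on
  species-rank confidence *c* with a dual threshold — singleton zOTUs
  need *c* ≥ 0.95, multitons *c* ≥ 0.8 — and conspecific zOTUs are
  aggregated per UNITE species hypothesis (SH). Classifiability, not
  mean Phred, is the quality filter.
* **98% OTU tables** (de novo): quality-filtered reads are dereplicated,
  de novo chimera-flagged (two-parent single-crossover model), clustered
  greedily around abundance-sorted centroids at identity *t* = 0.98, and
  curated LULU-style (daughters merge into ≥ min-ratio more abundant,
  ≥ 84%-identical, co-occurring parents).

The quality question is answered by the evaluation layer: reads are
binned by probability-domain mean Phred score
`Q̄ = −10·log₁₀(mean_i 10^(−q_i/10))`, every bin is subsampled to a common
depth, the chosen approach is replicated per bin, and the stabilization
point Q\* is the first bin from which consecutive bin means change by at
most ε (default 5%) over a sliding window. The key identity is that a
clustering radius *r* corresponds to Phred `−10·log₁₀(r)` — for the 2%
radius of 98% OTUs that is **Q17**, below which per-base error alone
pushes reads outside their centroid's radius and OTU counts inflate.

A fully ground-truthed simulator (`nanoits.simulate`) generates mock
communities — 16 ITS-like taxa sharing a conserved 5.8S-like core, one
reference pair at 1.5% divergence (inside the 2% radius), reads at
controlled mean Phred with quality-conditioned substitution/indel errors,
primer flanks, random orientation, and optional chimeras — so every
pipeline stage can be tested against known truth.

## Worked example

```python
from nanoits import *

spec = MockSpec(seed=1)                    # 16 taxa, one pair at 1.5% divergence
db = generate_reference_set(spec)
reads = []
for q in range(18, 29):                    # one bin per target mean Phred
    r, _ = simulate_reads(db, spec, 600, quality_targets=[q], seed=7 + q)
    reads.extend(r)

primers = PrimerPair()                     # ITS1F / ITS4 defaults
trimmed = [t for t in (trim_and_orient(r, primers) for r in reads)
           if not isinstance(t, TrimRejection)]

params = EvalParams(depth=500, q_range=(18, 28), n_rep=5, approach="OTU", seed=1)
curve = recovery_curve(trimmed, params)
print(curve.summary().round(1))
print("Q* =", detect_stabilization(curve, window=3, epsilon=0.05))
```

prints

```
       mean_all  sd_all  mean_no_singletons  sd_no_singletons
q_bin
18        442.0     1.4                20.6               1.1
19        340.6     7.8                40.0               3.9
20        206.6     7.5                36.0               2.9
21         70.2     3.0                25.8               2.4
22         31.0     3.8                19.0               1.6
23         18.4     0.5                16.6               0.5
24         16.6     0.5                16.0               0.0
25         16.0     0.0                16.0               0.0
26         16.0     0.0                16.0               0.0
27         16.0     0.0                16.0               0.0
28         16.0     0.0                16.0               0.0
Q* = 24
```

At Q18 a 500-read subsample explodes into ~442 OTUs — most reads differ
from each other by more than the 2% radius through error alone — and the
inflation collapses as accuracy crosses the radius-equivalent quality,
stabilizing at Q24 with all 16 taxa recovered. Running the same bins with
`approach="SH"` and `db=db` yields exactly 16 SHs in **every** bin from
Q18 down: reference-based classification with the dual-confidence filter
is insensitive to mean Phred, which is precisely why it needs no
Phred-based filtering.

The same pipeline is exposed as a CLI over per-sample FASTQ folders:

```bash
nanoits samples/ --db refs.fasta --approach sh  --id 1    --q 0
nanoits samples/ --db refs.fasta --approach otu --id 0.98 --q 25 --sintax 0.8
```

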