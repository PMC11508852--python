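"""Independent oracles used to cross-check the implementation.

Each oracle takes a route different from the code under test: Biopython's
affine-gap aligner for identity, exhaustive breakpoint scanning for
chimera models, and single-linkage merging of reference sequences for
expected OTU counts.
"""

import warnings

import edlib
import numpy as np


def affine_identity(a: str, b: str) -> float:
    """Identity from an affine-gap global alignment (match +2,
    mismatch -4, gap open -10, extend -1), terminal gaps excluded from
    the column count.  Independent of the edlib-based implementation."""
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2
    al.mismatch_score = -4
    al.open_gap_score = -10
    al.extend_gap_score = -1
    aln = al.align(a, b)[0]
    s0, s1 = str(aln[0]), str(aln[1])
    start = 0
    end = len(s0)
    while start < end and (s0[start] == "-" or s1[start] == "-"):
        start += 1
    while end > start and (s0[end - 1] == "-" or s1[end - 1] == "-"):
        end -= 1
    cols = end - start
    matches = sum(1 for i in range(start, end) if s0[i] == s1[i])
    return matches / cols if cols else 0.0


def chimera_breakpoint_scan(
    query: str, parent_a: str, parent_b: str, max_diffs: int = 1, min_div: int = 4
) -> bool:
    """Exhaustive single-crossover scan: is `query` within `max_diffs` of
    some A-prefix + B-suffix model (independent cut points in A and B)
    while >= `min_div` from each whole parent?

    Scans every split of the query; the prefix is aligned to the best
    prefix of A and the suffix to the best suffix of B (semi-global
    alignments), which covers all single-crossover models.
    """
    for p in (parent_a, parent_b):
        if edlib.align(query, p, mode="NW")["editDistance"] < min_div:
            return False

    def _prefix_dist(q, t):
        if not q:
            return 0
        return edlib.align(q, t, mode="SHW")["editDistance"]

    rb = parent_b[::-1]
    for s in range(len(query) + 1):
        d = _prefix_dist(query[:s], parent_a) + _prefix_dist(query[s:][::-1], rb)
        if d <= max_diffs:
            return True
    return False


def expected_otu_count(ref_seqs, radius: float, identity_fn) -> int:
    """Single-linkage merge of references whose pairwise identity is
    within `radius` of 1; the component count is the error-free OTU count."""
    n = len(ref_seqs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if identity_fn(ref_seqs[i], ref_seqs[j]) >= 1.0 - radius:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})
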