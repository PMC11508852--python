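"""Dereplication, greedy centroid clustering, chimera flagging and
LULU-style post-clustering curation.

Reads are first collapsed into zOTUs (zero-radius OTUs: one unit per
distinct sequence, with per-sample abundances).  zOTUs are then either
used directly (reference-based workflows) or clustered greedily into
OTUs at a fixed identity threshold (default 98%), largest first, each
zOTU joining the best-matching existing centroid within the radius or
founding a new one.

Identity between two sequences is defined on an optimal global alignment
as matching columns divided by alignment columns, with terminal gaps
excluded from both counts.  The optimal alignment is computed under unit
edit costs (banded bit-parallel Levenshtein via edlib); at the identity
levels where thresholds act here (>= 84%) the identity value is
insensitive to the exact gap scoring, and the unit-cost optimum is exact
and fast enough for replicated whole-pipeline runs.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .preprocess import QualityRead

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ZOtu:
    """A dereplicated unique sequence with per-sample read counts."""

    seq: str
    size: int
    per_sample: dict[str, int]
    label: str = ""

    def __post_init__(self) -> None:
        if self.size != sum(self.per_sample.values()) or self.size < 1:
            raise ValueError("ZOtu size must equal the sum of per-sample counts (>= 1)")


@dataclass
class ClusterParams:
    """Greedy clustering parameters; ``radius`` is 1 - identity threshold."""

    identity_t: float = 0.98

    def __post_init__(self) -> None:
        if not 0.5 < self.identity_t <= 1.0:
            raise ValueError("identity_t must be in (0.5, 1.0]")

    @property
    def radius(self) -> float:
        return 1.0 - self.identity_t


@dataclass
class MatchList:
    """Pairwise identity rows (query, target, percent identity) above a cutoff."""

    rows: list[tuple[str, str, float]]
    min_match: float = 84.0

    def __post_init__(self) -> None:
        for q, t, pid in self.rows:
            if q == t:
                raise ValueError("match list must not contain self-matches")
            if pid < self.min_match:
                raise ValueError("match list row below its minimum-match cutoff")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for q, t, pid in self.rows:
                fh.write(f"{q}\t{t}\t{pid:.1f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, min_match: float = 84.0) -> "MatchList":
        rows = []
        with open(path) as fh:
            for line in fh:
                q, t, pid = line.rstrip("\n").split("\t")
                rows.append((q, t, float(pid)))
        return cls(rows, min_match)


class UnitTable:
    """Taxonomic units x samples count matrix with a unit-kind tag.

    Thin wrapper over a pandas DataFrame (units as rows, samples as
    columns, non-negative integer counts).  All-zero rows are dropped at
    construction.
    """

    def __init__(self, df: pd.DataFrame, kind: str):
        if kind not in ("zOTU", "OTU", "SH"):
            raise ValueError(f"unknown unit kind {kind!r}")
        df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise ValueError("unit table counts must be non-negative")
        self.df = df.loc[df.sum(axis=1) > 0].copy()
        self.kind = kind

    # -- basic accessors ----------------------------------------------------
    @property
    def units(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def n_units(self, exclude_singletons: bool = False) -> int:
        if exclude_singletons:
            return int((self.df.sum(axis=1) >= 2).sum())
        return len(self.df)

    def total(self) -> int:
        return int(self.df.to_numpy().sum())

    def unit_sizes(self) -> pd.Series:
        return self.df.sum(axis=1)

    def without_singletons(self) -> "UnitTable":
        return UnitTable(self.df.loc[self.df.sum(axis=1) >= 2], self.kind)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="unit")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "UnitTable":
        return cls(pd.read_csv(path, sep="\t", index_col="unit"), kind)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[str, int]], kind: str
    ) -> "UnitTable":
        df = pd.DataFrame(counts).T.fillna(0)
        return cls(df, kind)


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------

def dereplicate(reads: Iterable[QualityRead]) -> list[ZOtu]:
    """Collapse reads into zOTUs, one per distinct sequence string.

    Output is sorted by decreasing size, ties broken lexicographically by
    sequence; labels are assigned in that order (zOTU_1, zOTU_2, ...).
    The sum of zOTU sizes equals the number of input reads and per-sample
    counts are preserved.
    """
    per_seq: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for r in reads:
        per_seq[r.seq][r.sample] += 1
    zotus = [
        ZOtu(seq, sum(samples.values()), dict(samples))
        for seq, samples in per_seq.items()
    ]
    zotus.sort(key=lambda z: (-z.size, z.seq))
    for i, z in enumerate(zotus, start=1):
        z.label = f"zOTU_{i}"
    return zotus


def zotu_table(zotus: Sequence[ZOtu]) -> UnitTable:
    """Per-sample count table for a zOTU set."""
    return UnitTable.from_counts({z.label: z.per_sample for z in zotus}, "zOTU")


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

def _trimmed_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    return ops


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences in [0, 1].

    Matching columns over alignment columns, terminal gaps excluded on
    both ends; symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity: empty sequence")
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    ops = _trimmed_cigar(res["cigar"])
    columns = sum(n for n, _ in ops)
    matches = sum(n for n, op in ops if op == "=")
    if columns == 0:
        return 0.0
    return matches / columns


def _identity_if_at_least(a: str, b: str, threshold: float) -> float | None:
    """Identity of (a, b) if it can reach ``threshold``, else None.

    Uses a banded edit-distance prefilter: if the unit-cost edit distance
    exceeds a conservative bound implied by the threshold, identity is
    certainly below it and no alignment path is computed.
    """
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    k = int(np.ceil((1.0 - threshold) * (la + lb))) + abs(la - lb) + 2
    res = edlib.align(a, b, mode="NW", task="distance", k=k)
    if res["editDistance"] < 0:
        return None
    pid = pairwise_identity(a, b)
    return pid if pid >= threshold else None


# ---------------------------------------------------------------------------
# Greedy centroid clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    table: UnitTable
    centroids: dict[str, str]            # OTU label -> centroid sequence
    assignments: dict[str, str]          # zOTU label -> OTU label


def greedy_cluster(zotus: Sequence[ZOtu], params: ClusterParams) -> ClusterResult:
    """Greedy centroid clustering of size-sorted zOTUs.

    zOTUs are processed in decreasing size (ties lexicographic by
    sequence).  Each is assigned to the best-matching existing centroid
    with identity >= the threshold (ties broken by larger founder size,
    then lexicographic centroid sequence); otherwise it founds a new
    centroid.  OTU abundances are the per-sample sums over member zOTUs.
    """
    order = sorted(zotus, key=lambda z: (-z.size, z.seq))
    labels: list[str] = []
    seqs: list[str] = []
    founder_sizes: list[int] = []
    counts: dict[str, dict[str, int]] = {}
    assignments: dict[str, str] = {}
    for z in order:
        best: tuple[float, int, str, int] | None = None  # (pid, size, seq, idx)
        for i, cseq in enumerate(seqs):
            pid = _identity_if_at_least(z.seq, cseq, params.identity_t)
            if pid is None:
                continue
            key = (pid, founder_sizes[i], _lex_key(cseq))
            if best is None or key > (best[0], best[1], _lex_key(best[2])):
                best = (pid, founder_sizes[i], cseq, i)
        if best is None:
            label = f"OTU_{len(labels) + 1}"
            labels.append(label)
            seqs.append(z.seq)
            founder_sizes.append(z.size)
            counts[label] = defaultdict(int)
            idx = len(labels) - 1
        else:
            idx = best[3]
            label = labels[idx]
        for sample, n in z.per_sample.items():
            counts[label][sample] = counts[label].get(sample, 0) + n
        assignments[z.label or z.seq] = label
    table = UnitTable.from_counts(counts, "OTU")
    return ClusterResult(table, dict(zip(labels, seqs)), assignments)


def _lex_key(seq: str):
    # Lexicographically *smaller* sequence wins ties; invert for max().
    return tuple(-ord(c) for c in seq)


# ---------------------------------------------------------------------------
# De novo chimera detection
# ---------------------------------------------------------------------------

def _query_mismatch_profile(query: str, parent: str) -> np.ndarray:
    """Per-query-position mismatch indicator from an optimal alignment.

    Substitutions and query insertions are charged to their query
    position; parent deletions are charged to the current query position.
    Entry [i] of the returned length-(L+1) cumulative array is the number
    of differences in query[:i].
    """
    res = edlib.align(query, parent, mode="NW", task="path")
    diffs = np.zeros(len(query) + 1, dtype=np.int32)
    pos = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op == "=":
            pos += n
        elif op in ("X", "I"):
            diffs[pos : pos + n] += 1
            pos += n
        else:  # D: parent bases absent from query
            diffs[min(pos, len(query))] += n
    return np.concatenate(([0], np.cumsum(diffs[: len(query)])))


def detect_chimeras(
    zotus: Sequence[ZOtu],
    max_chimera_diffs: int = 1,
    min_div: int = 4,
    parent_ratio: float = 2.0,
) -> dict[str, bool]:
    """Flag zOTUs explainable as two-parent, single-crossover chimeras.

    A query is flagged when two distinct parents, each at least
    ``parent_ratio`` times as abundant, admit a breakpoint such that the
    prefix-from-parent-A + suffix-from-parent-B model differs from the
    query by at most ``max_chimera_diffs``, while each single parent
    alone differs from the query by at least ``min_div``.  The
    most-abundant zOTU can never be flagged (no eligible parents).
    """
    order = sorted(zotus, key=lambda z: (-z.size, z.seq))
    flags: dict[str, bool] = {}
    for qi, q in enumerate(order):
        key = q.label or q.seq
        flags[key] = False
        parents = [p for p in order if p.size >= parent_ratio * q.size and p.seq != q.seq]
        if len(parents) < 2:
            continue
        eligible: list[np.ndarray] = []
        for p in parents:
            dist = edlib.align(q.seq, p.seq, mode="NW", task="distance")["editDistance"]
            if dist < min_div:
                eligible = []
                break  # near-copy of an abundant parent: not a chimera
            eligible.append(_query_mismatch_profile(q.seq, p.seq))
        if len(eligible) < 2:
            continue
        prefix = np.stack(eligible)                       # (P, L+1) diffs in q[:i]
        totals = prefix[:, -1][:, None]
        suffix = totals - prefix                          # diffs in q[i:]
        # Best two-parent model: min over breakpoints of best prefix parent +
        # best (different) suffix parent.
        best_pre_idx = np.argmin(prefix, axis=0)
        best_suf_idx = np.argmin(suffix, axis=0)
        best_pre = prefix[best_pre_idx, np.arange(prefix.shape[1])]
        best_suf = suffix[best_suf_idx, np.arange(suffix.shape[1])]
        combined = best_pre + best_suf
        clash = best_pre_idx == best_suf_idx
        if clash.any() and prefix.shape[0] >= 2:
            masked_pre = prefix.copy().astype(float)
            masked_pre[best_pre_idx, np.arange(prefix.shape[1])] = np.inf
            second_pre = masked_pre.min(axis=0)
            masked_suf = suffix.copy().astype(float)
            masked_suf[best_suf_idx, np.arange(suffix.shape[1])] = np.inf
            second_suf = masked_suf.min(axis=0)
            alt = np.minimum(best_pre + second_suf, second_pre + best_suf)
            combined = np.where(clash, alt, combined)
        if combined.min() <= max_chimera_diffs:
            flags[key] = True
    return flags


def remove_chimeras(
    zotus: Sequence[ZOtu], **kwargs
) -> tuple[list[ZOtu], list[ZOtu]]:
    """Split a zOTU set into (kept, flagged-as-chimera) using
    :func:`detect_chimeras` defaults."""
    flags = detect_chimeras(zotus, **kwargs)
    kept = [z for z in zotus if not flags[z.label or z.seq]]
    flagged = [z for z in zotus if flags[z.label or z.seq]]
    return kept, flagged


# ---------------------------------------------------------------------------
# LULU match list + curation
# ---------------------------------------------------------------------------

def build_match_list(
    centroids: Mapping[str, str], min_match: float = 84.0
) -> MatchList:
    """All ordered centroid pairs with pairwise identity >= ``min_match`` %."""
    if len(centroids) < 2:
        raise ValueError("build_match_list requires at least two centroids")
    labels = list(centroids)
    rows: list[tuple[str, str, float]] = []
    for i, qi in enumerate(labels):
        for qj in labels:
            if qi == qj:
                continue
            pid = _identity_if_at_least(centroids[qi], centroids[qj], min_match / 100.0)
            if pid is not None:
                rows.append((qi, qj, pid * 100.0))
    return MatchList(rows, min_match)


def lulu_curate(
    table: UnitTable,
    matches: MatchList,
    min_ratio: float = 1.0,
    min_cooccurrence: float = 0.95,
) -> tuple[UnitTable, list[tuple[str, str]]]:
    """Merge low-abundance daughter units into sequence-similar,
    co-occurring, more abundant parents (LULU-style curation).

    Daughters are processed from least to most abundant.  A daughter
    merges into its best-matching (highest identity) more abundant
    parent when the parent is present in at least ``min_cooccurrence``
    of the daughter's occupied samples and the parent/daughter ratio in
    those samples is at least ``min_ratio``.  Counts are conserved.
    Returns the curated table and a (daughter, parent) merge log.
    """
    df = table.df.copy()
    by_query: dict[str, list[tuple[float, str]]] = defaultdict(list)
    for q, t, pid in matches.rows:
        by_query[q].append((pid, t))
    totals0 = df.sum(axis=1)
    order = list(totals0.sort_values(kind="stable").index)
    redirect: dict[str, str] = {}
    merge_log: list[tuple[str, str]] = []
    for daughter in order:
        if daughter not in df.index:
            continue
        drow = df.loc[daughter]
        dtotal = drow.sum()
        occupied = drow[drow > 0].index
        if len(occupied) == 0:
            continue
        cands = sorted(by_query.get(daughter, []), reverse=True)
        for pid, parent in cands:
            while parent in redirect:
                parent = redirect[parent]
            if parent == daughter or parent not in df.index:
                continue
            prow = df.loc[parent]
            if prow.sum() <= dtotal:
                continue
            co = (prow[occupied] > 0)
            if co.mean() < min_cooccurrence:
                continue
            shared = occupied[co]
            ratios = prow[shared] / drow[shared]
            if len(shared) == 0 or ratios.min() < min_ratio:
                continue
            df.loc[parent] += drow
            df = df.drop(index=daughter)
            redirect[daughter] = parent
            merge_log.append((daughter, parent))
            break
    return UnitTable(df, table.kind), merge_log


# ---------------------------------------------------------------------------
# FASTA output for centroids / zOTUs
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n{seq}\n")
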