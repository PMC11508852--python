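"""Read-level preprocessing for long-read amplicon data.

Covers the stages that sit between basecalled FASTQ and taxonomic-unit
construction: FASTQ I/O, primer-based reorientation and trimming,
probability-domain mean-Phred computation, quality stratification into
integer Q bins, and seeded subsampling to a fixed depth.

The central quality statistic is the *mean Phred score* of a read,
computed in probability domain::

    mean_q = -10 * log10( mean_i 10^(-q_i / 10) )

i.e. the Phred transform of the mean per-base error probability.  This is
the read-quality convention used by long-read quality filters; it is
always <= the arithmetic mean of the per-base Phred values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

PHRED_OFFSET = 33

#: IUPAC nucleotide ambiguity codes -> set of plain bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)

#: additionalEqualities for edlib so primer ambiguity codes match plain bases.
IUPAC_EQUALITIES = [
    (code, base) for code, bases in IUPAC.items() for base in bases if code != base
]

#: ITS1F / ITS4, the classic full-ITS fungal primer pair.  These are
#: defaults only; any pair can be supplied through :class:`PrimerPair`.
ITS1F = "CTTGGTCATTTAGAGGAAGTAA"
ITS4 = "TCCTCCGCTTATTGATATGC"


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Phred arithmetic
# ---------------------------------------------------------------------------

def mean_phred(quals: Sequence[int] | np.ndarray) -> float:
    """Probability-domain mean Phred score of a quality vector.

    Converts each per-base Phred value to an error probability, averages
    the probabilities, and converts back.  Raises ``ValueError`` on an
    empty vector.
    """
    q = np.asarray(quals, dtype=float)
    if q.size == 0:
        raise ValueError("mean_phred: empty quality vector")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def accuracy_from_phred(q: float) -> float:
    """Expected base-call accuracy (percent) at Phred score ``q``.

    Q10 -> 90.0, Q30 -> 99.9.
    """
    if q < 0:
        raise ValueError("Phred score must be >= 0")
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))


def phred_from_error(p: float) -> float:
    """Phred score for a per-base error probability ``p`` in (0, 1]."""
    if p <= 0 or p > 1:
        raise ValueError("error probability must be in (0, 1]")
    return float(-10.0 * np.log10(p))


def phred_for_radius(radius: float) -> int:
    """Phred score at which the expected per-base error rate equals a
    clustering radius.

    For a 98% OTU radius of 0.02 this is Q17: below it, per-read error
    alone can push a read outside its centroid's radius, inflating OTU
    counts; above it, errors stop dominating clustering.
    """
    if not 0 < radius < 1:
        raise ValueError("radius must be in (0, 1)")
    return int(round(-10.0 * np.log10(radius)))


# ---------------------------------------------------------------------------
# Core read type
# ---------------------------------------------------------------------------

@dataclass
class QualityRead:
    """A sequence with per-base Phred qualities and a sample label."""

    id: str
    seq: str
    quals: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        if self.quals.size and (self.quals.min() < 0 or self.quals.max() > 93):
            raise ValueError(f"record {self.id!r}: Phred values outside [0, 93]")

    @property
    def mean_q(self) -> float:
        """Probability-domain mean Phred score of the read."""
        return mean_phred(self.quals)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PrimerPair:
    """Forward/reverse amplification primers with a mismatch budget.

    ``max_mismatch`` is the per-primer edit-distance budget (substitutions
    and indels) for locating a primer at a read end.
    """

    forward: str = ITS1F
    reverse: str = ITS4
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.max_mismatch >= min(len(self.forward), len(self.reverse)):
            raise ValueError("max_mismatch must be smaller than the primer length")


@dataclass
class TrimRejection:
    """Outcome of :func:`trim_and_orient` for a read that failed primer location."""

    read_id: str
    reason: str


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path, sample: str = "") -> list[QualityRead]:
    """Read a Phred+33 FASTQ file into :class:`QualityRead` records.

    A record whose sequence and quality strings disagree in length raises
    ``ValueError`` naming the record.
    """
    reads: list[QualityRead] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
            reads.append(QualityRead(rec.id, str(rec.seq).upper(), quals, sample))
    except ValueError as exc:
        # Biopython reports the offending title; keep it in our message.
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    """Write reads as 4-line Phred+33 FASTQ (byte-stable for round trips)."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Primer reorientation / trimming
# ---------------------------------------------------------------------------

def _locate_primer(primer: str, window: str, max_mismatch: int):
    """Best infix match of ``primer`` in ``window``; (distance, start, end)."""
    import edlib

    res = edlib.align(
        primer, window, mode="HW", task="locations", k=max_mismatch,
        additionalEqualities=IUPAC_EQUALITIES,
    )
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1


def _match_ends(seq: str, primers: PrimerPair):
    """Locate forward primer at the 5' end and the reverse primer's
    reverse-complement at the 3' end; returns (total_dist, cut5, cut3) or None."""
    fwd = primers.forward
    rev_rc = reverse_complement(primers.reverse)
    head = seq[: len(fwd) + 15]
    tail_off = max(0, len(seq) - (len(rev_rc) + 15))
    tail = seq[tail_off:]
    hit_f = _locate_primer(fwd, head, primers.max_mismatch)
    hit_r = _locate_primer(rev_rc, tail, primers.max_mismatch)
    return hit_f, hit_r, tail_off


def trim_and_orient(
    read: QualityRead, primers: PrimerPair
) -> QualityRead | TrimRejection:
    """Reorient a read to forward-primer-first and cut both primer flanks.

    The read is reverse-complemented when the forward primer matches the
    reverse strand better.  Qualities are trimmed in lockstep with the
    sequence.  Reads lacking either primer within ``max_mismatch`` are
    returned as :class:`TrimRejection` with a reason code
    (``forward_primer_not_found`` / ``reverse_primer_not_found`` /
    ``empty_interior``) rather than raising.
    """
    candidates = []
    for flipped in (False, True):
        if flipped:
            seq = reverse_complement(read.seq)
            quals = read.quals[::-1]
        else:
            seq, quals = read.seq, read.quals
        hit_f, hit_r, tail_off = _match_ends(seq, primers)
        score = (hit_f[0] if hit_f else primers.max_mismatch + 1) + (
            hit_r[0] if hit_r else primers.max_mismatch + 1
        )
        candidates.append((score, flipped, seq, quals, hit_f, hit_r, tail_off))
    candidates.sort(key=lambda c: (c[0], c[1]))  # prefer forward on ties
    score, flipped, seq, quals, hit_f, hit_r, tail_off = candidates[0]
    if hit_f is None:
        return TrimRejection(read.id, "forward_primer_not_found")
    if hit_r is None:
        return TrimRejection(read.id, "reverse_primer_not_found")
    cut5 = hit_f[2]
    cut3 = tail_off + hit_r[1]
    if cut3 <= cut5:
        return TrimRejection(read.id, "empty_interior")
    return QualityRead(read.id, seq[cut5:cut3], quals[cut5:cut3], read.sample)


def head_trim(read: QualityRead, n_bases: int) -> QualityRead:
    """Remove the first ``n_bases`` from sequence and qualities.

    Used to strip the low-quality leading stretch typical of Nanopore
    reads before re-evaluating mean quality.
    """
    if n_bases < 0 or n_bases >= len(read):
        raise ValueError(
            f"head_trim: n_bases {n_bases} out of range for length {len(read)}"
        )
    return QualityRead(read.id, read.seq[n_bases:], read.quals[n_bases:], read.sample)


# ---------------------------------------------------------------------------
# Quality stratification / subsampling
# ---------------------------------------------------------------------------

def phred_bin(mean_q: float) -> int:
    """Integer Q bin for a mean Phred score (round half up)."""
    return int(np.floor(mean_q + 0.5))


def stratify_by_phred(
    reads: Iterable[QualityRead], q_min: int, q_max: int
) -> dict[int, list[QualityRead]]:
    """Partition reads into integer mean-Phred bins within [q_min, q_max].

    A read is assigned to ``round(mean_q)`` (half up); reads binning
    outside the range are dropped.  The returned dict has one entry per
    bin in the range (possibly empty lists).
    """
    if q_min > q_max:
        raise ValueError("q_min must be <= q_max")
    bins: dict[int, list[QualityRead]] = {q: [] for q in range(q_min, q_max + 1)}
    for r in reads:
        b = phred_bin(r.mean_q)
        if q_min <= b <= q_max:
            bins[b].append(r)
    return bins


def subsample(
    reads: Sequence[QualityRead], depth: int, seed: int
) -> list[QualityRead]:
    """Draw exactly ``depth`` reads uniformly without replacement.

    Deterministic for a fixed seed; the selection is returned in input
    order.  Raises ``ValueError`` when fewer than ``depth`` reads are
    available.
    """
    if depth > len(reads):
        raise ValueError(
            f"subsample: requested depth {depth} exceeds {len(reads)} available reads"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=depth, replace=False))
    return [reads[i] for i in idx]


def write_stage_log(
    rows: Iterable[tuple[str, str, str, str]], path: str | Path
) -> None:
    """Write a per-stage action log as TSV: read_id, stage, action, reason."""
    with open(path, "w") as fh:
        fh.write("read_id\tstage\taction\treason\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
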