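"""Mock-community simulation: references, Nanopore-like reads, chimeras.

The generator stands in for a sequenced mock community of phylogenetically
diverse ectomycorrhizal taxa.  Defaults mirror the study conditions this
toolkit is evaluated under: 16 taxa, amplicons of 600-800 bp (median near
the ~709 bp observed for full-ITS fungal amplicons), one near-neighbour
reference pair at 1.5% divergence (inside the 2% radius of 98% OTU
clustering, so the pair merges under de novo clustering exactly as truly
close congeners do), and reads at controlled probability-domain mean
Phred scores.

Every reference shares a fixed 150 bp conserved core (emulating the
5.8S region) embedded in otherwise random ITS-like sequence, so k-mer
classifiers and cross-taxon chimeras face realistic shared signal.

Reads are emitted with forward/reverse primer flanks and random strand
orientation so primer reorientation/trimming is exercised.  Errors are
injected per base at rate ``10^(-q/10)`` for that base's Phred value,
between the primer flanks; the error-class mix (substitution, insertion,
deletion) is configurable.  Each emitted read carries exactly one ground
truth record (source taxon, chimera parents/breakpoint, realized error
count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import RefRecord, ReferenceDB
from .preprocess import ITS1F, ITS4, QualityRead, mean_phred, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Shared conserved core ("5.8S-like"): fixed across all generated taxa.
_core_rng = np.random.default_rng(58000)
CONSERVED_CORE = "".join(chr(b) for b in _BASES[_core_rng.integers(0, 4, 150)])


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class MockSpec:
    """Mock-community layout.

    ``near_pairs`` lists (divergence fraction, count) entries: for each,
    ``count`` references are created by duplicating an existing reference
    and mutating it to the stated pairwise divergence.  The total number
    of references is ``n_taxa`` (near-pair partners included).
    """

    n_taxa: int = 16
    length_range: tuple[int, int] = (600, 800)
    near_pairs: Sequence[tuple[float, int]] = ((0.015, 1),)
    abundance_profile: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        for d, count in self.near_pairs:
            if not 0 < d <= 0.1:
                raise ValueError("near-pair divergence must be in (0, 0.1]")
            if count < 1:
                raise ValueError("near-pair count must be >= 1")
        n_dup = sum(c for _, c in self.near_pairs)
        if n_dup >= self.n_taxa:
            raise ValueError("near-pair partners must leave >= 1 independent taxon")
        if self.abundance_profile is not None:
            p = np.asarray(self.abundance_profile, dtype=float)
            if len(p) != self.n_taxa or not np.isclose(p.sum(), 1.0):
                raise ValueError("abundance_profile must have n_taxa entries summing to 1")


@dataclass
class ErrorModel:
    """Error-class mix and per-base quality spread.

    Fractions give the share of injected errors that are substitutions,
    insertions and deletions (they must sum to 1); the default
    0.5 : 0.25 : 0.25 split is a Nanopore-like convention.
    ``qual_spread`` is the per-base Phred standard deviation around a
    read's target mean.
    """

    sub_fraction: float = 0.5
    ins_fraction: float = 0.25
    del_fraction: float = 0.25
    qual_spread: float = 3.0

    def __post_init__(self) -> None:
        fr = (self.sub_fraction, self.ins_fraction, self.del_fraction)
        if any(f < 0 for f in fr) or not np.isclose(sum(fr), 1.0):
            raise ValueError("error-class fractions must be non-negative and sum to 1")


@dataclass
class GroundTruthRecord:
    read_id: str
    taxon: str
    is_chimera: bool
    parent_a: str | None
    parent_b: str | None
    breakpoint: int | None
    n_errors: int


@dataclass
class GroundTruth:
    records: list[GroundTruthRecord]

    def __len__(self) -> int:
        return len(self.records)

    def by_read(self) -> dict[str, GroundTruthRecord]:
        return {r.read_id: r for r in self.records}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "read_id\ttaxon\tis_chimera\tparent_a\tparent_b\tbreakpoint\tn_errors\n"
            )
            for r in self.records:
                fh.write(
                    f"{r.read_id}\t{r.taxon}\t{int(r.is_chimera)}\t"
                    f"{r.parent_a or '-'}\t{r.parent_b or '-'}\t"
                    f"{'-' if r.breakpoint is None else r.breakpoint}\t{r.n_errors}\n"
                )


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

_PHYLA = ("Mockomycota", "Fictobasidiomycota", "Pseudoascomycota", "Terramycota")


def _dummy_lineage(i: int, sh_index: int) -> dict[str, str]:
    return {
        "d": "Fungi",
        "p": _PHYLA[i % len(_PHYLA)],
        "c": f"Class{i % len(_PHYLA):02d}",
        "o": f"Order{i:02d}",
        "f": f"Family{i:02d}",
        "g": f"Genus{i:02d}",
        "s": f"SH{sh_index:07d}.10FU",
    }


def _random_its(rng: np.random.Generator, length: int) -> str:
    """Random ITS-like sequence with the conserved core embedded mid-sequence."""
    flank = max(length - len(CONSERVED_CORE), 2)
    left = flank // 2
    right = flank - left
    seq = "".join(
        chr(b) for b in _BASES[rng.integers(0, 4, left + right)]
    )
    return seq[:left] + CONSERVED_CORE + seq[left:]


def _mutate_to_divergence(
    seq: str, divergence: float, rng: np.random.Generator
) -> str:
    n_mut = int(round(divergence * len(seq)))
    core_start = seq.find(CONSERVED_CORE)
    if core_start >= 0:
        allowed = np.concatenate(
            [
                np.arange(core_start),
                np.arange(core_start + len(CONSERVED_CORE), len(seq)),
            ]
        )
    else:
        allowed = np.arange(len(seq))
    if not 1 <= n_mut <= len(allowed):
        raise ValueError(
            f"divergence {divergence} unreachable for length {len(seq)} reference"
        )
    positions = rng.choice(allowed, size=n_mut, replace=False)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_reference_set(spec: MockSpec) -> ReferenceDB:
    """Generate a mock reference set with SINTAX-style dummy lineages.

    Independent references are mutually divergent random ITS-like
    sequences sharing only the conserved core; near-pair partners are
    mutated copies at the stated divergence, sharing their source's
    lineage down to genus but carrying their own dummy SH code.
    """
    rng = np.random.default_rng(spec.seed)
    n_dup = sum(c for _, c in spec.near_pairs)
    n_independent = spec.n_taxa - n_dup
    records: list[RefRecord] = []
    for i in range(n_independent):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _random_its(rng, length)
        records.append(RefRecord(f"MOCK{i + 1:04d}", seq, _dummy_lineage(i, i + 1)))
    sh_index = n_independent + 1
    src = 0
    for divergence, count in spec.near_pairs:
        for _ in range(count):
            source = records[src % n_independent]
            src += 1
            seq = _mutate_to_divergence(source.seq, divergence, rng)
            lineage = dict(source.lineage)
            lineage["s"] = f"SH{sh_index:07d}.10FU"
            records.append(
                RefRecord(f"MOCK{len(records) + 1:04d}", seq, lineage)
            )
            sh_index += 1
    return ReferenceDB(records)


# ---------------------------------------------------------------------------
# Quality strings
# ---------------------------------------------------------------------------

def make_quality_string(
    target_mean_q: float,
    length: int,
    model: ErrorModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Integer Phred vector whose probability-domain mean is within
    +/- 0.5 of ``target_mean_q``.

    Per-base values are drawn Normal(target, qual_spread), clipped to
    [2, 50], then shifted iteratively: clipping and the convexity of the
    probability-domain mean both bias the realized mean, so a scalar
    offset is adjusted until the target is met.
    """
    if not 2 <= target_mean_q <= 50:
        raise ValueError("target_mean_q must be in [2, 50]")
    if length < 1:
        raise ValueError("length must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base = rng.normal(target_mean_q, model.qual_spread, length)
    offset = 0.0
    for _ in range(60):
        quals = np.clip(np.rint(base + offset), 2, 50).astype(np.int16)
        realized = mean_phred(quals)
        if abs(realized - target_mean_q) <= 0.45:
            return quals
        offset += np.clip(target_mean_q - realized, -2.0, 2.0)
    return quals  # at the clip boundary the closest achievable vector


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _homologous_position(a: str, b: str, pos_a: int) -> int:
    """Position in ``b`` aligned to ``pos_a`` of ``a`` (template switching
    happens at homologous sites, so chimera junctions carry no indel)."""
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    ia = ib = 0
    import re as _re

    for n, op in _re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        if op in ("=", "X", "M"):
            if ia + n > pos_a:
                return ib + (pos_a - ia)
            ia += n
            ib += n
        elif op == "I":  # bases of a absent from b
            if ia + n > pos_a:
                return ib
            ia += n
        else:  # D: bases of b absent from a
            ib += n
    return min(ib, len(b))


def _inject_errors(
    template: str,
    quals: np.ndarray,
    model: ErrorModel,
    target_q: int,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray, int]:
    """Inject quality-conditioned errors; returns (seq, quals, n_errors)."""
    arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    L = len(arr)
    p_err = 10.0 ** (-quals.astype(float) / 10.0)
    err = rng.random(L) < p_err
    n_err = int(err.sum())
    if n_err == 0:
        return template, quals, 0
    classes = rng.choice(
        3, size=n_err, p=[model.sub_fraction, model.ins_fraction, model.del_fraction]
    )
    err_idx = np.nonzero(err)[0]
    sub_idx = err_idx[classes == 0]
    ins_idx = err_idx[classes == 1]
    del_idx = err_idx[classes == 2]
    # substitutions: shift by 1-3 within ACGT, never the same base
    cur = np.searchsorted(_BASES, arr[sub_idx])
    arr[sub_idx] = _BASES[(cur + rng.integers(1, 4, size=len(sub_idx))) % 4]
    # indels via repeat counts: deleted positions vanish, inserted
    # positions occupy two output slots (original base + random base)
    counts = np.ones(L, dtype=np.int64)
    counts[del_idx] = 0
    counts[ins_idx] = 2
    out_seq = np.repeat(arr, counts)
    out_quals = np.repeat(quals, counts)
    if len(ins_idx):
        slot = np.cumsum(counts)[ins_idx] - 1  # second copy of each inserted position
        out_seq[slot] = _BASES[rng.integers(0, 4, size=len(ins_idx))]
        out_quals[slot] = target_q
    return out_seq.tobytes().decode(), out_quals, n_err


def simulate_reads(
    db: ReferenceDB,
    spec: MockSpec,
    n_reads: int,
    quality_targets: Sequence[float],
    chimera_rate: float = 0.0,
    model: ErrorModel | None = None,
    seed: int = 0,
    sample: str = "mock1",
    forward_primer: str = ITS1F,
    reverse_primer: str = ITS4,
    inject_errors: bool = True,
) -> tuple[list[QualityRead], GroundTruth]:
    """Simulate ground-truthed amplicon reads from a mock reference set.

    Each read copies one reference (or, with probability
    ``chimera_rate``, a single-breakpoint two-parent chimera whose
    breakpoint falls in the middle 80% of the amplicon), receives a
    per-base quality string targeting a mean Phred drawn uniformly from
    ``quality_targets``, has errors injected between the primer flanks at
    each base's Phred-implied rate, and is emitted with primer flanks in
    random orientation (50% reverse-complemented).
    """
    if len(db) == 0:
        raise ValueError("simulate_reads: empty reference database")
    if not 0 <= chimera_rate <= 1:
        raise ValueError("chimera_rate must be in [0, 1]")
    if model is None:
        model = ErrorModel()
    rng = np.random.default_rng(seed)
    if spec.abundance_profile is not None:
        probs = np.asarray(spec.abundance_profile, dtype=float)
    else:
        probs = np.full(len(db), 1.0 / len(db))
    if len(probs) != len(db):
        raise ValueError("abundance profile length must match database size")
    fwd = forward_primer.upper()
    rev_rc = reverse_complement(reverse_primer.upper())
    reads: list[QualityRead] = []
    truth: list[GroundTruthRecord] = []
    for i in range(n_reads):
        rid = f"read_{i:06d}"
        target = float(quality_targets[rng.integers(len(quality_targets))])
        target_int = int(round(target))
        chimeric = len(db) >= 2 and rng.random() < chimera_rate
        if chimeric:
            ia, ib = rng.choice(len(db), size=2, replace=False, p=probs)
            a, b = db.records[int(ia)], db.records[int(ib)]
            u = rng.uniform(0.1, 0.9)
            bp_a = int(round(u * len(a.seq)))
            bp_b = _homologous_position(a.seq, b.seq, bp_a)
            template = a.seq[:bp_a] + b.seq[bp_b:]
            taxon, pa, pb, bp = a.accession, a.accession, b.accession, bp_a
        else:
            ia = int(rng.choice(len(db), p=probs))
            rec = db.records[ia]
            template = rec.seq
            taxon, pa, pb, bp = rec.accession, None, None, None
        quals = make_quality_string(target, len(template), model, rng)
        if inject_errors:
            seq, quals, n_err = _inject_errors(template, quals, model, target_int, rng)
        else:
            seq, n_err = template, 0
        full_seq = fwd + seq + rev_rc
        flank_q = np.full(len(fwd), target_int, dtype=np.int16)
        tail_q = np.full(len(rev_rc), target_int, dtype=np.int16)
        full_quals = np.concatenate([flank_q, quals, tail_q])
        if rng.random() < 0.5:
            full_seq = reverse_complement(full_seq)
            full_quals = full_quals[::-1]
        reads.append(QualityRead(rid, full_seq, full_quals, sample))
        truth.append(GroundTruthRecord(rid, taxon, chimeric, pa, pb, bp, n_err))
    return reads, GroundTruth(truth)
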