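"""SINTAX-style k-mer bootstrap taxonomy classification.

The reference database is a FASTA file whose headers carry a taxonomy
string in SINTAX format::

    >UDB05341741;tax=d:Fungi,p:Rozellomycota,s:SH0910702.10FU;

Ranks are single-letter prefixed (d, p, c, o, f, g, s) and intermediate
ranks may be missing.  The species rank holds a UNITE species hypothesis
(SH) code where available; user references absent from UNITE are added
under *dummy* SH codes (SH0000001.10FU style) so they flow through SH
aggregation like any database taxon.

Classification follows the SINTAX scheme: for each of ``n_boot``
bootstraps, ``n_kmers`` k-mers are drawn from the query with
replacement and the reference sharing the most of them is the
bootstrap's top hit (ties broken by a seeded uniform choice).  Per-rank
confidence is the fraction of bootstraps whose top hit carries that
rank's value; because a species vote implies votes for its whole
lineage, confidences are non-increasing from domain to species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cluster import UnitTable, ZOtu

RANKS = ("d", "p", "c", "o", "f", "g", "s")
SH_PATTERN = re.compile(r"SH\d{7}\.10FU$")


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

@dataclass
class RefRecord:
    accession: str
    seq: str
    lineage: dict[str, str]  # rank letter -> name, in RANKS order

    @property
    def species(self) -> str | None:
        return self.lineage.get("s")


class ReferenceDB:
    """Taxonomy-annotated reference sequences with a cached k-mer index."""

    def __init__(self, records: Sequence[RefRecord] | None = None):
        self.records: list[RefRecord] = list(records or [])
        self._index_cache: dict[int, dict] = {}

    def __len__(self) -> int:
        return len(self.records)

    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def species_codes(self) -> list[str]:
        return [r.lineage["s"] for r in self.records if "s" in r.lineage]

    def add(self, record: RefRecord) -> None:
        self.records.append(record)
        self._index_cache.clear()

    # -- k-mer index --------------------------------------------------------
    def kmer_index(self, k: int) -> dict:
        """Map from encoded k-mer to array of reference indices containing it."""
        if k not in self._index_cache:
            hits: dict[int, list[int]] = {}
            for i, rec in enumerate(self.records):
                for km in set(_encode_kmers(rec.seq, k).tolist()):
                    hits.setdefault(km, []).append(i)
            self._index_cache[k] = {
                km: np.asarray(idx, dtype=np.int32) for km, idx in hits.items()
            }
        return self._index_cache[k]


_BASE_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Encode all ACGT k-mers of ``seq`` as integers; ambiguous bases break k-mers."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    vals = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        vals = (vals << 2) | np.maximum(window, 0).astype(np.int64)
        ok &= valid[j : j + n]
    return vals[ok]


# ---------------------------------------------------------------------------
# SINTAX FASTA I/O
# ---------------------------------------------------------------------------

def _parse_tax(tax: str, accession: str) -> dict[str, str]:
    tax = tax.rstrip(";").strip()
    if not tax:
        raise ValueError(f"record {accession!r}: empty taxonomy string")
    lineage: dict[str, str] = {}
    for part in tax.split(","):
        if ":" not in part:
            raise ValueError(f"record {accession!r}: malformed taxonomy field {part!r}")
        rank, name = part.split(":", 1)
        if rank not in RANKS:
            raise ValueError(f"record {accession!r}: unknown rank prefix {rank!r}")
        lineage[rank] = name
    return lineage


def load_sintax_db(path: str | Path) -> ReferenceDB:
    """Load a SINTAX-format FASTA reference database.

    Headers must contain ``;tax=``; intermediate ranks may be missing and
    a trailing semicolon is tolerated.  A header without a taxonomy
    string raises ``ValueError`` naming the record.
    """
    records: list[RefRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        if ";tax=" not in header:
            raise ValueError(f"record {header!r}: missing ';tax=' annotation")
        accession, tax = header.split(";tax=", 1)
        records.append(
            RefRecord(accession, "".join(chunks).upper(), _parse_tax(tax, accession))
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                _flush()
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line.strip())
        _flush()
    return ReferenceDB(records)


def write_sintax_db(db: ReferenceDB, path: str | Path) -> None:
    """Write a reference database in the exact SINTAX header grammar."""
    with open(path, "w") as fh:
        for rec in db.records:
            tax = ",".join(f"{r}:{rec.lineage[r]}" for r in RANKS if r in rec.lineage)
            fh.write(f">{rec.accession};tax={tax};\n{rec.seq}\n")


def add_reference(
    db: ReferenceDB,
    seq: str,
    lineage: Mapping[str, str],
    accession: str | None = None,
) -> ReferenceDB:
    """Append a user reference carrying a dummy SH code to the database.

    The species rank must hold an unused code matching ``SH\\d{7}.10FU``.
    Modifies ``db`` in place (the k-mer index is rebuilt lazily) and
    returns it.
    """
    sh = lineage.get("s")
    if sh is None or not SH_PATTERN.match(sh):
        raise ValueError(f"species rank must hold an SH-style code, got {sh!r}")
    if sh in db.species_codes():
        raise ValueError(f"SH code {sh} already present in database")
    if accession is None:
        accession = f"USER{len(db.records) + 1:05d}"
    db.add(RefRecord(accession, seq.upper(), dict(lineage)))
    return db


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifyParams:
    """SINTAX hyperparameters and the dual classifiability cutoffs.

    ``singleton_cutoff``/``multiton_cutoff`` are the species-rank
    confidence thresholds used by :func:`apply_confidence_filter`:
    stricter (0.95) for single-read zOTUs, relaxed (0.8) for multi-read
    zOTUs, which are less likely to be dominated by sequencing error.
    """

    k: int = 8
    n_boot: int = 100
    n_kmers: int = 32
    singleton_cutoff: float = 0.95
    multiton_cutoff: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.multiton_cutoff <= self.singleton_cutoff <= 1):
            raise ValueError(
                "cutoffs must satisfy 0 <= multiton_cutoff <= singleton_cutoff <= 1"
            )


@dataclass
class Classification:
    """Per-rank predictions with confidences, plus the modal top hit."""

    ranks: dict[str, tuple[str | None, float]]  # rank -> (name, confidence)
    top_hit: str | None

    def name(self, rank: str) -> str | None:
        return self.ranks.get(rank, (None, 0.0))[0]

    def confidence(self, rank: str) -> float:
        return self.ranks.get(rank, (None, 0.0))[1]

    @property
    def species(self) -> str | None:
        return self.name("s")

    @property
    def species_confidence(self) -> float:
        return self.confidence("s")

    @property
    def unclassifiable(self) -> bool:
        return all(conf == 0.0 for _, conf in self.ranks.values())


def sintax_classify(
    query: str,
    db: ReferenceDB,
    params: ClassifyParams,
    rng: np.random.Generator | None = None,
) -> Classification:
    """Classify one query sequence against the reference database.

    Each bootstrap samples ``n_kmers`` query k-mers with replacement and
    votes for the reference sharing most of them; bootstraps whose best
    hit shares no k-mer cast no vote.  Per-rank confidence is the voted
    fraction of all ``n_boot`` bootstraps for the modal lineage prefix at
    that rank, which makes confidences non-increasing with depth.
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    if len(query) < params.k:
        raise ValueError(f"query shorter than k={params.k}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    kmers = np.unique(_encode_kmers(query.upper(), params.k))
    index = db.kmer_index(params.k)
    n_refs = len(db)
    m = np.zeros((max(len(kmers), 1), n_refs), dtype=np.int32)
    for row, km in enumerate(kmers.tolist()):
        hit = index.get(km)
        if hit is not None:
            m[row, hit] = 1
    draws = rng.integers(0, max(len(kmers), 1), size=(params.n_boot, params.n_kmers))
    counts = m[draws].sum(axis=1)  # (n_boot, n_refs)
    noise = rng.random(counts.shape)
    top = np.argmax(counts + 0.5 * noise, axis=1)
    voted = counts[np.arange(params.n_boot), top] > 0

    prefix_votes: list[dict[tuple, int]] = [dict() for _ in RANKS]
    hit_votes: dict[str, int] = {}
    for b in np.nonzero(voted)[0]:
        rec = db.records[int(top[b])]
        hit_votes[rec.accession] = hit_votes.get(rec.accession, 0) + 1
        key: tuple = ()
        for j, rank in enumerate(RANKS):
            key = key + (rec.lineage.get(rank),)
            prefix_votes[j][key] = prefix_votes[j].get(key, 0) + 1

    ranks: dict[str, tuple[str | None, float]] = {}
    for j, rank in enumerate(RANKS):
        if prefix_votes[j]:
            best_key = max(prefix_votes[j], key=lambda kk: (prefix_votes[j][kk], kk))
            conf = prefix_votes[j][best_key] / params.n_boot
            ranks[rank] = (best_key[-1], conf)
        else:
            ranks[rank] = (None, 0.0)
    top_hit = max(hit_votes, key=lambda a: (hit_votes[a], a)) if hit_votes else None
    return Classification(ranks, top_hit)


def classify_zotus(
    zotus: Sequence[ZOtu],
    db: ReferenceDB,
    params: ClassifyParams,
    rng: np.random.Generator | None = None,
) -> dict[str, Classification]:
    """Classify every zOTU; one shared RNG stream keeps runs reproducible."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return {
        (z.label or z.seq): sintax_classify(z.seq, db, params, rng) for z in zotus
    }


def apply_confidence_filter(
    zotu: ZOtu, cls: Classification, params: ClassifyParams
) -> bool:
    """Classifiability filter: keep a zOTU iff its species-rank confidence
    clears the singleton (size 1) or multiton (size >= 2) cutoff."""
    cutoff = params.singleton_cutoff if zotu.size == 1 else params.multiton_cutoff
    return cls.species is not None and cls.species_confidence >= cutoff


def aggregate_sh(
    zotus: Sequence[ZOtu],
    classifications: Mapping[str, Classification],
) -> UnitTable:
    """Sum per-sample counts of conspecific zOTUs into an SH table.

    Every retained zOTU must carry a species-rank SH prediction; totals
    equal the retained-zOTU totals.
    """
    counts: dict[str, dict[str, int]] = {}
    for z in zotus:
        cls = classifications[z.label or z.seq]
        sh = cls.species
        if sh is None:
            raise ValueError(f"retained zOTU {z.label!r} has no species-rank SH")
        row = counts.setdefault(sh, {})
        for sample, n in z.per_sample.items():
            row[sample] = row.get(sample, 0) + n
    return UnitTable.from_counts(counts, "SH")


def classification_rate(
    zotus: Sequence[ZOtu],
    db: ReferenceDB,
    params: ClassifyParams,
    rng: np.random.Generator | None = None,
    classifications: Mapping[str, Classification] | None = None,
) -> float:
    """Fraction of reads whose zOTU passes the classifiability filter."""
    if not zotus:
        raise ValueError("classification_rate: empty input")
    if classifications is None:
        classifications = classify_zotus(zotus, db, params, rng)
    total = sum(z.size for z in zotus)
    kept = sum(
        z.size
        for z in zotus
        if apply_confidence_filter(z, classifications[z.label or z.seq], params)
    )
    return kept / total


def write_classification_tsv(
    classifications: Mapping[str, Classification],
    decisions: Mapping[str, bool] | None,
    path: str | Path,
) -> None:
    """Classification table: unit, per-rank name:confidence, keep/drop decision."""
    with open(path, "w") as fh:
        header = ["unit"] + [f"{r}" for r in RANKS] + ["decision"]
        fh.write("\t".join(header) + "\n")
        for unit, cls in classifications.items():
            cells = [unit]
            for r in RANKS:
                name, conf = cls.ranks.get(r, (None, 0.0))
                cells.append(f"{name or '-'}:{conf:.2f}")
            if decisions is None:
                cells.append("-")
            else:
                cells.append("keep" if decisions.get(unit, False) else "drop")
            fh.write("\t".join(cells) + "\n")
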