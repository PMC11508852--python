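"""Minimum-quality evaluation: taxonomic-unit recovery versus read quality.

Reads are binned by integer mean Phred score, each bin is subsampled to
a common depth (so recovery differences reflect quality, not sequencing
effort), and the chosen unit-building approach is run end to end on each
subsample, replicated with distinct seeds:

* ``zOTU`` - dereplication only;
* ``OTU``  - dereplication followed by greedy clustering at the identity
  threshold;
* ``SH``   - dereplication, classification, the dual-threshold
  classifiability filter, and aggregation of conspecific zOTUs into SHs.

Unit counts are recorded per bin x replicate, with and without singleton
units.  The minimum acceptable quality is read off the curve as the
first bin from which consecutive means stop changing by more than a
relative epsilon over a window (see :func:`detect_stabilization`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import classify as _classify
from .classify import ClassifyParams, ReferenceDB
from .cluster import ClusterParams, UnitTable
from .preprocess import QualityRead, stratify_by_phred, subsample

_SEED_MOD = 2**31 - 1


@dataclass
class EvalParams:
    """Evaluation design: Q range, common depth, replication, approach."""

    depth: int
    q_range: tuple[int, int] = (14, 28)
    n_rep: int = 100
    approach: str = "OTU"  # OTU | SH | zOTU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.n_rep < 1:
            raise ValueError("depth and n_rep must be >= 1")
        if self.approach not in ("OTU", "SH", "zOTU"):
            raise ValueError(f"unknown approach {self.approach!r}")

    def replicate_seed(self, q_bin: int, rep: int) -> int:
        """Deterministic per-(bin, replicate) seed derived from the master seed."""
        return (self.seed * 1_000_003 + q_bin * 1009 + rep) % _SEED_MOD


@dataclass
class RecoveryCurve:
    """Per (Q bin, replicate) unit counts, with and without singletons."""

    df: pd.DataFrame  # columns: approach, q_bin, replicate, seed,
    #                   n_units_all, n_units_no_singletons

    def __post_init__(self) -> None:
        bad = self.df["n_units_no_singletons"] > self.df["n_units_all"]
        if bad.any():
            raise ValueError("singleton-excluded counts exceed full counts")

    def means(self, exclude_singletons: bool = False) -> pd.Series:
        col = "n_units_no_singletons" if exclude_singletons else "n_units_all"
        return self.df.groupby("q_bin")[col].mean()

    def summary(self) -> pd.DataFrame:
        g = self.df.groupby("q_bin")
        return pd.DataFrame(
            {
                "mean_all": g["n_units_all"].mean(),
                "sd_all": g["n_units_all"].std(ddof=1).fillna(0.0),
                "mean_no_singletons": g["n_units_no_singletons"].mean(),
                "sd_no_singletons": g["n_units_no_singletons"].std(ddof=1).fillna(0.0),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _units_for_replicate(
    reads: Sequence[QualityRead],
    approach: str,
    db: ReferenceDB | None,
    cluster_params: ClusterParams,
    classify_params: ClassifyParams,
    seed: int,
    remove_chimeras: bool,
) -> UnitTable:
    zotus = _cluster.dereplicate(reads)
    if remove_chimeras:
        zotus, _ = _cluster.remove_chimeras(zotus)
    if approach == "zOTU":
        return _cluster.zotu_table(zotus)
    if approach == "OTU":
        return _cluster.greedy_cluster(zotus, cluster_params).table
    if db is None:
        raise ValueError("SH approach requires a reference database")
    rng = np.random.default_rng(seed)
    classifications = _classify.classify_zotus(zotus, db, classify_params, rng)
    kept = [
        z
        for z in zotus
        if _classify.apply_confidence_filter(
            z, classifications[z.label or z.seq], classify_params
        )
    ]
    if not kept:
        return UnitTable(pd.DataFrame(), "SH")
    return _classify.aggregate_sh(kept, classifications)


def recovery_curve(
    reads: Sequence[QualityRead],
    params: EvalParams,
    db: ReferenceDB | None = None,
    cluster_params: ClusterParams | None = None,
    classify_params: ClassifyParams | None = None,
    remove_chimeras: bool = False,
) -> RecoveryCurve:
    """Replicated per-Phred-bin taxonomic-unit recovery at fixed depth.

    Every bin in ``params.q_range`` must hold at least ``params.depth``
    reads (an underfilled bin raises, naming the bin).  For each bin and
    replicate the bin is subsampled with the replicate seed and the
    chosen approach is run end to end; unit counts are recorded with and
    without singleton units.
    """
    cluster_params = cluster_params or ClusterParams()
    classify_params = classify_params or ClassifyParams()
    q_min, q_max = params.q_range
    bins = stratify_by_phred(reads, q_min, q_max)
    for q in range(q_min, q_max + 1):
        if len(bins[q]) < params.depth:
            raise ValueError(
                f"bin Q{q} holds {len(bins[q])} reads, fewer than depth {params.depth}"
            )
    rows = []
    for q in range(q_min, q_max + 1):
        for rep in range(params.n_rep):
            seed = params.replicate_seed(q, rep)
            sub = subsample(bins[q], params.depth, seed)
            table = _units_for_replicate(
                sub,
                params.approach,
                db,
                cluster_params,
                classify_params,
                seed,
                remove_chimeras,
            )
            rows.append(
                {
                    "approach": params.approach,
                    "q_bin": q,
                    "replicate": rep,
                    "seed": seed,
                    "n_units_all": table.n_units(),
                    "n_units_no_singletons": table.n_units(exclude_singletons=True),
                }
            )
    return RecoveryCurve(pd.DataFrame(rows))


def detect_stabilization(
    curve: RecoveryCurve | Mapping[int, float],
    window: int = 3,
    epsilon: float = 0.05,
    exclude_singletons: bool = False,
) -> int | None:
    """First Q from which the recovery curve stops changing materially.

    Returns the smallest Q* such that for every consecutive bin pair
    within [Q*, Q* + window], the relative change
    ``|mean(Q+1) - mean(Q)| / max(mean(Q), 1)`` is at most ``epsilon``;
    ``None`` when no such Q* exists.  The curve must span at least
    ``window + 1`` bins.
    """
    if isinstance(curve, RecoveryCurve):
        means = curve.means(exclude_singletons=exclude_singletons)
        qs = list(means.index)
        vals = means.to_numpy(dtype=float)
    else:
        qs = sorted(curve)
        vals = np.asarray([curve[q] for q in qs], dtype=float)
    if len(qs) < window + 1:
        raise ValueError(f"curve spans {len(qs)} bins; needs >= window + 1 = {window + 1}")
    if qs != list(range(qs[0], qs[0] + len(qs))):
        raise ValueError("curve bins must be consecutive integers")
    rel = np.abs(np.diff(vals)) / np.maximum(vals[:-1], 1.0)
    for start in range(len(qs) - window):
        if np.all(rel[start : start + window] <= epsilon):
            return qs[start]
    return None


def classification_rate_curve(
    reads: Sequence[QualityRead],
    db: ReferenceDB,
    params: EvalParams,
    classify_params: ClassifyParams | None = None,
) -> pd.DataFrame:
    """Replicate-averaged classified-read fraction per Phred bin."""
    classify_params = classify_params or ClassifyParams()
    q_min, q_max = params.q_range
    bins = stratify_by_phred(reads, q_min, q_max)
    for q in range(q_min, q_max + 1):
        if len(bins[q]) < params.depth:
            raise ValueError(
                f"bin Q{q} holds {len(bins[q])} reads, fewer than depth {params.depth}"
            )
    rows = []
    for q in range(q_min, q_max + 1):
        rates = []
        for rep in range(params.n_rep):
            seed = params.replicate_seed(q, rep)
            sub = subsample(bins[q], params.depth, seed)
            zotus = _cluster.dereplicate(sub)
            rng = np.random.default_rng(seed)
            rates.append(
                _classify.classification_rate(zotus, db, classify_params, rng)
            )
        rows.append(
            {
                "q_bin": q,
                "mean_rate": float(np.mean(rates)),
                "sd_rate": float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("q_bin")


def singleton_fraction(table: UnitTable) -> float:
    """Fraction of reads sitting in singleton units (unit total == 1)."""
    if len(table.df) == 0:
        raise ValueError("singleton_fraction: empty table")
    sizes = table.unit_sizes()
    return float(sizes[sizes == 1].sum() / sizes.sum())
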