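"""End-to-end pipeline driver.

Takes a directory of per-sample subfolders (subfolder name = sample
barcode, FASTQ files inside) and a SINTAX-formatted reference FASTA,
and produces a taxonomic-unit table with per-stage read-attrition
accounting:

* ``sh`` approach: trim/orient -> quality filter -> dereplicate (100%
  identity) -> chimera removal -> classify -> classifiability filter ->
  aggregate conspecific zOTUs into SHs.
* ``otu`` approach: trim/orient -> quality filter -> dereplicate ->
  chimera removal -> greedy 98% clustering -> classify centroids ->
  LULU curation.

Every read entering the pipeline is accounted for: final table counts
plus logged attrition equal the per-sample input counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import cluster as _cluster
from . import preprocess as _pre
from .classify import ClassifyParams, ReferenceDB
from .cluster import ClusterParams, UnitTable


@dataclass
class PipelineConfig:
    """Pipeline configuration; mirrors the CLI flags.

    ``min_mean_q`` of 0 disables the quality filter; ``identity_t`` of 1
    makes clustering equivalent to dereplication.
    """

    input_dir: str
    reference: str | None = None
    output_dir: str = "nanoits_out"
    approach: str = "otu"  # otu | sh
    identity_t: float = 0.98
    min_mean_q: float = 0.0
    sintax_cutoff: float = 0.8       # multiton species-confidence cutoff
    singleton_cutoff: float = 0.95   # singleton species-confidence cutoff
    lulu: bool = True
    lulu_min_match: float = 84.0
    lulu_min_ratio: float = 1.0
    lulu_min_cooccurrence: float = 0.95
    forward_primer: str = _pre.ITS1F
    reverse_primer: str = _pre.ITS4
    max_primer_mismatch: int = 3
    seed: int = 0
    threads: int = 1  # accepted for interface compatibility; single-threaded

    def __post_init__(self) -> None:
        if self.approach not in ("otu", "sh"):
            raise ValueError(f"approach must be 'otu' or 'sh', got {self.approach!r}")
        if not 0.5 < self.identity_t <= 1.0:
            raise ValueError("identity_t must be in (0.5, 1.0]")
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")
        if self.approach == "sh" and self.reference is None:
            raise ValueError("the sh approach requires a reference database")

    # -- config file round trip --------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    table: UnitTable
    attrition: pd.DataFrame            # sample x stage read losses + input/final
    classifications: dict
    merge_log: list
    zotu_seqs: dict[str, str]
    centroid_seqs: dict[str, str]


def _load_samples(input_dir: str | Path) -> dict[str, list[_pre.QualityRead]]:
    root = Path(input_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory {root} does not exist")
    samples: dict[str, list[_pre.QualityRead]] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        reads: list[_pre.QualityRead] = []
        for fq in sorted(sub.glob("*.fastq")) + sorted(sub.glob("*.fq")):
            reads.extend(_pre.read_fastq(fq, sample=sub.name))
        if reads:
            samples[sub.name] = reads
        else:
            import warnings

            warnings.warn(f"sample folder {sub.name!r} holds no reads; skipped")
    if not samples:
        raise ValueError(f"no FASTQ reads found under {root}")
    return samples


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Run the configured approach end to end; optionally write the
    output bundle (tables, FASTA, logs) under ``config.output_dir``."""
    samples = _load_samples(config.input_dir)
    primers = _pre.PrimerPair(
        config.forward_primer, config.reverse_primer, config.max_primer_mismatch
    )
    attrition: dict[str, dict[str, int]] = {
        s: {"input": len(reads)} for s, reads in samples.items()
    }
    stage_log: list[tuple[str, str, str, str]] = []

    # trim / orient, then quality filter
    retained: list[_pre.QualityRead] = []
    for sample, reads in samples.items():
        att = attrition[sample]
        att["primer_rejected"] = 0
        att["quality_filtered"] = 0
        for r in reads:
            out = _pre.trim_and_orient(r, primers)
            if isinstance(out, _pre.TrimRejection):
                att["primer_rejected"] += 1
                stage_log.append((r.id, "trim_orient", "reject", out.reason))
                continue
            if config.min_mean_q > 0 and out.mean_q < config.min_mean_q:
                att["quality_filtered"] += 1
                stage_log.append((r.id, "quality_filter", "reject", "below_min_mean_q"))
                continue
            retained.append(out)

    zotus = _cluster.dereplicate(retained)
    zotu_seqs = {z.label: z.seq for z in zotus}
    kept, flagged = _cluster.remove_chimeras(zotus)
    for sample in attrition:
        attrition[sample]["chimera_removed"] = 0
    for z in flagged:
        stage_log.append((z.label, "chimera", "reject", "two_parent_model"))
        for sample, n in z.per_sample.items():
            attrition[sample]["chimera_removed"] += n

    db = _classify.load_sintax_db(config.reference) if config.reference else None
    cls_params = ClassifyParams(
        singleton_cutoff=config.singleton_cutoff,
        multiton_cutoff=config.sintax_cutoff,
        seed=config.seed,
    )
    rng = np.random.default_rng(cls_params.seed)
    classifications: dict = {}
    merge_log: list = []
    centroid_seqs: dict[str, str] = {}
    for sample in attrition:
        attrition[sample]["unclassified"] = 0

    if config.approach == "sh":
        assert db is not None
        classifications = _classify.classify_zotus(kept, db, cls_params, rng)
        retained_z = []
        for z in kept:
            if _classify.apply_confidence_filter(z, classifications[z.label], cls_params):
                retained_z.append(z)
            else:
                stage_log.append((z.label, "classify", "reject", "below_confidence"))
                for sample, n in z.per_sample.items():
                    attrition[sample]["unclassified"] += n
        if retained_z:
            table = _classify.aggregate_sh(retained_z, classifications)
        else:
            table = UnitTable(pd.DataFrame(), "SH")
    else:
        if config.identity_t == 1.0:
            result = _cluster.greedy_cluster(kept, ClusterParams(1.0))
        else:
            result = _cluster.greedy_cluster(kept, ClusterParams(config.identity_t))
        table = result.table
        centroid_seqs = result.centroids
        if db is not None:
            centroid_zotus = [
                _cluster.ZOtu(
                    seq=centroid_seqs[label],
                    size=int(table.df.loc[label].sum()),
                    per_sample=table.df.loc[label][table.df.loc[label] > 0].to_dict(),
                    label=label,
                )
                for label in table.units
            ]
            classifications = _classify.classify_zotus(centroid_zotus, db, cls_params, rng)
        if config.lulu and len(centroid_seqs) >= 2:
            matches = _cluster.build_match_list(centroid_seqs, config.lulu_min_match)
            table, merge_log = _cluster.lulu_curate(
                table,
                matches,
                min_ratio=config.lulu_min_ratio,
                min_cooccurrence=config.lulu_min_cooccurrence,
            )
            for daughter, parent in merge_log:
                stage_log.append((daughter, "lulu", "merge", f"into:{parent}"))

    # attrition accounting: final per-sample counts
    att_df = pd.DataFrame(attrition).T
    final = pd.Series(0, index=att_df.index, dtype=np.int64)
    if len(table.df):
        for s in table.samples:
            final[s] = int(table.df[s].sum())
    att_df["final"] = final
    att_df["accounted"] = (
        att_df[["primer_rejected", "quality_filtered", "chimera_removed", "unclassified"]]
        .sum(axis=1)
        + att_df["final"]
    )

    result = PipelineResult(
        table, att_df, classifications, merge_log, zotu_seqs, centroid_seqs
    )
    if write_outputs:
        _write_bundle(config, result, stage_log)
    return result


def _write_bundle(
    config: PipelineConfig, result: PipelineResult, stage_log
) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_tsv(out / "unit_table.tsv")
    _cluster.write_fasta(result.zotu_seqs, out / "zotus.fasta")
    if result.centroid_seqs:
        _cluster.write_fasta(result.centroid_seqs, out / "centroids.fasta")
        if len(result.centroid_seqs) >= 2:
            _cluster.build_match_list(
                result.centroid_seqs, config.lulu_min_match
            ).to_tsv(out / "match_list.tsv")
    if result.classifications:
        _classify.write_classification_tsv(
            result.classifications, None, out / "classifications.tsv"
        )
    result.attrition.to_csv(out / "attrition.tsv", sep="\t", index_label="sample")
    _pre.write_stage_log(stage_log, out / "stage_log.tsv")
    config.to_yaml(out / "config_used.yaml")
    with open(out / "log.txt", "w") as fh:
        fh.write(
            f"approach={config.approach} identity_t={config.identity_t} "
            f"min_mean_q={config.min_mean_q} seed={config.seed}\n"
            f"units={result.table.n_units()} total_reads={result.table.total()}\n"
        )
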