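"""End-to-end probe design: curate, align, consensus, enumerate,
partition, screen, merge.

``run_design`` is the in-memory entry point; ``design_pipeline`` wraps it
with file I/O driven by a :class:`~probegrid.config.RunConfig`, writing
every intermediate (curation report, group alignments, consensus
sequences, probe candidates, job subfiles, job manifest) alongside the
final result tables.
"""

from __future__ import annotations

import functools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import alignment as _aln
from .config import RunConfig
from .consensus_design import (
    ConsensusSequence,
    DegenerateProbe,
    build_consensus,
    enumerate_probes,
)
from .curation import CurationCriteria, CurationReport, build_database
from .partition_exec import JobPartition, run_jobs_local, worst_fit_partition
from .seq_core import (
    DesignParameters,
    Kingdom,
    SequenceRecord,
    TaxonGroup,
    read_fasta,
    write_fasta,
)
from .specificity import DatabaseIndex, ProbeReport, evaluate_probe, seed_length

logger = logging.getLogger(__name__)

__all__ = [
    "DesignResult",
    "run_design",
    "design_pipeline",
    "screen_job",
    "reports_to_tables",
    "write_probes_tsv",
    "read_probes_tsv",
]


@dataclass
class DesignResult:
    groups: list[TaxonGroup]
    report: CurationReport
    consensus: dict[str, ConsensusSequence]
    probes: list[DegenerateProbe]
    partition: JobPartition
    probe_reports: list[ProbeReport]
    results: pd.DataFrame
    hits: pd.DataFrame


def screen_job(
    job_id: int,
    probes: list[DegenerateProbe],
    attempt: int,
    *,
    groups: Mapping[str, TaxonGroup],
    database: Sequence[TaxonGroup],
    params: DesignParameters,
) -> list[ProbeReport]:
    """Screening worker: evaluate each probe of one job (pure function)."""
    idx = DatabaseIndex(
        database, seed_length(params.probe_length, params.specificity_threshold)
    )
    return [evaluate_probe(p, groups[p.taxon], idx, params) for p in probes]


def reports_to_tables(
    reports: Sequence[ProbeReport],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten probe reports into the final result and hit tables."""
    rows = []
    hit_rows = []
    for rep in reports:
        p = rep.probe
        for exp in sorted(rep.known | rep.explorative):
            label = "known" if exp in rep.known else "explorative"
            exp_hits = rep.hits.get(exp, [])
            rows.append(
                (p.taxon, p.start, p.sequence, p.degeneracy, exp, label,
                 rep.status, rep.cross_hyb_count, len(exp_hits))
            )
            for h in exp_hits:
                hit_rows.append(
                    (p.taxon, p.start, exp, h.subject_id, h.subject_taxon,
                     h.strand, h.subject_start, round(h.similarity, 6),
                     ",".join(str(m) for m in h.mismatch_positions))
                )
    results = pd.DataFrame(
        rows,
        columns=["taxon", "start", "sequence", "degeneracy", "expansion",
                 "label", "status", "cross_hyb_count", "expansion_hits"],
    )
    hits = pd.DataFrame(
        hit_rows,
        columns=["taxon", "start", "expansion", "subject_id", "subject_taxon",
                 "strand", "subject_start", "similarity",
                 "mismatch_positions"],
    )
    return results, hits


def run_design(
    records: Sequence[SequenceRecord],
    reference: SequenceRecord | Mapping[Kingdom, SequenceRecord],
    params: DesignParameters,
    criteria: CurationCriteria | None = None,
    large_group_threshold: int = 100,
    homogeneity_margin: float = 0.10,
    max_retries: int = 2,
    max_workers: int = 1,
    seed: int = 0,
) -> DesignResult:
    """Run the whole design in memory and return every stage's output.

    The merged result tables are canonically ordered and therefore
    identical for any job count.
    """
    criteria = criteria or CurationCriteria()
    groups, report = build_database(
        records, criteria, reference,
        homogeneity_margin=homogeneity_margin,
        large_group_threshold=large_group_threshold,
        random_state=seed,
    )
    logger.info("curation: %d groups, dispositions %s",
                len(groups), dict(report.totals()))

    consensus: dict[str, ConsensusSequence] = {}
    probes: list[DegenerateProbe] = []
    for grp in groups:
        aln = _aln.align_group(grp, large_group_threshold)
        cons, _ = build_consensus(aln, taxon=grp.taxon)
        consensus[grp.taxon] = cons
        group_probes = enumerate_probes(cons, params)
        probes.extend(group_probes)
        logger.info("group %s: consensus %d columns, %d candidate probes",
                    grp.taxon, cons.source_alignment_columns, len(group_probes))

    partition = worst_fit_partition(probes, params.job_count)
    groups_by_taxon = {g.taxon: g for g in groups}
    worker = functools.partial(
        screen_job, groups=groups_by_taxon, database=groups, params=params
    )
    reports, job_records = run_jobs_local(
        partition, worker, max_retries=max_retries, max_workers=max_workers
    )
    results, hits = reports_to_tables(reports)
    logger.info("screened %d probes in %d jobs: %d accepted",
                len(reports), len(partition.jobs),
                int((results.drop_duplicates(["taxon", "start"])["status"]
                     == "accepted").sum()))
    return DesignResult(
        groups=groups, report=report, consensus=consensus, probes=probes,
        partition=partition, probe_reports=reports, results=results,
        hits=hits,
    )


# ---------------------------------------------------------------------------
# tabular I/O

_PROBE_COLUMNS = ["taxon", "start", "length", "sequence", "degeneracy", "weight"]


def write_probes_tsv(probes: Sequence[DegenerateProbe], path: str | Path) -> None:
    pd.DataFrame(
        [(p.taxon, p.start, p.length, p.sequence, p.degeneracy, p.weight)
         for p in probes],
        columns=_PROBE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_probes_tsv(path: str | Path) -> list[DegenerateProbe]:
    df = pd.read_csv(path, sep="\t")
    return [
        DegenerateProbe(
            taxon=str(r.taxon), start=int(r.start), length=int(r.length),
            sequence=str(r.sequence), degeneracy=int(r.degeneracy),
            weight=float(r.weight),
        )
        for r in df.itertuples()
    ]


def write_report_tsv(report: CurationReport, path: str | Path) -> None:
    rows = [
        (rid, disp.value, report.reoriented.get(rid, False))
        for rid, disp in sorted(report.dispositions.items())
    ]
    pd.DataFrame(rows, columns=["id", "disposition", "reoriented"]).to_csv(
        path, sep="\t", index=False
    )


def design_pipeline(cfg: RunConfig) -> DesignResult:
    """File-driven end-to-end run; every intermediate lands in out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_fasta(cfg.fasta, taxonomy=cfg.taxonomy,
                         require_taxonomy=cfg.require_taxon)
    reference = read_fasta(cfg.reference)[0]
    result = run_design(
        records, reference, cfg.design_parameters(), cfg.curation_criteria(),
        large_group_threshold=cfg.large_group_threshold,
        homogeneity_margin=cfg.homogeneity_margin,
        max_retries=cfg.max_retries, max_workers=cfg.max_workers,
        seed=cfg.seed,
    )
    write_report_tsv(result.report, out / "curation_report.tsv")
    groups_dir = out / "groups"
    groups_dir.mkdir(exist_ok=True)
    for grp in result.groups:
        write_fasta(grp.members, groups_dir / f"{grp.taxon}.fasta")
    with open(out / "consensus.fasta", "w") as fh:
        for taxon, cons in result.consensus.items():
            fh.write(f">{taxon}\n{cons.text}\n")
    write_probes_tsv(result.probes, out / "probes.tsv")
    jobs_dir = out / "jobs"
    jobs_dir.mkdir(exist_ok=True)
    for j, job in enumerate(result.partition.jobs):
        write_probes_tsv(job, jobs_dir / f"job{j:03d}.tsv")
    with open(jobs_dir / "manifest.json", "w") as fh:
        json.dump(
            {"loads": result.partition.loads,
             "mean_load": result.partition.mean_load},
            fh, indent=1,
        )
    result.results.to_csv(out / "results.tsv", sep="\t", index=False)
    result.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    return result
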