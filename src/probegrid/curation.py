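"""Curated SSU rRNA group-database construction.

The pipeline keeps only full-length, high-quality, taxon-assigned sequences
(length and ambiguous-base filters), groups them at a taxonomic rank, fixes
sequences deposited in the wrong orientation, removes redundant sequences
(identical or exactly contained in a longer member, the 100%-identity
single-linkage convention with coverage required on one sequence of a pair),
and finally removes misannotated outliers so that each group is homogeneous
enough to admit group-specific probes.

Outlier removal embeds each member as its row of the pairwise distance
matrix (distance = 1 - fraction of identical gap-free aligned columns),
splits the group with 2-means (deterministic farthest-pair initialization),
and keeps the larger cluster — unless the two cluster centroids are closer
than a homogeneity margin, in which case the group is left intact.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from . import alignment as _aln
from .seq_core import (
    GAP,
    Kingdom,
    SequenceRecord,
    TaxonGroup,
    reverse_complement,
    with_sequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CurationCriteria",
    "Disposition",
    "CurationReport",
    "filter_sequence",
    "orient_sequence",
    "dereplicate_group",
    "homogeneity_filter",
    "build_database",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class CurationCriteria:
    """Quality/size filters for SSU rRNA sequences.

    Defaults target full-length 16S/18S genes: strictly longer than 1,200
    bases, strictly shorter than 1,600 (prokaryote) or 1,800 (fungi) bases,
    less than 1% ambiguous bases with no run longer than 5, and an assigned
    taxon.
    """

    min_length: int = 1200
    max_length_prokaryote: int = 1600
    max_length_fungi: int = 1800
    max_unknown_fraction: float = 0.01
    max_unknown_run: int = 5
    require_taxon: bool = True

    def __post_init__(self) -> None:
        if not (self.min_length < self.max_length_prokaryote
                and self.min_length < self.max_length_fungi):
            raise ValueError("min_length must be below each kingdom maximum")

    def max_length(self, kingdom: Kingdom) -> int:
        if kingdom == Kingdom.PROKARYOTE:
            return self.max_length_prokaryote
        if kingdom == Kingdom.FUNGI:
            return self.max_length_fungi
        raise ValueError(f"unknown kingdom {kingdom!r}")


class Disposition(str, Enum):
    KEPT = "kept"
    REJECTED_LENGTH = "rejected_length"
    REJECTED_TAXON = "rejected_taxon"
    REJECTED_UNKNOWN_FRACTION = "rejected_unknown_fraction"
    REJECTED_UNKNOWN_RUN = "rejected_unknown_run"
    REMOVED_DUPLICATE = "removed_duplicate"
    REMOVED_INHOMOGENEOUS = "removed_inhomogeneous"


@dataclass
class CurationReport:
    """Per-sequence dispositions, reorientation flags, and per-group counts."""

    dispositions: dict[str, Disposition] = field(default_factory=dict)
    reoriented: dict[str, bool] = field(default_factory=dict)
    group_counts: dict[str, Counter] = field(default_factory=dict)

    def record(self, taxon: str, rec_id: str, disp: Disposition) -> None:
        self.dispositions[rec_id] = disp
        self.group_counts.setdefault(taxon, Counter())[disp.value] += 1

    def totals(self) -> Counter:
        total: Counter = Counter()
        for c in self.group_counts.values():
            total += c
        return total


def _unknown_runs(seq: str) -> tuple[int, int]:
    """(count, longest run) of characters outside {A, C, G, T}."""
    count = longest = run = 0
    for ch in seq:
        if ch not in _ACGT:
            count += 1
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    return count, longest


def filter_sequence(rec: SequenceRecord, crit: CurationCriteria) -> Disposition:
    """Quality filter; the first failing rule (length, taxon, ambiguous-base
    fraction, ambiguous-base run — in that order) is reported."""
    n = len(rec.sequence)
    if not (n > crit.min_length and n < crit.max_length(rec.kingdom)):
        return Disposition.REJECTED_LENGTH
    if crit.require_taxon and not rec.taxon:
        return Disposition.REJECTED_TAXON
    unknown, run = _unknown_runs(rec.sequence)
    if not unknown / n < crit.max_unknown_fraction:
        return Disposition.REJECTED_UNKNOWN_FRACTION
    if run > crit.max_unknown_run:
        return Disposition.REJECTED_UNKNOWN_RUN
    return Disposition.KEPT


def orient_sequence(
    rec: SequenceRecord,
    reference: SequenceRecord,
    scoring: _aln.ScoringScheme = _aln.DEFAULT_SCORING,
) -> SequenceRecord:
    """Flip a sequence to its reverse complement when that orients it better.

    The record is returned unchanged if its best local-alignment score
    against the trusted reference is at least that of its reverse
    complement; otherwise the reverse complement is returned with
    ``reoriented`` set.
    """
    if not reference.sequence:
        raise ValueError("empty orientation reference")
    fwd = _aln.local_score(rec.sequence, reference.sequence, scoring)
    rc = reverse_complement(rec.sequence)
    rev = _aln.local_score(rc, reference.sequence, scoring)
    if fwd >= rev:
        return rec
    return with_sequence(rec, rc, reoriented=True)


def dereplicate_group(group: TaxonGroup) -> tuple[TaxonGroup, list[str]]:
    """Remove members identical to, or exact substrings of, another member.

    Among duplicates the longer sequence survives; ties go to the earlier
    input position.  Returns the dereplicated group (input order preserved)
    and the removed ids.
    """
    if not group.members:
        raise ValueError("cannot dereplicate an empty group")
    order = sorted(
        range(len(group.members)),
        key=lambda i: (-len(group.members[i].sequence), i),
    )
    kept_idx: list[int] = []
    removed: list[str] = []
    for i in order:
        seq = group.members[i].sequence
        if any(seq in group.members[j].sequence for j in kept_idx):
            removed.append(group.members[i].id)
        else:
            kept_idx.append(i)
    kept_idx.sort()
    return TaxonGroup(group.taxon, [group.members[i] for i in kept_idx]), removed


def homogeneity_filter(
    group: TaxonGroup,
    margin: float = 0.10,
    k: int = 2,
    random_state: int = 0,
    large_group_threshold: int = 100,
    scoring: _aln.ScoringScheme = _aln.DEFAULT_SCORING,
) -> tuple[TaxonGroup, list[str]]:
    """Drop misannotated outliers so the group is homogeneous.

    Members are embedded as rows of the pairwise distance matrix computed
    from the group alignment and split with k-means (k = 2 by default,
    deterministic farthest-pair initialization).  The largest cluster is
    retained (size ties: the cluster holding the earliest input member);
    when the RMS separation between the cluster centroids is below
    ``margin`` the group is considered homogeneous and kept whole.

    Returns the filtered group and removed ids.  Groups of fewer than two
    members pass through.
    """
    if len(group.members) < 2:
        return group, []
    aln = _aln.align_group(group, large_group_threshold, scoring=scoring)
    order = {m.id: i for i, m in enumerate(group.members)}
    aln.rows.sort(key=lambda r: order[r[0]])
    D = _aln.distance_matrix(aln)
    n = D.shape[0]
    # farthest pair (lexicographically first on ties) seeds the centroids
    far = max(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda p: (D[p], -p[0], -p[1]),
    )
    init = D[list(far)]
    if np.allclose(init[0], init[1]):
        return group, []  # all mutually equidistant/identical: homogeneous
    km = KMeans(
        n_clusters=k, init=init, n_init=1, max_iter=100,
        random_state=random_state,
    )
    labels = km.fit_predict(D)
    sizes = Counter(labels)
    if len(sizes) < 2:
        return group, []
    # centroid separation in units of sequence distance (RMS over features)
    sep = float(
        np.sqrt(np.mean((km.cluster_centers_[0] - km.cluster_centers_[1]) ** 2))
    )
    if sep < margin:
        return group, []
    best = max(
        sizes,
        key=lambda lbl: (sizes[lbl], -min(i for i in range(n) if labels[i] == lbl)),
    )
    kept = [m for m, lbl in zip(group.members, labels) if lbl == best]
    removed = [m.id for m, lbl in zip(group.members, labels) if lbl != best]
    return TaxonGroup(group.taxon, kept), removed


def build_database(
    records: Sequence[SequenceRecord],
    crit: CurationCriteria,
    reference: SequenceRecord | Mapping[Kingdom, SequenceRecord],
    homogeneity_margin: float = 0.10,
    large_group_threshold: int = 100,
    random_state: int = 0,
) -> tuple[list[TaxonGroup], CurationReport]:
    """Run the full curation pipeline: filter, group by taxon, orient,
    dereplicate, homogeneity-screen.

    ``reference`` is the trusted sequence used for the orientation check,
    either one record or one per kingdom.  Records must already carry their
    taxon labels (see :func:`probegrid.seq_core.read_fasta`).
    """
    if not records:
        raise ValueError("no input records")
    report = CurationReport()
    grouped: dict[tuple[str, Kingdom], list[SequenceRecord]] = {}
    for rec in records:
        disp = filter_sequence(rec, crit)
        if disp != Disposition.KEPT:
            report.record(rec.taxon, rec.id, disp)
            continue
        grouped.setdefault((rec.taxon, rec.kingdom), []).append(rec)

    groups: list[TaxonGroup] = []
    for (taxon, kingdom), members in grouped.items():
        ref = (
            reference[kingdom]
            if isinstance(reference, Mapping)
            else reference
        )
        oriented = [orient_sequence(m, ref) for m in members]
        for m in oriented:
            report.reoriented[m.id] = m.reoriented
        group = TaxonGroup(taxon, oriented)
        group, dup_ids = dereplicate_group(group)
        for rid in dup_ids:
            report.record(taxon, rid, Disposition.REMOVED_DUPLICATE)
        group, out_ids = homogeneity_filter(
            group,
            margin=homogeneity_margin,
            random_state=random_state,
            large_group_threshold=large_group_threshold,
        )
        for rid in out_ids:
            report.record(taxon, rid, Disposition.REMOVED_INHOMOGENEOUS)
        for m in group.members:
            report.record(taxon, m.id, Disposition.KEPT)
        if group.members:
            groups.append(group)
        logger.info(
            "group %s: %d kept, %d duplicate, %d inhomogeneous",
            taxon, len(group.members), len(dup_ids), len(out_ids),
        )
    return groups, report
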