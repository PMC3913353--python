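"""Cross-hybridization screening against the reference group database.

A probe expansion cross-hybridizes with a non-target sequence when some
ungapped window of length l on either strand matches it with similarity
(identity fraction) at or above the specificity threshold S.  Screening is
exhaustive: a seed-and-extend search over a k-mer index finds every such
window.  With k allowed mismatches (k = l - ceil(S*l)) the query is tiled
with floor(l/w) >= k+1 non-overlapping seeds of length
w = min(7, floor(l/(k+1))), so by pigeonhole any qualifying window shares
at least one exact seed with the query and no hit can be missed; every
candidate is then verified by direct mismatch counting, so no spurious hit
is reported either.  A probe is rejected when its expansions accumulate
more than MaxXH non-target cross-hybridizations in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .consensus_design import DegenerateProbe, classify_expansions
from .seq_core import DesignParameters, TaxonGroup, reverse_complement

__all__ = [
    "CrossHybridization",
    "ProbeReport",
    "DatabaseIndex",
    "allowed_mismatches",
    "seed_length",
    "similarity",
    "find_cross_hybridizations",
    "evaluate_probe",
]


@dataclass(frozen=True)
class CrossHybridization:
    """One qualifying probe/subject window match.

    ``subject_start`` is the 1-based window start on the subject's forward
    strand; ``mismatch_positions`` are 1-based offsets on the probe (5'->3'
    of the probe itself, on either strand).
    """

    probe_expansion: str
    subject_id: str
    subject_taxon: str
    strand: Literal["+", "-"]
    subject_start: int
    similarity: float
    mismatch_positions: tuple[int, ...]


@dataclass
class ProbeReport:
    """Screening outcome for one degenerate probe."""

    probe: DegenerateProbe
    known: set[str]
    explorative: set[str]
    hits: dict[str, list[CrossHybridization]]  # per expansion, non-target
    status: Literal["accepted", "rejected_cross_hyb"]

    @property
    def cross_hyb_count(self) -> int:
        return sum(len(h) for h in self.hits.values())


def allowed_mismatches(length: int, threshold: float) -> int:
    """Largest mismatch count whose similarity still reaches the threshold."""
    import math

    return length - math.ceil(threshold * length - 1e-9)


def seed_length(length: int, threshold: float) -> int:
    """Exact-seed length guaranteeing pigeonhole completeness (capped at 7)."""
    k = allowed_mismatches(length, threshold)
    return max(1, min(7, length // (k + 1)))


def similarity(probe: str, window: str) -> float:
    """Identity fraction between two equal-length ungapped strings."""
    if len(probe) != len(window):
        raise ValueError("similarity needs equal-length strings")
    matches = sum(a == b for a, b in zip(probe, window))
    return matches / len(probe)


class DatabaseIndex:
    """k-mer index over the forward strands of a group database.

    Built once per screening run; shared by every probe of the run.
    """

    def __init__(self, database: Sequence[TaxonGroup], word: int):
        self.word = word
        self.entries: list[tuple[str, str, str]] = []  # (id, taxon, sequence)
        for grp in database:
            for m in grp.members:
                self.entries.append((m.id, grp.taxon, m.sequence))
        index: dict[str, list[tuple[int, int]]] = {}
        for si, (_, _, seq) in enumerate(self.entries):
            for p in range(len(seq) - word + 1):
                index.setdefault(seq[p : p + word], []).append((si, p))
        self._index = index

    def candidate_windows(self, query: str, l: int) -> set[tuple[int, int]]:
        """(sequence index, window start) pairs sharing a tiled seed."""
        w = self.word
        cands: set[tuple[int, int]] = set()
        for off in range(0, l - w + 1, w):
            for si, p in self._index.get(query[off : off + w], ()):
                start = p - off
                if 0 <= start <= len(self.entries[si][2]) - l:
                    cands.add((si, start))
        return cands


def _scan_strand(
    query: str,
    idx: DatabaseIndex,
    max_mismatches: int,
    strand: Literal["+", "-"],
    expansion: str,
    target_taxon: str | None,
) -> list[CrossHybridization]:
    l = len(query)
    hits = []
    for si, start in sorted(idx.candidate_windows(query, l)):
        sid, taxon, seq = idx.entries[si]
        if target_taxon is not None and taxon == target_taxon:
            continue
        window = seq[start : start + l]
        mism = [i for i in range(l) if query[i] != window[i]]
        if len(mism) > max_mismatches:
            continue
        if strand == "+":
            probe_pos = tuple(i + 1 for i in mism)
        else:
            # query is the reverse complement of the expansion: map window
            # offsets back onto the probe's own 5'->3' coordinates
            probe_pos = tuple(sorted(l - i for i in mism))
        hits.append(
            CrossHybridization(
                probe_expansion=expansion,
                subject_id=sid,
                subject_taxon=taxon,
                strand=strand,
                subject_start=start + 1,
                similarity=(l - len(mism)) / l,
                mismatch_positions=probe_pos,
            )
        )
    return hits


def find_cross_hybridizations(
    expansion: str,
    database: Sequence[TaxonGroup] | DatabaseIndex,
    target_taxon: str | None,
    params: DesignParameters,
) -> list[CrossHybridization]:
    """Every window of every non-target database sequence, on both strands,
    with similarity >= the specificity threshold.

    Pass ``target_taxon=None`` to include target-group hits (used for
    auditing rather than for the cross-hybridization count).  A prebuilt
    :class:`DatabaseIndex` may be supplied instead of the group list to
    amortize indexing across probes.
    """
    l = params.probe_length
    if len(expansion) != l:
        raise ValueError(
            f"expansion length {len(expansion)} != probe length {l}"
        )
    k = allowed_mismatches(l, params.specificity_threshold)
    if isinstance(database, DatabaseIndex):
        idx = database
    else:
        idx = DatabaseIndex(database, seed_length(l, params.specificity_threshold))
    hits = _scan_strand(expansion, idx, k, "+", expansion, target_taxon)
    hits += _scan_strand(
        reverse_complement(expansion), idx, k, "-", expansion, target_taxon
    )
    hits.sort(key=lambda h: (h.subject_id, h.strand, h.subject_start))
    return hits


def evaluate_probe(
    probe: DegenerateProbe,
    group: TaxonGroup,
    database: Sequence[TaxonGroup] | DatabaseIndex,
    params: DesignParameters,
) -> ProbeReport:
    """Classify a probe's expansions and screen each against the database.

    Non-target cross-hybridizations are summed over all expansions (each
    (expansion, subject, position, strand) match counts once); the probe is
    accepted iff the total is at most MaxXH.
    """
    known, explorative = classify_expansions(probe, group)
    hits: dict[str, list[CrossHybridization]] = {}
    for exp in sorted(known | explorative):
        hits[exp] = find_cross_hybridizations(
            exp, database, probe.taxon, params
        )
    total = sum(len(h) for h in hits.values())
    status = "accepted" if total <= params.max_cross_hyb else "rejected_cross_hyb"
    return ProbeReport(
        probe=probe, known=known, explorative=explorative,
        hits=hits, status=status,
    )
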