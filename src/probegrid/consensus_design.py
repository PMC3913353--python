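"""IUPAC consensus construction and degenerate-probe enumeration.

A group alignment is summarized column by column into one degenerate
consensus sequence.  In a column of m rows, let U be the number of
*unknown* characters (gaps and ambiguous bases).  If U < m/2 (strictly),
the column's consensus is the IUPAC code for the set of specific bases
observed there, and the unknown characters in that column are corrected to
that code — the consensus both represents the group and repairs likely
sequencing errors.  Otherwise the consensus gets a gap and the column is
left untouched.

Candidate probes are all gap-free windows of length l along the consensus
whose degeneracy does not exceed MaxDeg; each carries a weight (equal to
its degeneracy) used later for load balancing, and its expansions are
classified *known* (seen verbatim in a group member) or *explorative*
(predicted variants that may detect sequences absent from the database).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alignment import Alignment
from .seq_core import (
    GAP,
    IUPAC_CODES,
    DesignParameters,
    TaxonGroup,
    code_for_set,
    degeneracy_of,
    expand,
)

__all__ = [
    "ConsensusSequence",
    "DegenerateProbe",
    "build_consensus",
    "enumerate_probes",
    "classify_expansions",
]

_ACGT = "ACGT"


@dataclass
class ConsensusSequence:
    """Gapped IUPAC consensus over a group alignment."""

    taxon: str
    text: str
    source_alignment_columns: int

    def __post_init__(self) -> None:
        if len(self.text) != self.source_alignment_columns:
            raise ValueError("consensus length must equal alignment columns")


@dataclass
class DegenerateProbe:
    """A gap-free consensus window: a candidate degenerate probe.

    ``start`` is 1-based on the consensus, gap columns included, so probe
    coordinates are stable identifiers across reports.
    """

    taxon: str
    start: int
    length: int
    sequence: str
    degeneracy: int
    weight: float

    def __post_init__(self) -> None:
        if GAP in self.sequence:
            raise ValueError("probe sequence must be gap-free")
        if len(self.sequence) != self.length:
            raise ValueError("probe length mismatch")


def build_consensus(
    aln: Alignment,
    taxon: str = "",
    strict_unknown: bool = False,
) -> tuple[ConsensusSequence, Alignment]:
    """Consensus sequence plus the corrected alignment.

    ``strict_unknown`` restricts "unknown" to N and gap (the narrowest
    reading); by default every non-ACGT character counts as unknown, the
    same convention the quality filters use.  In strict mode, ambiguity
    codes other than N count as observed and contribute their base sets.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    M = aln.matrix()
    m, ncols = M.shape
    if strict_unknown:
        unknown = (M == ord("N")) | (M == ord(GAP))
    else:
        acgt = np.zeros(256, dtype=bool)
        for b in _ACGT:
            acgt[ord(b)] = True
        unknown = ~acgt[M]
    U = unknown.sum(axis=0)
    replace_mask = U * 2 < m  # strictly less than half
    corrected = M.copy()
    cons_chars: list[str] = []
    for c in range(ncols):
        if not replace_mask[c]:
            cons_chars.append(GAP)
            continue
        col = M[:, c]
        known = col[~unknown[:, c]]
        bases: set[str] = set()
        for code in np.unique(known):
            bases |= IUPAC_CODES[chr(code)]
        symbol = code_for_set(bases)
        cons_chars.append(symbol)
        corrected[unknown[:, c], c] = ord(symbol)
    rows = [
        (rid, corrected[i].tobytes().decode())
        for i, (rid, _) in enumerate(aln.rows)
    ]
    cons = ConsensusSequence(taxon=taxon, text="".join(cons_chars),
                             source_alignment_columns=ncols)
    return cons, Alignment(rows=rows)


def enumerate_probes(
    cons: ConsensusSequence, params: DesignParameters
) -> list[DegenerateProbe]:
    """All gap-free windows of length l with degeneracy <= MaxDeg,
    in consensus order.  Weight = degeneracy (the load-balancing unit)."""
    l = params.probe_length
    text = cons.text
    if l > len(text):
        raise ValueError(
            f"probe length {l} exceeds consensus length {len(text)}"
        )
    probes: list[DegenerateProbe] = []
    for p in range(len(text) - l + 1):
        window = text[p : p + l]
        if GAP in window:
            continue
        deg = degeneracy_of(window)
        if deg > params.max_degeneracy:
            continue
        probes.append(
            DegenerateProbe(
                taxon=cons.taxon,
                start=p + 1,
                length=l,
                sequence=window,
                degeneracy=deg,
                weight=float(deg),
            )
        )
    return probes


def classify_expansions(
    probe: DegenerateProbe, group: TaxonGroup | Iterable[str]
) -> tuple[set[str], set[str]]:
    """Partition a probe's expansions into (known, explorative).

    An expansion is *known* when it occurs as an exact forward-strand
    substring of at least one group member; the rest are *explorative* —
    combinations of observed variation that no deposited sequence carries,
    capable of detecting undiscovered relatives.
    """
    seqs = [
        m.sequence if hasattr(m, "sequence") else m  # type: ignore[union-attr]
        for m in group
    ]
    expansions = expand(probe.sequence, cap=None)
    known = {e for e in expansions if any(e in s for s in seqs)}
    return known, expansions - known
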