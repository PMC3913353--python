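"""IUPAC nucleotide algebra, sequence records, and FASTA/taxonomy I/O.

The degenerate-probe machinery rests on the 15 IUPAC nucleotide codes, each
naming a nonempty subset of {A, C, G, T}.  A degenerate oligonucleotide is a
string over these codes; its *degeneracy* is the number of distinct plain-ACGT
oligonucleotides (expansions) it represents, i.e. the product of per-position
set sizes.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from math import prod
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "IUPAC_CODES",
    "GAP",
    "Kingdom",
    "SequenceRecord",
    "TaxonGroup",
    "DesignParameters",
    "degeneracy_of",
    "expand",
    "code_for_set",
    "base_set",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
]

#: The 15 IUPAC nucleotide symbols and the base sets they denote.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    "-": "-",
}

GAP = "-"


class Kingdom(str, Enum):
    """Kingdom of an SSU rRNA sequence: 16S (prokaryote) or 18S (fungi)."""

    PROKARYOTE = "prokaryote"
    FUNGI = "fungi"


@dataclass
class SequenceRecord:
    """One nucleotide sequence with its taxonomic labels.

    ``reoriented`` records whether the orientation check flipped the sequence
    to its reverse complement.
    """

    id: str
    sequence: str
    kingdom: Kingdom = Kingdom.PROKARYOTE
    taxon: str = ""
    reoriented: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")
        self.kingdom = Kingdom(self.kingdom)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TaxonGroup:
    """A curated set of sequences for one taxon — the unit of probe design."""

    taxon: str
    members: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        taxa = {m.taxon for m in self.members}
        kingdoms = {m.kingdom for m in self.members}
        if len(taxa) > 1 or len(kingdoms) > 1:
            raise ValueError(
                f"group {self.taxon!r} mixes taxa {taxa} or kingdoms {kingdoms}"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def kingdom(self) -> Kingdom:
        return self.members[0].kingdom


@dataclass(frozen=True)
class DesignParameters:
    """The four main design parameters plus the job count.

    probe_length
        Length l of the window slid along the consensus (default 25).
    max_degeneracy
        Upper bound MaxDeg on the degeneracy of a saved probe (default 2000).
    specificity_threshold
        Minimum probe/non-target similarity S that counts as a
        cross-hybridization (default 0.88, inclusive).
    max_cross_hyb
        Maximum number of tolerated non-target cross-hybridizations MaxXH
        (default 100).
    job_count
        Number N of parallel screening jobs.
    """

    probe_length: int = 25
    max_degeneracy: int = 2000
    specificity_threshold: float = 0.88
    max_cross_hyb: int = 100
    job_count: int = 1

    def __post_init__(self) -> None:
        if self.probe_length < 1:
            raise ValueError("probe_length must be >= 1")
        if self.max_degeneracy < 1:
            raise ValueError("max_degeneracy must be >= 1")
        if not 0 < self.specificity_threshold <= 1:
            raise ValueError("specificity_threshold must be in (0, 1]")
        if self.max_cross_hyb < 0:
            raise ValueError("max_cross_hyb must be >= 0")
        if self.job_count < 1:
            raise ValueError("job_count must be >= 1")


def _check_iupac(seq: str, allow_gap: bool = False) -> None:
    for ch in seq:
        if ch in IUPAC_CODES:
            continue
        if allow_gap and ch == GAP:
            continue
        raise ValueError(f"invalid IUPAC symbol {ch!r} in sequence")


def base_set(code: str) -> frozenset[str]:
    """Base set denoted by a single IUPAC symbol."""
    try:
        return IUPAC_CODES[code]
    except KeyError:
        raise ValueError(f"unknown IUPAC code {code!r}") from None


def degeneracy_of(seq: str) -> int:
    """Number of distinct ACGT expansions: product of per-position set sizes.

    Gap characters are rejected — degeneracy is defined on gap-free windows
    only.
    """
    _check_iupac(seq)
    return prod(len(IUPAC_CODES[ch]) for ch in seq)


def expand(seq: str, cap: int | None = 2000) -> set[str]:
    """All plain-ACGT expansions of a degenerate sequence.

    ``cap`` bounds the expansion size (memory guard, default mirrors the
    2000 default for MaxDeg); pass ``None`` to disable.
    """
    deg = degeneracy_of(seq)
    if cap is not None and deg > cap:
        raise ValueError(f"degeneracy {deg} exceeds expansion cap {cap}")
    pools = [sorted(IUPAC_CODES[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def code_for_set(bases: Iterable[str]) -> str:
    """The unique IUPAC symbol for a nonempty subset of {A, C, G, T}."""
    key = frozenset(bases)
    if not key:
        raise ValueError("empty base set has no IUPAC code")
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"not a subset of ACGT: {sorted(key)}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement honoring ambiguity codes (R<->Y, B<->V, ...)."""
    try:
        return "".join(_COMPLEMENT[ch] for ch in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"cannot complement symbol {exc.args[0]!r}") from None


def normalize_sequence(raw: str) -> str:
    """Uppercase, RNA U -> T, '.' gaps -> '-'; validate the alphabet."""
    s = raw.upper().replace("U", "T").replace(".", GAP)
    _check_iupac(s, allow_gap=True)
    return s


def read_taxonomy(path: str | Path) -> dict[str, tuple[Kingdom, str]]:
    """Read a taxonomy table: TSV with header ``id<TAB>kingdom<TAB>taxon``."""
    table: dict[str, tuple[Kingdom, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "kingdom", "taxon"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"taxonomy table needs columns {sorted(required)}")
        for row in reader:
            if row["id"] in table:
                raise ValueError(f"duplicate taxonomy id {row['id']!r}")
            table[row["id"]] = (Kingdom(row["kingdom"]), row["taxon"])
    return table


def read_fasta(
    path: str | Path,
    taxonomy: Mapping[str, tuple[Kingdom, str]] | str | Path | None = None,
    require_taxonomy: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Sequences are uppercased, U mapped to T, and '.' gaps to '-'.  If a
    taxonomy table (or its path) is given, kingdom/taxon are merged by id;
    with ``require_taxonomy`` an id missing from the table is an error.
    """
    if isinstance(taxonomy, (str, Path)):
        taxonomy = read_taxonomy(taxonomy)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        kingdom, taxon = Kingdom.PROKARYOTE, ""
        if taxonomy is not None:
            if rec.id in taxonomy:
                kingdom, taxon = taxonomy[rec.id]
            elif require_taxonomy:
                raise ValueError(f"id {rec.id!r} absent from taxonomy table")
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=normalize_sequence(str(rec.seq)),
                kingdom=kingdom,
                taxon=taxon,
            )
        )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-FASTA (wrapped lines, ids only in headers)."""
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def with_sequence(rec: SequenceRecord, sequence: str, **kw) -> SequenceRecord:
    """Copy a record with a new sequence (and optional field overrides)."""
    return replace(rec, sequence=sequence, **kw)
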