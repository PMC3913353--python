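"""Synthetic genus-like fixture generation.

Real SSU rRNA group databases are large downloads; the generator emulates
their structure at any scale so that every pipeline stage is testable
offline.  Each group descends from a shared root template: the group
template diverges from the root by a between-group substitution rate, and
members diverge from their group template by a small within-group rate,
mimicking genus-level sequence variation.  On top of the clean members the
generator plants, with known ground truth, the pathologies the curation
stage must handle: exact duplicates, reverse-complemented entries, short
fragments, scattered ambiguous bases, and one strongly divergent outlier
per group (a misannotated sequence).

Each group template also carries a *unique marker*: a probe-length
subsequence kept free of mutations within the group and verified to stay
below the cross-hybridization similarity threshold against every window of
every other group, on both strands — so probes over the marker are
guaranteed cross-hybridization-free.  The manifest records every planted
fact for ground-truth comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .seq_core import (
    Kingdom,
    SequenceRecord,
    reverse_complement,
    write_fasta,
)

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "write_fixture"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a synthetic group database.

    Defaults emulate genus-level 16S data under the default curation
    criteria: full-length (1,400 base) templates, ten groups of ten
    homogeneous members at 2% within-group divergence, 20% between-group
    divergence, sparse ambiguous bases, and one planted duplicate,
    reversed entry, short fragment, and outlier per group.
    """

    n_groups: int = 10
    sequences_per_group: int = 10
    template_length: int = 1400
    substitution_rate: float = 0.02
    between_group_divergence: float = 0.20
    ambiguity_rate: float = 0.001
    n_duplicates: int = 1
    n_reversed: int = 1
    n_short: int = 1
    n_outliers: int = 1
    outlier_divergence: float = 0.30
    short_length: int | None = None
    marker_length: int = 25
    marker_max_similarity: float = 0.88
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "between_group_divergence",
                     "ambiguity_rate", "outlier_divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_duplicates", "n_reversed", "n_short", "n_outliers"):
            if getattr(self, name) > self.sequences_per_group:
                raise ValueError(f"{name} exceeds sequences_per_group")
        if self.marker_length > self.template_length:
            raise ValueError("marker longer than template")


@dataclass
class Fixture:
    """Generated records plus the ground truth the curation stage must find."""

    spec: FixtureSpec
    records: list[SequenceRecord]
    taxonomy: dict[str, tuple[Kingdom, str]]
    reference: SequenceRecord
    manifest: dict


def _mutate(rng: np.random.Generator, template: np.ndarray, rate: float,
            protect: slice | None = None) -> np.ndarray:
    """Substitute bases at ``rate`` (always to a different base)."""
    seq = template.copy()
    hit = rng.random(seq.size) < rate
    if protect is not None:
        hit[protect] = False
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != seq[i]]
        seq[i] = rng.choice(choices)
    return seq


def _inject_ambiguity(rng: np.random.Generator, seq: np.ndarray, rate: float,
                      protect: slice | None = None) -> np.ndarray:
    # scattered single N's, count capped well below the 1% quality bound
    cap = max(0, seq.size // 200)
    n = min(int(rng.binomial(seq.size, rate)), cap)
    if n == 0:
        return seq
    out = seq.copy()
    positions = rng.choice(seq.size, size=n, replace=False)
    for p in positions:
        if protect is not None and protect.start <= p < protect.stop:
            continue
        out[p] = ord("N")
    return out


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


def _window_similarity_below(marker: str, others: list[str], cap: float) -> bool:
    """True iff every window of every other sequence (both strands) stays
    strictly below ``cap`` similarity to the marker."""
    l = len(marker)
    mv = np.frombuffer(marker.encode(), dtype=np.uint8)
    for seq in others:
        for s in (seq, reverse_complement(seq)):
            sv = np.frombuffer(s.encode(), dtype=np.uint8)
            if sv.size < l:
                continue
            win = np.lib.stride_tricks.sliding_window_view(sv, l)
            best = int((win == mv).sum(axis=1).max())
            if best / l >= cap:
                return False
    return True


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministically generate a fixture from its spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    L = spec.template_length
    root = rng.choice(_BASES, size=L)
    short_len = spec.short_length or L // 2
    marker_start = L // 3
    marker_slice = slice(marker_start, marker_start + spec.marker_length)

    group_templates: dict[str, np.ndarray] = {}
    for g in range(spec.n_groups):
        taxon = f"genus{g:02d}"
        group_templates[taxon] = _mutate(
            rng, root, spec.between_group_divergence
        )

    records: list[SequenceRecord] = []
    taxonomy: dict[str, tuple[Kingdom, str]] = {}
    dispositions: dict[str, str] = {}
    reoriented: dict[str, bool] = {}
    markers: dict[str, dict] = {}
    per_group: dict[str, dict] = {}

    for taxon, template in group_templates.items():
        group_records: list[SequenceRecord] = []
        seen: set[str] = set()

        def variant(rate: float) -> np.ndarray:
            # members are kept distinct so that only the planted duplicates
            # are duplicates; with all mutation switched off identical
            # members are unavoidable and allowed (no ground-truth guarantee)
            for _ in range(100):
                seq = _inject_ambiguity(
                    rng,
                    _mutate(rng, template, rate, protect=marker_slice),
                    spec.ambiguity_rate,
                    protect=marker_slice,
                )
                if _to_str(seq) not in seen or (
                    rate == 0 and spec.ambiguity_rate == 0
                ):
                    return seq
            raise RuntimeError("could not generate a distinct variant")

        def add(rec: SequenceRecord, disp: str, flipped: bool = False) -> None:
            group_records.append(rec)
            seen.add(rec.sequence)
            taxonomy[rec.id] = (Kingdom.PROKARYOTE, taxon)
            dispositions[rec.id] = disp
            if disp in ("kept", "removed_duplicate", "removed_inhomogeneous"):
                reoriented[rec.id] = flipped

        good: list[SequenceRecord] = []
        for k in range(spec.sequences_per_group):
            rec = SequenceRecord(
                id=f"{taxon}_s{k:02d}", sequence=_to_str(variant(spec.substitution_rate)),
                kingdom=Kingdom.PROKARYOTE, taxon=taxon,
            )
            good.append(rec)
            add(rec, "kept")
        for k in range(spec.n_reversed):
            seq = _to_str(variant(spec.substitution_rate))
            rec = SequenceRecord(
                id=f"{taxon}_rev{k:02d}", sequence=reverse_complement(seq),
                kingdom=Kingdom.PROKARYOTE, taxon=taxon,
            )
            group_records.append(rec)
            taxonomy[rec.id] = (Kingdom.PROKARYOTE, taxon)
            dispositions[rec.id] = "kept"
            reoriented[rec.id] = True
            seen.add(seq)
        for k in range(spec.n_duplicates):
            src = good[k % len(good)]
            rec = SequenceRecord(
                id=f"{taxon}_dup{k:02d}", sequence=src.sequence,
                kingdom=Kingdom.PROKARYOTE, taxon=taxon,
            )
            group_records.append(rec)
            taxonomy[rec.id] = (Kingdom.PROKARYOTE, taxon)
            dispositions[rec.id] = "removed_duplicate"
            reoriented[rec.id] = False
        for k in range(spec.n_short):
            rec = SequenceRecord(
                id=f"{taxon}_short{k:02d}",
                sequence=_to_str(template[:short_len]),
                kingdom=Kingdom.PROKARYOTE, taxon=taxon,
            )
            group_records.append(rec)
            taxonomy[rec.id] = (Kingdom.PROKARYOTE, taxon)
            dispositions[rec.id] = "rejected_length"
        for k in range(spec.n_outliers):
            rec = SequenceRecord(
                id=f"{taxon}_outlier{k:02d}",
                sequence=_to_str(variant(spec.outlier_divergence)),
                kingdom=Kingdom.PROKARYOTE, taxon=taxon,
            )
            group_records.append(rec)
            taxonomy[rec.id] = (Kingdom.PROKARYOTE, taxon)
            dispositions[rec.id] = "removed_inhomogeneous"
            reoriented[rec.id] = False

        records.extend(group_records)
        markers[taxon] = {
            "template_position": marker_start + 1,
            "sequence": _to_str(template[marker_slice]),
        }
        per_group[taxon] = {
            "kept": [r.id for r in group_records
                     if dispositions[r.id] == "kept"],
            "input": len(group_records),
        }

    # verify each group's marker is cross-hybridization-free against the
    # other groups; re-randomize a marker (and the member copies of it)
    # until the guarantee holds
    taxa = list(group_templates)

    def _replant(taxon: str, fresh: np.ndarray) -> None:
        markers[taxon]["sequence"] = _to_str(fresh)
        for rec in records:
            if rec.taxon != taxon:
                continue
            if rec.id.startswith(f"{taxon}_rev"):
                rc = np.frombuffer(
                    reverse_complement(rec.sequence).encode(), dtype=np.uint8
                ).copy()
                if rc.size > marker_slice.stop:
                    rc[marker_slice] = fresh
                rec.sequence = reverse_complement(_to_str(rc))
            else:
                body = np.frombuffer(rec.sequence.encode(), dtype=np.uint8).copy()
                if body.size > marker_slice.stop:
                    body[marker_slice] = fresh
                    rec.sequence = _to_str(body)

    # verification runs to a fixed point because replanting one group's
    # marker perturbs the windows other groups were checked against
    for _pass in range(10):
        changed = False
        for taxon in taxa:
            others = [r.sequence for r in records if r.taxon != taxon]
            for _try in range(200):
                if _window_similarity_below(
                    markers[taxon]["sequence"], others,
                    spec.marker_max_similarity,
                ):
                    break
                _replant(taxon, rng.choice(_BASES, size=spec.marker_length))
                changed = True
            else:
                raise RuntimeError(f"no specific marker found for {taxon}")
        if not changed:
            break

    manifest = {
        "spec": asdict(spec),
        "dispositions": dispositions,
        "reoriented": reoriented,
        "markers": markers,
        "groups": per_group,
    }
    reference = SequenceRecord(
        id="REF", sequence=_to_str(root), kingdom=Kingdom.PROKARYOTE,
        taxon="reference",
    )
    return Fixture(
        spec=spec, records=records, taxonomy=taxonomy,
        reference=reference, manifest=manifest,
    )


def write_fixture(fix: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write input FASTA, taxonomy TSV, reference FASTA, and manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "input.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "reference": out / "reference.fasta",
        "manifest": out / "manifest.json",
    }
    write_fasta(fix.records, paths["fasta"])
    with open(paths["taxonomy"], "w") as fh:
        fh.write("id\tkingdom\ttaxon\n")
        for rid, (kingdom, taxon) in fix.taxonomy.items():
            fh.write(f"{rid}\t{kingdom.value}\t{taxon}\n")
    write_fasta([fix.reference], paths["reference"])
    with open(paths["manifest"], "w") as fh:
        json.dump(fix.manifest, fh, indent=1, sort_keys=True)
    return paths
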