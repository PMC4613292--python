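"""Reading, writing and summarising labeled marker alignments.

A *labeled alignment* is the universe every analysis stage consumes: a set of
(pre-trimmed, usually pre-aligned) marker sequences, each carrying the species
it was sampled from, plus an optional set of species flagged as outgroups.
Species labels come either from a two/three-column TSV (``id<TAB>species`` with
an optional ``outgroup`` column) or, by default, from the FASTA description
after the first whitespace-delimited token — the way organism names ride along
in GenBank-style headers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SeqioError",
    "LabeledRecord",
    "LabeledAlignment",
    "SequenceSummary",
    "read_labeled_fasta",
    "read_labels_tsv",
    "write_labeled_fasta",
    "summarize_sequences",
]

_GAP = "-"
_NUCLEOTIDES = frozenset("ACGT")


class SeqioError(ValueError):
    """Raised for unparseable or inconsistent sequence input."""


@dataclass(frozen=True)
class LabeledRecord:
    """One sequence with its species label."""

    id: str
    species: str
    residues: str


@dataclass
class LabeledAlignment:
    """Ordered labeled sequences; ``aligned`` is true when all lengths match.

    Residues are uppercase over ``{A, C, G, T, -, N}`` plus any other IUPAC
    ambiguity codes, which are retained on read and excluded site-wise at
    computation time (pairwise deletion).
    """

    records: list[LabeledRecord]
    aligned: bool = False
    outgroup_species: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqioError(f"duplicate sequence id(s): {', '.join(dup)}")
        for r in self.records:
            if not r.species:
                raise SeqioError(f"empty species label for sequence {r.id!r}")
        if self.aligned:
            lengths = {len(r.residues) for r in self.records}
            if len(lengths) > 1:
                raise SeqioError(
                    f"aligned=True but sequence lengths differ: {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> dict[str, str]:
        """Mapping sequence id -> species."""
        return {r.id: r.species for r in self.records}

    @property
    def species(self) -> list[str]:
        """Distinct species in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def ingroup(self) -> "LabeledAlignment":
        """Copy with outgroup-flagged species removed."""
        recs = [r for r in self.records if r.species not in self.outgroup_species]
        return LabeledAlignment(recs, aligned=self.aligned, outgroup_species=set())

    def subset(self, ids: Iterable[str]) -> "LabeledAlignment":
        keep = set(ids)
        recs = [r for r in self.records if r.id in keep]
        return LabeledAlignment(
            recs, aligned=self.aligned, outgroup_species=set(self.outgroup_species)
        )


@dataclass(frozen=True)
class SequenceSummary:
    """Per-dataset sequence characteristics (lengths in bp, GC as fractions).

    Lengths count ungapped residues; GC is (G+C)/(A+C+G+T) per sequence with
    N and other ambiguity codes excluded from numerator and denominator.
    """

    n_sequences: int
    length_min: int
    length_max: int
    length_mean: float
    gc_mean: float
    gc_min: float
    gc_max: float


def _normalize(residues: str) -> str:
    return residues.upper().replace(".", _GAP)


def read_labels_tsv(path: str | Path) -> tuple[dict[str, str], set[str]]:
    """Parse an ``id<TAB>species[<TAB>outgroup]`` table.

    The third column marks outgroup membership; any of ``1/true/yes/outgroup``
    (case-insensitive) flags the *species* as outgroup.
    """
    labels: dict[str, str] = {}
    outgroups: set[str] = set()
    truthy = {"1", "true", "yes", "outgroup", "y"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SeqioError(f"{path}:{lineno}: expected id<TAB>species")
            sid, species = parts[0].strip(), parts[1].strip()
            if sid in labels:
                raise SeqioError(f"{path}:{lineno}: duplicate id {sid!r}")
            labels[sid] = species
            if len(parts) >= 3 and parts[2].strip().lower() in truthy:
                outgroups.add(species)
    return labels, outgroups


def read_labeled_fasta(
    fasta_path: str | Path, labels: str | Path | dict[str, str] | None = None
) -> LabeledAlignment:
    """Read a FASTA file and resolve every sequence to a species label.

    Parameters
    ----------
    fasta_path:
        FASTA file of marker sequences (aligned or not).
    labels:
        Either a TSV path / mapping of ``sequence id -> species``, or None to
        take the species from the FASTA description after the first token.

    Raises
    ------
    SeqioError
        On an empty file, a duplicate id, or a sequence without a label.
    """
    outgroups: set[str] = set()
    mapping: dict[str, str] | None
    if labels is None:
        mapping = None
    elif isinstance(labels, dict):
        mapping = dict(labels)
    else:
        mapping, outgroups = read_labels_tsv(labels)

    records: list[LabeledRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        residues = _normalize(str(rec.seq))
        if mapping is not None:
            if rec.id not in mapping:
                raise SeqioError(f"unlabeled sequence: {rec.id!r} not in label table")
            species = mapping[rec.id]
        else:
            parts = rec.description.split(None, 1)
            if len(parts) < 2 or not parts[1].strip():
                raise SeqioError(
                    f"unlabeled sequence: {rec.id!r} has no species in its header"
                )
            species = parts[1].strip()
        records.append(LabeledRecord(rec.id, species, residues))

    if not records:
        raise SeqioError(f"no sequences found in {fasta_path}")
    lengths = {len(r.residues) for r in records}
    return LabeledAlignment(records, aligned=len(lengths) == 1, outgroup_species=outgroups)


def write_labeled_fasta(
    aln: LabeledAlignment, fasta_path: str | Path, labels_path: str | Path | None = None
) -> None:
    """Write FASTA (id + species in the description) and optionally a labels TSV."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.species)
        for r in aln.records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for r in aln.records:
                flag = "outgroup" if r.species in aln.outgroup_species else ""
                row = [r.id, r.species] + ([flag] if flag else [])
                fh.write("\t".join(row) + "\n")


def _gc_fraction(residues: str) -> float:
    counts = {b: 0 for b in "ACGT"}
    for b in residues:
        if b in counts:
            counts[b] += 1
    total = sum(counts.values())
    if total == 0:
        raise SeqioError("sequence has zero countable (ACGT) residues")
    return (counts["G"] + counts["C"]) / total


def summarize_sequences(aln: LabeledAlignment) -> SequenceSummary:
    """Length and GC-content summary over the alignment's sequences.

    Lengths exclude gap characters; GC excludes N/ambiguity codes entirely.
    Permutation-invariant over records.
    """
    if not aln.records:
        raise SeqioError("cannot summarize an empty alignment")
    lengths = []
    gcs = []
    for r in aln.records:
        ungapped = r.residues.replace(_GAP, "")
        lengths.append(len(ungapped))
        gcs.append(_gc_fraction(ungapped))
    return SequenceSummary(
        n_sequences=len(aln.records),
        length_min=min(lengths),
        length_max=max(lengths),
        length_mean=math.fsum(lengths) / len(lengths),
        gc_mean=math.fsum(gcs) / len(gcs),
        gc_min=min(gcs),
        gc_max=max(gcs),
    )
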