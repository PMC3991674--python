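"""In-silico Trypsin/P digestion and reversed-decoy database construction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masschem import RESIDUE_MASS

__all__ = [
    "ProteinEntry",
    "DigestPeptide",
    "DEFAULT_DECOY_PREFIX",
    "digest",
    "reverse_decoy",
    "build_target_decoy",
    "read_fasta",
    "write_fasta",
]

logger = logging.getLogger(__name__)

DEFAULT_DECOY_PREFIX = "rev_"


@dataclass(frozen=True)
class ProteinEntry:
    """One FASTA entry; decoys carry a configurable accession prefix."""

    accession: str
    description: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        for aa in self.sequence:
            if not aa.isupper() or aa not in RESIDUE_MASS:
                raise ValueError(
                    f"invalid residue {aa!r} in protein {self.accession!r}"
                )


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with 1-based inclusive parent coordinates."""

    sequence: str
    accession: str
    start: int
    end: int
    missed_cleavages: int


def _cleavage_points(sequence: str) -> list[int]:
    """1-based positions after which Trypsin/P cleaves (every K/R, incl. before P)."""
    return [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]


def digest(
    protein: ProteinEntry,
    max_missed: int = 3,
    min_length: int = 1,
) -> list[DigestPeptide]:
    """Trypsin/P digestion products of ``protein`` with up to ``max_missed``
    missed cleavages.

    Cleavage occurs after every K or R (including K/R-P bonds). Peptides are
    all contiguous unions of up to ``max_missed + 1`` fully-cleaved fragments.
    """
    if max_missed < 0:
        raise ValueError(f"max_missed must be >= 0, got {max_missed}")
    seq = protein.sequence
    points = _cleavage_points(seq)
    # Fragment boundaries: [start, end] pairs, 1-based inclusive.
    cuts = [0] + [p for p in points if p < len(seq)] + [len(seq)]
    fragments = [(cuts[i] + 1, cuts[i + 1]) for i in range(len(cuts) - 1)]
    peptides: list[DigestPeptide] = []
    for i in range(len(fragments)):
        for mc in range(0, max_missed + 1):
            j = i + mc
            if j >= len(fragments):
                break
            start, end = fragments[i][0], fragments[j][1]
            pep = seq[start - 1 : end]
            if len(pep) >= min_length:
                peptides.append(
                    DigestPeptide(pep, protein.accession, start, end, mc)
                )
    return peptides


def reverse_decoy(
    protein: ProteinEntry, prefix: str = DEFAULT_DECOY_PREFIX
) -> ProteinEntry:
    """End-to-end sequence reversal; accession gains the decoy prefix."""
    if protein.is_decoy:
        raise ValueError(f"protein {protein.accession!r} is already a decoy")
    reversed_seq = protein.sequence[::-1]
    if reversed_seq == protein.sequence:
        logger.warning(
            "palindromic sequence: decoy %s%s is identical to its target",
            prefix,
            protein.accession,
        )
    return ProteinEntry(
        accession=prefix + protein.accession,
        description=f"decoy of {protein.accession}",
        sequence=reversed_seq,
        is_decoy=True,
    )


def build_target_decoy(
    proteins: Iterable[ProteinEntry], prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinEntry]:
    """Targets followed by their reversed decoys."""
    targets = list(proteins)
    return targets + [reverse_decoy(p, prefix) for p in targets]


def read_fasta(
    path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        description = rec.description
        if description.startswith(rec.id):
            description = description[len(rec.id) :].strip()
        entries.append(
            ProteinEntry(
                accession=rec.id,
                description=description,
                sequence=str(rec.seq).upper(),
                is_decoy=rec.id.startswith(decoy_prefix),
            )
        )
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description=e.description)
        for e in entries
    ]
    with open(path, "w") as fh:
        # Biopython's "fasta" writer wraps at 60 columns.
        SeqIO.write(records, fh, "fasta")
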