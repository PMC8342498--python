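"""Protein sequence handling and in-silico tryptic digestion.

Coordinates are 1-based and inclusive throughout, so a peptide spanning
residues 56..80 of its parent protein is written ``(56, 80)`` and its
flanking residues are the parent residues 55 and 81 (``"-"`` at protein
termini).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "AMINO_ACIDS",
    "Species",
    "ProteinRecord",
    "PeptideLocation",
    "CleavageClass",
    "digest",
    "cleavage_sites",
    "classify_cleavage",
    "find_sequons",
    "find_modifiable_sites",
    "read_fasta",
]


class Species(str, enum.Enum):
    """Source organism / role tag, assigned from the FASTA, never inferred."""

    BARLEY = "barley"
    YEAST = "yeast"
    CONTAMINANT = "contaminant"
    TRYPSIN = "trypsin"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    species: Species
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty accession")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"{self.accession}: position {pos} out of range")
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class PeptideLocation:
    """A peptide's span within a protein, with flanking residues.

    ``prev_aa``/``next_aa`` are ``"-"`` at the protein N-/C-terminus.
    """

    accession: str
    start: int
    end: int
    prev_aa: str
    next_aa: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sequence_in(self, protein: ProteinRecord) -> str:
        return protein.sequence[self.start - 1 : self.end]

    def validate_against(self, protein: ProteinRecord) -> None:
        """Raise ValueError if this location is inconsistent with ``protein``."""
        if self.accession != protein.accession:
            raise ValueError(
                f"location accession {self.accession!r} != {protein.accession!r}"
            )
        if self.end > len(protein):
            raise ValueError(
                f"{self.accession}: span {self.start}..{self.end} exceeds "
                f"length {len(protein)}"
            )
        want_prev = protein.sequence[self.start - 2] if self.start > 1 else "-"
        want_next = (
            protein.sequence[self.end] if self.end < len(protein) else "-"
        )
        if self.prev_aa != want_prev or self.next_aa != want_next:
            raise ValueError(
                f"{self.accession}:{self.start}-{self.end}: flanks "
                f"{self.prev_aa}/{self.next_aa} disagree with protein "
                f"({want_prev}/{want_next})"
            )


class CleavageClass(str, enum.Enum):
    FULL_TRYPTIC = "full_tryptic"
    SEMI_TRYPTIC = "semi_tryptic"
    NON_TRYPTIC = "non_tryptic"


def cleavage_sites(sequence: str, cleave_before_proline: bool = True) -> list[int]:
    """1-based positions after which trypsin cleaves (C-terminal to K/R).

    With ``cleave_before_proline=False`` a K/R followed by P is not a site
    (the conventional proline exception). The protein C-terminus is not
    returned; callers treat it as an implicit boundary.
    """
    sites = []
    for i, aa in enumerate(sequence[:-1], start=1):
        if aa in "KR" and (cleave_before_proline or sequence[i] != "P"):
            sites.append(i)
    return sites


def _location(protein: ProteinRecord, start: int, end: int) -> PeptideLocation:
    seq = protein.sequence
    return PeptideLocation(
        accession=protein.accession,
        start=start,
        end=end,
        prev_aa=seq[start - 2] if start > 1 else "-",
        next_aa=seq[end] if end < len(seq) else "-",
    )


def digest(
    protein: ProteinRecord,
    max_missed: int = 0,
    cleave_before_proline: bool = True,
) -> list[PeptideLocation]:
    """Enumerate tryptic peptides with 0..``max_missed`` missed cleavages.

    No length filter is applied; the full partition (``max_missed=0``)
    concatenates back to the protein sequence. Ordered by start then end.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    bounds = [0] + cleavage_sites(seq, cleave_before_proline) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            peptides.append(_location(protein, bounds[i] + 1, bounds[j]))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def classify_cleavage(
    loc: PeptideLocation,
    protein: ProteinRecord,
    cleave_before_proline: bool = True,
) -> CleavageClass:
    """Assign full/semi/non-tryptic from the peptide termini.

    A terminus is tryptic if it follows a K/R cleavage site or coincides
    with a protein terminus (protein termini count as tryptic by
    convention).
    """
    loc.validate_against(protein)
    seq = protein.sequence
    nt = loc.start == 1 or (
        loc.prev_aa in "KR"
        and (cleave_before_proline or seq[loc.start - 1] != "P")
    )
    last = seq[loc.end - 1]
    ct = loc.end == len(seq) or (
        last in "KR" and (cleave_before_proline or loc.next_aa != "P")
    )
    if nt and ct:
        return CleavageClass.FULL_TRYPTIC
    if nt or ct:
        return CleavageClass.SEMI_TRYPTIC
    return CleavageClass.NON_TRYPTIC


def find_sequons(peptide_seq: str, exclude_proline: bool = False) -> list[int]:
    """1-based positions of N in N-X-S/T motifs inside ``peptide_seq``.

    Motifs truncated by the peptide boundary are not reported. X=P is
    allowed unless ``exclude_proline`` is set.
    """
    out = []
    for i in range(len(peptide_seq) - 2):
        if (
            peptide_seq[i] == "N"
            and peptide_seq[i + 2] in "ST"
            and not (exclude_proline and peptide_seq[i + 1] == "P")
        ):
            out.append(i + 1)
    return out


def find_modifiable_sites(
    peptide_seq: str, residue_set: Iterable[str]
) -> list[int]:
    """1-based positions whose residue is in ``residue_set``."""
    residues = set(residue_set)
    return [i for i, aa in enumerate(peptide_seq, start=1) if aa in residues]


def read_fasta(
    path: str | Path,
    species_map: Mapping[str, Species | str] | None = None,
    species_field: str = "species=",
) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into ``{accession: ProteinRecord}``.

    The species tag is taken from ``species_map[accession]`` when given,
    otherwise parsed from a ``species=<tag>`` token in the header
    description. Records with no resolvable species raise.
    """
    db: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in db:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        species: Species | str | None = None
        if species_map is not None and acc in species_map:
            species = species_map[acc]
        else:
            for token in rec.description.split():
                if token.startswith(species_field):
                    species = token[len(species_field):]
                    break
        if species is None:
            raise ValueError(f"{acc}: no species tag in header or mapping")
        db[acc] = ProteinRecord(
            accession=acc,
            species=Species(species),
            sequence=str(rec.seq).upper(),
        )
    return db
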