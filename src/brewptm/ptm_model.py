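"""Modified peptide forms, the mods grammar, and peptide-family keys.

A *peptide family* is the set of peptide forms — unmodified, glycosylated,
glycated, or proteolytically clipped — that share one full-tryptic anchor
peptide; family membership is the normalization unit for all occupancy
statistics downstream.

Mods grammar (quant-table ``mods`` column), semicolon separated::

    unmodified
    Hex(3)@K2            glycation (site residue K)
    Hex(2)@S5            O-glycosylation (site residue S/T)
    Hex(3)@undetermined  kind inferred from the accession's species
    HexNAc(1)@N7         N-glycosylation (site must lie in an N-X-S/T sequon)
    HexNAc(2)Hex(5)@N7   N-glycosylation with hexose extension
    Deamidated@N3        common modification
    Oxidized@M5          common modification
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Mapping

from .seqdigest import (
    CleavageClass,
    PeptideLocation,
    ProteinRecord,
    Species,
    classify_cleavage,
    cleavage_sites,
    digest,
    find_sequons,
)

__all__ = [
    "ModKind",
    "CommonMod",
    "Modification",
    "PeptideForm",
    "FamilyKey",
    "FormError",
    "parse_mods",
    "locate_peptide",
    "parse_form",
    "family_key",
    "missed_cleavages",
]


class FormError(ValueError):
    """A quant-table row that cannot be turned into a valid PeptideForm."""


class ModKind(str, enum.Enum):
    GLYCATION_HEX = "glycation_hex"   # Hex1-10 on Lys
    O_GLYC_HEX = "o_glyc_hex"         # Hex1-10 on Ser/Thr
    N_GLYC = "n_glyc"                 # HexNAc1-2 (+Hex0-10) at a sequon


class CommonMod(str, enum.Enum):
    DEAMIDATED_N = "deamidated_N"
    OXIDIZED_M = "oxidized_M"


@dataclass(frozen=True)
class Modification:
    kind: ModKind
    hex: int = 0
    hexnac: int = 0
    site: int | None = None  # peptide-relative 1-based; None = undetermined

    def __post_init__(self) -> None:
        if self.kind is ModKind.N_GLYC:
            if not 1 <= self.hexnac <= 2:
                raise FormError(f"n_glyc requires HexNAc 1-2, got {self.hexnac}")
            if not 0 <= self.hex <= 10:
                raise FormError(f"n_glyc Hex must be 0-10, got {self.hex}")
        else:
            if self.hexnac != 0:
                raise FormError(f"{self.kind.value} cannot carry HexNAc")
            if not 1 <= self.hex <= 10:
                raise FormError(
                    f"{self.kind.value} requires Hex 1-10, got {self.hex}"
                )

    @property
    def composition(self) -> str:
        parts = []
        if self.hexnac:
            parts.append(f"HexNAc({self.hexnac})")
        if self.hex:
            parts.append(f"Hex({self.hex})")
        return "".join(parts) or "Hex(0)"


@dataclass(frozen=True)
class PeptideForm:
    """One quantifiable peptide form: location + cleavage + modification state."""

    location: PeptideLocation
    cleavage: CleavageClass
    mods: tuple[Modification, ...] = ()
    common_mods: tuple[CommonMod, ...] = ()

    def __post_init__(self) -> None:
        if len(self.mods) > 1:
            raise FormError("at most one glyco/glycation modification per peptide")
        if len(self.common_mods) > 2:
            raise FormError("at most two common modifications per peptide")
        if sum(m is CommonMod.DEAMIDATED_N for m in self.common_mods) > 1:
            raise FormError("deamidation allowed at most once per peptide")
        for m in self.mods:
            if m.site is not None and not 1 <= m.site <= self.location.length:
                raise FormError(
                    f"mod site {m.site} outside peptide of length "
                    f"{self.location.length}"
                )

    @property
    def mod_kind(self) -> ModKind | None:
        return self.mods[0].kind if self.mods else None

    def backbone_id(self) -> tuple:
        """Identity ignoring common mods (forms differing only in common
        mods are collapsed for family analysis)."""
        loc = self.location
        mods = tuple(
            (m.kind.value, m.hex, m.hexnac, m.site) for m in self.mods
        )
        return (loc.accession, loc.start, loc.end, mods)


@dataclass(frozen=True)
class FamilyKey:
    """The full-tryptic anchor peptide grouping all forms of one family."""

    accession: str
    anchor_start: int
    anchor_end: int

    def __str__(self) -> str:
        return f"{self.accession}:{self.anchor_start}-{self.anchor_end}"


_COMP_TOKEN = re.compile(r"(HexNAc|Hex)\((\d+)\)")
_MOD_RE = re.compile(
    r"^((?:(?:HexNAc|Hex)\(\d+\))+)@(?:([A-Z])(\d+)|undetermined)$"
)
_COMMON_RE = re.compile(r"^(Deamidated|Oxidized)@([A-Z])(\d+)$")


def _infer_hex_kind(
    peptide_seq: str, site: int | None, species: Species
) -> ModKind:
    if site is not None:
        residue = peptide_seq[site - 1]
        if residue == "K":
            return ModKind.GLYCATION_HEX
        if residue in "ST":
            return ModKind.O_GLYC_HEX
        raise FormError(f"Hex modification on residue {residue} (not K/S/T)")
    # Undetermined site: type from the species of the parent protein.
    if species is Species.YEAST:
        return ModKind.O_GLYC_HEX
    if species is Species.BARLEY:
        return ModKind.GLYCATION_HEX
    raise FormError(
        f"cannot type undetermined-site Hex modification on {species.value} protein"
    )


def parse_mods(
    mods_str: str,
    peptide_seq: str,
    species: Species,
    sequons: list[int] | None = None,
) -> tuple[tuple[Modification, ...], tuple[CommonMod, ...]]:
    """Parse and validate a ``mods`` column value against the peptide."""
    mods_str = mods_str.strip()
    if not mods_str or mods_str == "unmodified":
        return (), ()
    if sequons is None:
        sequons = find_sequons(peptide_seq)
    rare: list[Modification] = []
    common: list[CommonMod] = []
    for token in (t.strip() for t in mods_str.split(";")):
        m = _COMMON_RE.match(token)
        if m:
            name, residue, pos_s = m.groups()
            pos = int(pos_s)
            if not 1 <= pos <= len(peptide_seq):
                raise FormError(f"{token}: position outside peptide")
            if peptide_seq[pos - 1] != residue:
                raise FormError(
                    f"{token}: residue mismatch (peptide has "
                    f"{peptide_seq[pos - 1]} at {pos})"
                )
            if name == "Deamidated":
                if residue != "N":
                    raise FormError(f"{token}: deamidation is on Asn")
                common.append(CommonMod.DEAMIDATED_N)
            else:
                if residue != "M":
                    raise FormError(f"{token}: oxidation is on Met")
                common.append(CommonMod.OXIDIZED_M)
            continue
        m = _MOD_RE.match(token)
        if m is None:
            raise FormError(f"unparseable modification token {token!r}")
        comp_str, residue, pos_s = m.groups()
        comp = {"Hex": 0, "HexNAc": 0}
        for name, count in _COMP_TOKEN.findall(comp_str):
            comp[name] += int(count)
        site = int(pos_s) if pos_s is not None else None
        if site is not None:
            if not 1 <= site <= len(peptide_seq):
                raise FormError(f"{token}: position outside peptide")
            if peptide_seq[site - 1] != residue:
                raise FormError(
                    f"{token}: residue mismatch (peptide has "
                    f"{peptide_seq[site - 1]} at {site})"
                )
        if comp["HexNAc"] > 0:
            kind = ModKind.N_GLYC
            if site is not None and site not in sequons:
                raise FormError(f"{token}: site not in an N-X-S/T sequon")
        else:
            kind = _infer_hex_kind(peptide_seq, site, species)
        rare.append(
            Modification(kind=kind, hex=comp["Hex"], hexnac=comp["HexNAc"], site=site)
        )
    return tuple(rare), tuple(common)


def locate_peptide(
    peptide_seq: str,
    prev_aa: str,
    next_aa: str,
    protein: ProteinRecord,
) -> PeptideLocation:
    """Locate a peptide in its protein by exact string + flank match.

    Raises FormError when the peptide is absent or matches more than one
    position consistent with the stated flanks (ambiguous).
    """
    seq = protein.sequence
    hits = []
    i = seq.find(peptide_seq)
    while i != -1:
        start, end = i + 1, i + len(peptide_seq)
        p = seq[i - 1] if i > 0 else "-"
        n = seq[end] if end < len(seq) else "-"
        if p == prev_aa and n == next_aa:
            hits.append((start, end, p, n))
        i = seq.find(peptide_seq, i + 1)
    if not hits:
        raise FormError(
            f"peptide {peptide_seq!r} with flanks {prev_aa}/{next_aa} "
            f"not found in {protein.accession}"
        )
    if len(hits) > 1:
        raise FormError(
            f"peptide {peptide_seq!r} ambiguous in {protein.accession} "
            f"({len(hits)} hits)"
        )
    start, end, p, n = hits[0]
    return PeptideLocation(protein.accession, start, end, p, n)


def parse_form(
    row: Mapping[str, str],
    db: Mapping[str, ProteinRecord],
    cleave_before_proline: bool = True,
) -> PeptideForm:
    """Turn one quant-table record into a validated PeptideForm.

    ``row`` needs keys: accession, peptide, prev_aa, next_aa, mods.
    """
    acc = row["accession"]
    protein = db.get(acc)
    if protein is None:
        raise FormError(f"unknown accession {acc!r}")
    peptide = row["peptide"].strip().upper()
    if not peptide:
        raise FormError("empty peptide sequence")
    loc = locate_peptide(peptide, row["prev_aa"].strip(), row["next_aa"].strip(), protein)
    cleavage = classify_cleavage(loc, protein, cleave_before_proline)
    mods, common = parse_mods(row.get("mods", "unmodified"), peptide, protein.species)
    return PeptideForm(location=loc, cleavage=cleavage, mods=mods, common_mods=common)


def missed_cleavages(
    loc: PeptideLocation, protein: ProteinRecord, cleave_before_proline: bool = True
) -> int:
    """Number of internal K/R cleavage sites spanned by the peptide."""
    sites = cleavage_sites(protein.sequence, cleave_before_proline)
    return sum(loc.start <= s < loc.end for s in sites)


def family_key(
    form: PeptideForm,
    db: Mapping[str, ProteinRecord],
    max_missed: int = 2,
    cleave_before_proline: bool = True,
) -> FamilyKey | None:
    """Anchor a form on its minimal containing full-tryptic peptide.

    Minimal means fewest missed cleavages, then shortest span, then
    smallest start (deterministic, disjoint family definitions). Returns
    None when no containing full-tryptic peptide exists within
    ``max_missed`` (the form is unassignable).
    """
    protein = db[form.location.accession]
    best: tuple[int, int, int] | None = None
    best_loc = None
    for cand in digest(protein, max_missed, cleave_before_proline):
        if cand.start <= form.location.start and cand.end >= form.location.end:
            mc = missed_cleavages(cand, protein, cleave_before_proline)
            rank = (mc, cand.length, cand.start)
            if best is None or rank < best:
                best, best_loc = rank, cand
    if best_loc is None:
        return None
    return FamilyKey(protein.accession, best_loc.start, best_loc.end)
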