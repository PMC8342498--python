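"""Shared fixtures: worked-example proteins and a small synthetic bundle.

The four named proteins embed published peptide coordinates (1-based):
GLT3-like has the full-tryptic peptide V56..R80 with flanks R/D and
documented clipped forms V56..Q74 and V56..T69; PST1-like carries the
sequon-bearing peptide C51..K65 (N at protein position 57) with flanks
R/T; NLTP1-like carries the glycation peptide M36..R58 (K at 37) with
flanks K/S; PAU15-like carries V94..R104 with flanks R/L.
"""

from __future__ import annotations

import numpy as np
import pytest

from brewptm.seqdigest import ProteinRecord, Species

# filler with no K/R so cleavage sites sit only where we plant them
_FILLER = "ADEFGHILMNPQSTVW"


def filler(n: int) -> str:
    return (_FILLER * (n // len(_FILLER) + 1))[:n]


GLT3_PEPTIDE = "VVDQQLVGQLPWSTGLQMQCCQQLR"     # V56..R80
PST1_PEPTIDE = "CDTLVGNLTIGGGLK"               # C51..K65, sequon N57
NLTP1_PEPTIDE = "MKPCLTYVQGGPGPSGECCNGVR"      # M36..R58, Lys at 37
PAU15_PEPTIDE = "VITGVPWYSTR"                  # V94..R104

GLT3_SEQ = filler(54) + "R" + GLT3_PEPTIDE + "D" + filler(10)
PST1_SEQ = filler(49) + "R" + PST1_PEPTIDE + "T" + filler(10)
NLTP1_SEQ = filler(34) + "K" + NLTP1_PEPTIDE + "S" + filler(10)
PAU15_SEQ = filler(92) + "R" + PAU15_PEPTIDE + "L" + filler(8)


@pytest.fixture(scope="session")
def glt3() -> ProteinRecord:
    return ProteinRecord("GLT3", Species.BARLEY, GLT3_SEQ)


@pytest.fixture(scope="session")
def pst1() -> ProteinRecord:
    return ProteinRecord("PST1", Species.YEAST, PST1_SEQ)


@pytest.fixture(scope="session")
def nltp1() -> ProteinRecord:
    return ProteinRecord("NLTP1", Species.BARLEY, NLTP1_SEQ)


@pytest.fixture(scope="session")
def pau15() -> ProteinRecord:
    return ProteinRecord("PAU15", Species.YEAST, PAU15_SEQ)


@pytest.fixture(scope="session")
def toy_db(glt3, pst1, nltp1, pau15) -> dict[str, ProteinRecord]:
    return {p.accession: p for p in (glt3, pst1, nltp1, pau15)}


def random_protein(rng: np.random.Generator, length: int = 120,
                   accession: str = "RND1",
                   species: Species = Species.BARLEY) -> ProteinRecord:
    residues = np.array(list("ACDEFGHILMNPQSTVWYKR"))
    p = np.full(20, 0.895 / 18)
    p[-2:] = 0.105 / 2
    seq = "".join(rng.choice(residues, size=length, p=p))
    return ProteinRecord(accession, species, seq)


@pytest.fixture(scope="session")
def small_bundle():
    """Small default-config synthetic bundle shared across test modules."""
    from brewptm.synthetic_data import GeneratorConfig, generate

    cfg = GeneratorConfig(
        seed=7, n_breweries=3, beers_per_brewery=2,
        n_barley_proteins=5, n_yeast_proteins=3,
    )
    return generate(cfg)
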