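"""Synthetic dataset generator with recorded ground truth.

Produces a complete, structurally valid bundle — protein FASTA, long
quant table, sample metadata, foam table — together with the planted
truth (per-family occupancies, protein abundances, group effects, foam
coefficients), so that every downstream stage can be tested for
parameter recovery without any external data.

Structure emulated: barley proteins carry Lys glycation (Hex1..7,
weighted toward Hex1/Hex2) and semi/non-tryptic clipped forms; yeast
proteins carry Ser/Thr O-glycosylation (Hex1..8) and a single
HexNAc1 sequon event on one designated protein; abundances have
brewery and style effects with technical-replicate noise; dark styles
get less glycated-protein abundance, more within-family clipping, and
less clipped-protein abundance; foam variables are linear in
seripauperin / NLTP class abundance with calibrated noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdigest import ProteinRecord, Species, digest

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "Bundle",
    "generate",
    "write_bundle",
    "truth_check",
]

_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWYKR"))


def _residue_probs(kr_frequency: float) -> np.ndarray:
    p = np.full(20, (1.0 - kr_frequency) / 18.0)
    p[-2:] = kr_frequency / 2.0
    return p


@dataclass
class GeneratorConfig:
    seed: int = 1
    # cohort
    n_breweries: int = 4
    beers_per_brewery: int = 3
    styles: tuple = ("lager", "pale_ale", "porter")
    dark_styles: tuple = ("porter", "amber_ale", "dark_ale", "stout")
    n_multinational: int = 2  # first k breweries tagged multinational
    n_replicates: int = 3
    replicate_cv: float = 0.2
    # proteome
    n_barley_proteins: int = 10
    n_yeast_proteins: int = 5
    n_contaminants: int = 1
    n_nltp: int = 3
    n_serpin: int = 3
    n_seripauperin: int = 3
    protein_length: tuple = (150, 280)
    kr_frequency: float = 0.105
    max_families_per_protein: int = 5
    family_length_range: tuple = (6, 30)
    # modification models
    glycation_site_prob: float = 0.6
    glycation_hex_weights: tuple = (0.47, 0.33, 0.09, 0.05, 0.03, 0.02, 0.01)
    oglyc_site_prob: float = 0.5
    oglyc_hex_weights: tuple = (0.35, 0.25, 0.15, 0.10, 0.06, 0.04, 0.03, 0.02)
    undetermined_site_prob: float = 0.2
    sequon_event: bool = True
    clipping_family_prob: float = 0.6
    max_clip_sites: int = 2
    occupancy_range: tuple = (0.1, 0.5)
    # abundance model
    base_log10_abundance: float = 5.0
    base_log10_sd: float = 0.5
    brewery_sd: float = 0.5
    style_sd: float = 0.25
    dark_glycation_abundance_mult: float = 0.3
    dark_clip_occupancy_mult: float = 2.0
    dark_clipped_abundance_mult: float = 0.5
    trypsin_peptide_intensity: float = 2.0e5
    contaminant_log10_abundance: float = 4.0
    detection_limit: float = 0.0  # forms below this base intensity are not emitted
    # fdr model
    fdr_fail_rate: float = 0.01
    fdr_cutoff: float = 0.01
    n_decoys: int = 0
    # foam model: (field, protein class, slope, intercept, target R^2).
    # The predictor is centered before applying the slope, so the intercept
    # is the cohort mean of the foam variable and truncation at 0 is rare.
    foam_couplings: tuple = (
        ("foam_lifetime", "seripauperin", -4.0e2, 220.0, 0.70),
        ("bubbles_small", "seripauperin", -3.0e3, 1500.0, 0.38),
        ("max_foam_volume", "NLTP", 3.0e2, 250.0, 0.30),
    )
    foam_baselines: tuple = (
        ("max_foam_volume", 250.0, 25.0),
        ("foam_lifetime", 200.0, 20.0),
        ("drainage", 1.5, 0.3),
        ("bubbles_small", 1200.0, 150.0),
        ("bubbles_medium", 500.0, 60.0),
        ("bubbles_large", 120.0, 20.0),
    )

    def validate(self) -> None:
        for name in ("glycation_site_prob", "oglyc_site_prob",
                     "undetermined_site_prob", "clipping_family_prob",
                     "fdr_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        for name in ("n_breweries", "beers_per_brewery", "n_replicates",
                     "n_barley_proteins", "n_yeast_proteins",
                     "max_families_per_protein"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        lo, hi = self.occupancy_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("occupancy_range must satisfy 0 <= lo <= hi < 1")
        if not abs(sum(self.glycation_hex_weights) - 1) < 1e-6:
            raise ValueError("glycation_hex_weights must sum to 1")
        if not abs(sum(self.oglyc_hex_weights) - 1) < 1e-6:
            raise ValueError("oglyc_hex_weights must sum to 1")


@dataclass
class GroundTruth:
    seed: int
    occupancy: pd.DataFrame        # beer, family, kind, occupancy
    protein_norm: pd.DataFrame     # beer, accession, norm_total_true
    brewery_effects: pd.DataFrame  # accession x brewery log10 effects
    foam_model: dict               # field -> model parameters
    decoy_form_ids: list
    class_map: dict


@dataclass
class Bundle:
    config: GeneratorConfig
    proteins: dict                 # accession -> ProteinRecord
    quant: pd.DataFrame
    metadata: pd.DataFrame
    foam: pd.DataFrame
    truth: GroundTruth


def _random_sequence(rng: np.random.Generator, length: int,
                     probs: np.ndarray) -> str:
    return "".join(rng.choice(_RESIDUES, size=length, p=probs))


def _unique_with_flanks(seq: str, start: int, end: int) -> bool:
    """Is the (substring, flanks) combination unique within the protein?"""
    sub = seq[start - 1 : end]
    prev = seq[start - 2] if start > 1 else "-"
    nxt = seq[end] if end < len(seq) else "-"
    hits = 0
    i = seq.find(sub)
    while i != -1:
        s, e = i + 1, i + len(sub)
        p = seq[i - 1] if i > 0 else "-"
        n = seq[e] if e < len(seq) else "-"
        if p == prev and n == nxt:
            hits += 1
        i = seq.find(sub, i + 1)
    return hits == 1


def _flanks(seq: str, start: int, end: int) -> tuple[str, str]:
    prev = seq[start - 2] if start > 1 else "-"
    nxt = seq[end] if end < len(seq) else "-"
    return prev, nxt


def _plant_sequon(seq: str, start: int, end: int,
                  rng: np.random.Generator) -> str | None:
    """Overwrite residues inside [start, end] to create an N-X-T motif
    without touching K/R (so the digestion is unchanged)."""
    positions = list(range(start + 1, end - 2))  # keep peptide ends intact
    rng.shuffle(positions)
    for pos in positions:
        window = seq[pos - 1 : pos + 2]
        if any(aa in "KR" for aa in window):
            continue
        return seq[: pos - 1] + "N" + window[1] + "T" + seq[pos + 2 :]
    return None


def generate(cfg: GeneratorConfig | None = None) -> Bundle:
    """Generate a full in-memory dataset bundle from ``cfg``.

    Deterministic: the same config (including seed) reproduces the bundle
    exactly.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    probs = _residue_probs(cfg.kr_frequency)
    fam_lo, fam_hi = cfg.family_length_range

    # --- cohort -----------------------------------------------------------
    breweries = [chr(ord("A") + i) for i in range(cfg.n_breweries)]
    beers = []
    for bi, brewery in enumerate(breweries):
        scale = "multinational" if bi < cfg.n_multinational else "independent"
        for k in range(cfg.beers_per_brewery):
            style = cfg.styles[k % len(cfg.styles)]
            beers.append(
                {
                    "sample_id": f"{brewery}_{style}_{k + 1}",
                    "brewery": brewery,
                    "style": style,
                    "scale": scale,
                    "dark": style in cfg.dark_styles,
                }
            )
    metadata = pd.DataFrame(beers)
    beer_ids = metadata["sample_id"].tolist()

    # --- protein database -------------------------------------------------
    def make_accessions() -> list[tuple[str, Species]]:
        accs = []
        for i in range(cfg.n_barley_proteins):
            if i < cfg.n_nltp:
                name = f"NLTP{i + 1}S"
            elif i < cfg.n_nltp + cfg.n_serpin:
                name = f"SPZ{i + 1 - cfg.n_nltp}S"
            else:
                name = f"BARL{i + 1}"
            accs.append((name, Species.BARLEY))
        for i in range(cfg.n_yeast_proteins):
            if i < cfg.n_seripauperin:
                name = f"PAU{i + 1}S"
            else:
                name = f"YST{i + 1}"
            accs.append((name, Species.YEAST))
        for i in range(cfg.n_contaminants):
            accs.append((f"CONT{i + 1}", Species.CONTAMINANT))
        accs.append(("TRYP1", Species.TRYPSIN))
        return accs

    proteins: dict[str, ProteinRecord] = {}
    sequon_acc = None
    yeast_accs = []
    for acc, species in make_accessions():
        length = int(rng.integers(*cfg.protein_length))
        seq = _random_sequence(rng, length, probs)
        proteins[acc] = ProteinRecord(acc, species, seq)
        if species is Species.YEAST:
            yeast_accs.append(acc)

    # plant one sequon on the first yeast protein inside a usable peptide
    if cfg.sequon_event and yeast_accs:
        sequon_acc = yeast_accs[0]
        rec = proteins[sequon_acc]
        for loc in digest(rec, 0):
            if loc.length < max(fam_lo, 8) or loc.length > fam_hi:
                continue
            planted = _plant_sequon(rec.sequence, loc.start, loc.end, rng)
            if planted is not None:
                proteins[sequon_acc] = ProteinRecord(
                    sequon_acc, Species.YEAST, planted
                )
                break
        else:
            sequon_acc = None

    # --- families and member forms ---------------------------------------
    # each family: list of member dicts with keys
    #   peptide/prev/next/mods/kind ("unmod"|"glycation"|"o_glyc"|"n_glyc"|"clip")
    # and a per-family base share vector.
    families = []  # dicts: accession, family_id, members, base_shares
    sequon_done = False
    for acc, rec in proteins.items():
        if rec.species in (Species.CONTAMINANT, Species.TRYPSIN):
            continue
        anchors = [
            loc for loc in digest(rec, 0)
            if fam_lo <= loc.length <= fam_hi
            and _unique_with_flanks(rec.sequence, loc.start, loc.end)
        ]
        anchors = anchors[: cfg.max_families_per_protein]
        for loc in anchors:
            pep = loc.sequence_in(rec)
            members = [
                {"peptide": pep, "prev": loc.prev_aa, "next": loc.next_aa,
                 "mods": "unmodified", "kind": "unmod"}
            ]
            if rec.species is Species.BARLEY:
                for pos, aa in enumerate(pep, start=1):
                    if aa != "K" or rng.random() > cfg.glycation_site_prob:
                        continue
                    h = 1 + int(rng.choice(len(cfg.glycation_hex_weights),
                                           p=cfg.glycation_hex_weights))
                    members.append(
                        {"peptide": pep, "prev": loc.prev_aa,
                         "next": loc.next_aa, "mods": f"Hex({h})@K{pos}",
                         "kind": "glycation"}
                    )
                if rng.random() < cfg.clipping_family_prob and loc.length >= 8:
                    n_cuts = 1 + int(rng.integers(cfg.max_clip_sites))
                    cuts = rng.choice(
                        np.arange(4, loc.length - 1), size=min(
                            n_cuts, loc.length - 5), replace=False)
                    for cut in sorted(int(c) for c in cuts):
                        end = loc.start + cut - 1
                        if not _unique_with_flanks(rec.sequence, loc.start, end):
                            continue
                        prev, nxt = _flanks(rec.sequence, loc.start, end)
                        members.append(
                            {"peptide": rec.sequence[loc.start - 1 : end],
                             "prev": prev, "next": nxt,
                             "mods": "unmodified", "kind": "clip"}
                        )
            else:  # yeast
                for pos, aa in enumerate(pep, start=1):
                    if aa not in "ST" or rng.random() > cfg.oglyc_site_prob:
                        continue
                    h = 1 + int(rng.choice(len(cfg.oglyc_hex_weights),
                                           p=cfg.oglyc_hex_weights))
                    if rng.random() < cfg.undetermined_site_prob:
                        mods = f"Hex({h})@undetermined"
                    else:
                        mods = f"Hex({h})@{aa}{pos}"
                    members.append(
                        {"peptide": pep, "prev": loc.prev_aa,
                         "next": loc.next_aa, "mods": mods, "kind": "o_glyc"}
                    )
                if (not sequon_done and acc == sequon_acc):
                    npos = next(
                        (i + 1 for i in range(len(pep) - 2)
                         if pep[i] == "N" and pep[i + 2] in "ST"), None)
                    if npos is not None:
                        members.append(
                            {"peptide": pep, "prev": loc.prev_aa,
                             "next": loc.next_aa,
                             "mods": f"HexNAc(1)@N{npos}", "kind": "n_glyc"}
                        )
                        sequon_done = True
            # dedupe identical (peptide, flanks, mods)
            seen = set()
            unique_members = []
            for m in members:
                key = (m["peptide"], m["prev"], m["next"], m["mods"])
                if key not in seen:
                    seen.add(key)
                    unique_members.append(m)
            members = unique_members
            # base share vector: unmodified gets 1 - theta
            n_mod = len(members) - 1
            if n_mod:
                theta = rng.uniform(*cfg.occupancy_range)
                split = rng.dirichlet(np.ones(n_mod))
                shares = np.concatenate([[1 - theta], theta * split])
            else:
                shares = np.array([1.0])
            families.append(
                {
                    "accession": acc,
                    "family_id": f"{acc}:{loc.start}-{loc.end}",
                    "members": members,
                    "base_shares": shares,
                }
            )

    # per-protein family weights
    fam_by_protein: dict[str, list[int]] = {}
    for i, fam in enumerate(families):
        fam_by_protein.setdefault(fam["accession"], []).append(i)
    family_weight = np.zeros(len(families))
    for acc, idxs in fam_by_protein.items():
        family_weight[idxs] = rng.dirichlet(np.ones(len(idxs)))

    protein_has = {
        acc: {
            "glycation": any(
                m["kind"] == "glycation"
                for i in idxs for m in families[i]["members"]),
            "clip": any(
                m["kind"] == "clip"
                for i in idxs for m in families[i]["members"]),
        }
        for acc, idxs in fam_by_protein.items()
    }

    # --- abundance model --------------------------------------------------
    quant_accs = sorted(fam_by_protein)
    base_log10 = {
        acc: rng.normal(cfg.base_log10_abundance, cfg.base_log10_sd)
        for acc in quant_accs
    }
    brewery_eff = pd.DataFrame(
        rng.normal(0.0, cfg.brewery_sd, size=(len(quant_accs), len(breweries))),
        index=quant_accs, columns=breweries,
    )
    style_eff = pd.DataFrame(
        rng.normal(0.0, cfg.style_sd,
                   size=(len(quant_accs), len(set(cfg.styles)))),
        index=quant_accs, columns=sorted(set(cfg.styles)),
    )

    def protein_abundance_in(acc: str, beer: dict) -> float:
        log10 = (base_log10[acc]
                 + brewery_eff.at[acc, beer["brewery"]]
                 + style_eff.at[acc, beer["style"]])
        a = 10.0 ** log10
        if beer["dark"]:
            if protein_has[acc]["glycation"]:
                a *= cfg.dark_glycation_abundance_mult
            if protein_has[acc]["clip"]:
                a *= cfg.dark_clipped_abundance_mult
        return a

    # --- per-beer shares, intensities, truth ------------------------------
    kind_of = {"glycation": "glycation", "o_glyc": "glycosylation",
               "n_glyc": "glycosylation", "clip": "proteolysis"}
    sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
    rep_ids = [f"rep{r + 1}" for r in range(cfg.n_replicates)]

    quant_rows = []
    occ_rows = []
    protein_raw = {acc: {} for acc in quant_accs}
    for beer in beers:
        bid = beer["sample_id"]
        for fi, fam in enumerate(families):
            shares = fam["base_shares"].copy()
            if beer["dark"]:
                clip_mask = np.array(
                    [m["kind"] == "clip" for m in fam["members"]])
                if clip_mask.any():
                    shares[clip_mask] *= cfg.dark_clip_occupancy_mult
                    shares /= shares.sum()
            kinds_here = {kind_of[m["kind"]] for m in fam["members"]
                          if m["kind"] != "unmod"}
            for kind in sorted(kinds_here):
                occ = float(sum(
                    s for m, s in zip(fam["members"], shares)
                    if m["kind"] != "unmod" and kind_of[m["kind"]] == kind))
                occ_rows.append({"beer": bid, "family": fam["family_id"],
                                 "kind": kind, "occupancy": occ})
            abund = protein_abundance_in(fam["accession"], beer)
            fam_total = abund * family_weight[fi]
            protein_raw[fam["accession"]][bid] = (
                protein_raw[fam["accession"]].get(bid, 0.0) + fam_total)
            for m, s in zip(fam["members"], shares):
                base_intensity = fam_total * s
                if base_intensity < cfg.detection_limit:
                    continue  # below the XIC detection floor: not emitted
                for rep in rep_ids:
                    if cfg.replicate_cv > 0:
                        mult = float(np.exp(
                            rng.normal(-sigma * sigma / 2.0, sigma)))
                    else:
                        mult = 1.0
                    if rng.random() < cfg.fdr_fail_rate:
                        fdr = float(rng.uniform(cfg.fdr_cutoff * 1.1, 0.2))
                    else:
                        fdr = float(rng.uniform(1e-4, cfg.fdr_cutoff * 0.9))
                    quant_rows.append(
                        {"sample_id": bid, "replicate": rep,
                         "accession": fam["accession"],
                         "peptide": m["peptide"], "prev_aa": m["prev"],
                         "next_aa": m["next"], "mods": m["mods"],
                         "intensity": base_intensity * mult, "fdr": fdr}
                    )

    # trypsin self-digest and contaminant peptides
    for acc, rec in proteins.items():
        if rec.species not in (Species.CONTAMINANT, Species.TRYPSIN):
            continue
        peps = [
            loc for loc in digest(rec, 0)
            if fam_lo <= loc.length <= fam_hi
            and _unique_with_flanks(rec.sequence, loc.start, loc.end)
        ][:3]
        if rec.species is Species.TRYPSIN:
            base = cfg.trypsin_peptide_intensity
        else:
            base = 10.0 ** cfg.contaminant_log10_abundance
        for beer in beers:
            for loc in peps:
                for rep in rep_ids:
                    mult = (float(np.exp(rng.normal(-sigma * sigma / 2, sigma)))
                            if cfg.replicate_cv > 0 else 1.0)
                    quant_rows.append(
                        {"sample_id": beer["sample_id"], "replicate": rep,
                         "accession": acc,
                         "peptide": loc.sequence_in(rec),
                         "prev_aa": loc.prev_aa, "next_aa": loc.next_aa,
                         "mods": "unmodified",
                         "intensity": base * mult,
                         "fdr": float(rng.uniform(1e-4,
                                                  cfg.fdr_cutoff * 0.9))}
                    )

    # decoy rows: non-tryptic interior fragments failing the FDR cutoff
    decoy_ids = []
    barley_accs = [a for a, r in proteins.items()
                   if r.species is Species.BARLEY]
    attempts = 0
    while len(decoy_ids) < cfg.n_decoys and attempts < cfg.n_decoys * 20 + 20:
        attempts += 1
        acc = barley_accs[int(rng.integers(len(barley_accs)))]
        seq = proteins[acc].sequence
        start = int(rng.integers(3, len(seq) - 14))
        end = start + int(rng.integers(8, 14))
        if seq[start - 2] in "KR" or seq[end - 1] in "KR":
            continue  # keep it non-tryptic
        if not _unique_with_flanks(seq, start, end):
            continue
        prev, nxt = _flanks(seq, start, end)
        pep = seq[start - 1 : end]
        fid = f"{acc}:{start}-{end}|non_tryptic|unmodified"
        if fid in decoy_ids:
            continue
        decoy_ids.append(fid)
        for beer in beers:
            for rep in rep_ids:
                quant_rows.append(
                    {"sample_id": beer["sample_id"], "replicate": rep,
                     "accession": acc, "peptide": pep,
                     "prev_aa": prev, "next_aa": nxt, "mods": "unmodified",
                     "intensity": float(rng.uniform(1e2, 1e4)),
                     "fdr": float(rng.uniform(cfg.fdr_cutoff * 2, 0.5))}
                )

    quant = pd.DataFrame(quant_rows)

    # --- truth tables -----------------------------------------------------
    occupancy = pd.DataFrame(occ_rows)
    raw_df = pd.DataFrame(protein_raw).T  # accession x beer
    norm = raw_df / raw_df.sum(axis=0)
    protein_norm = (
        norm.reset_index(names="accession")
        .melt(id_vars="accession", var_name="beer",
              value_name="norm_total_true")
        .sort_values(["accession", "beer"], ignore_index=True)
    )

    # --- foam -------------------------------------------------------------
    class_map = {}
    for acc in quant_accs:
        if acc.startswith("NLTP"):
            class_map[acc] = "NLTP"
        elif acc.startswith("SPZ"):
            class_map[acc] = "serpin"
        elif acc.startswith("PAU"):
            class_map[acc] = "seripauperin"
    class_sums = pd.DataFrame(0.0, index=beer_ids,
                              columns=sorted({*class_map.values()}))
    for acc, cls in class_map.items():
        class_sums[cls] += norm.loc[acc].reindex(beer_ids).values

    coupled = {f for f, *_ in cfg.foam_couplings}
    foam_model = {}
    foam = pd.DataFrame(index=beer_ids)
    foam.index.name = "sample_id"
    for fieldname, base, sd in cfg.foam_baselines:
        if fieldname in coupled:
            continue
        vals = base + rng.normal(0.0, sd, size=len(beer_ids))
        foam[fieldname] = np.maximum(vals, 0.0)
        foam_model[fieldname] = {"kind": "baseline", "base": base, "sd": sd}
    for fieldname, cls, slope, intercept, target_r2 in cfg.foam_couplings:
        x = class_sums[cls].to_numpy()
        xc = x - x.mean()
        var_signal = slope * slope * float(np.var(x))
        if 0 < target_r2 < 1 and var_signal > 0:
            noise_sd = float(np.sqrt(var_signal * (1 - target_r2) / target_r2))
        else:
            noise_sd = 0.0
        vals = intercept + slope * xc + rng.normal(0.0, noise_sd,
                                                   size=len(beer_ids))
        foam[fieldname] = np.maximum(vals, 0.0)
        foam_model[fieldname] = {
            "kind": "coupled", "class": cls, "slope": slope,
            "intercept": intercept, "target_r2": target_r2,
            "noise_sd": noise_sd,
        }
    foam = foam.reset_index()

    truth = GroundTruth(
        seed=cfg.seed,
        occupancy=occupancy,
        protein_norm=protein_norm,
        brewery_effects=brewery_eff,
        foam_model=foam_model,
        decoy_form_ids=decoy_ids,
        class_map=class_map,
    )
    return Bundle(config=cfg, proteins=proteins, quant=quant,
                  metadata=metadata, foam=foam, truth=truth)


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as deterministic plain-text files.

    Returns the paths: fasta, quant, metadata, foam, truth (JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "quant": outdir / "quant.tsv",
        "metadata": outdir / "metadata.tsv",
        "foam": outdir / "foam.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for acc, rec in bundle.proteins.items():
            fh.write(f">{acc} species={rec.species.value}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    kw = dict(sep="\t", index=False, float_format="%.8g", lineterminator="\n")
    bundle.quant.to_csv(paths["quant"], **kw)
    bundle.metadata.to_csv(paths["metadata"], **kw)
    bundle.foam.to_csv(paths["foam"], **kw)
    truth = bundle.truth
    payload = {
        "seed": truth.seed,
        "occupancy": truth.occupancy.to_dict(orient="records"),
        "protein_norm": truth.protein_norm.to_dict(orient="records"),
        "brewery_effects": truth.brewery_effects.round(10).to_dict(),
        "foam_model": truth.foam_model,
        "decoy_form_ids": truth.decoy_form_ids,
        "class_map": truth.class_map,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(bundle.config).items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return paths


def truth_check(
    bundle: Bundle,
    occupancy_summaries: pd.DataFrame,
    protein_abundance_tidy: pd.DataFrame,
    per_family_occupancy: pd.DataFrame | None = None,
    regression_table: pd.DataFrame | None = None,
    seed: int | None = None,
) -> dict:
    """Recovery report: estimates vs. the bundle's planted truth.

    ``occupancy_summaries`` is the concatenation of per-kind frames from
    :func:`brewptm.quant_normalize.occupancy_summary`;
    ``protein_abundance_tidy`` is the mode="total" frame from
    :func:`brewptm.quant_normalize.protein_abundance`.
    """
    if seed is not None and seed != bundle.truth.seed:
        raise ValueError(
            f"seed mismatch: results seed {seed} != bundle seed "
            f"{bundle.truth.seed}"
        )
    report: dict = {"seed": bundle.truth.seed}

    # average occupancy per (beer, kind): truth vs estimate
    truth_avg = (
        bundle.truth.occupancy.groupby(["beer", "kind"])["occupancy"]
        .mean().rename("truth")
    )
    est = occupancy_summaries.set_index(["sample_id", "kind"])["average"]
    est.index.names = ["beer", "kind"]
    joined = pd.concat([truth_avg, est.rename("est")], axis=1).dropna()
    err = joined["est"] - joined["truth"]
    report["avg_occupancy_bias"] = float(err.mean())
    report["avg_occupancy_rmse"] = float(np.sqrt((err**2).mean()))
    report["n_occupancy_cells"] = int(len(joined))

    if per_family_occupancy is not None:
        t = bundle.truth.occupancy.set_index(["beer", "family", "kind"])[
            "occupancy"]
        e = per_family_occupancy.set_index(["beer", "family", "kind"])[
            "occupancy"]
        j = pd.concat([t.rename("truth"), e.rename("est")], axis=1).dropna()
        d = j["est"] - j["truth"]
        report["family_occupancy_rmse"] = float(np.sqrt((d**2).mean()))
        report["n_family_cells"] = int(len(j))

    # protein abundance recovery (Pearson r on log10 of norm_total)
    t = bundle.truth.protein_norm.set_index(["accession", "beer"])[
        "norm_total_true"]
    e = protein_abundance_tidy.set_index(["accession", "sample_id"])["norm"]
    e.index.names = ["accession", "beer"]
    j = pd.concat([t.rename("truth"), e.rename("est")], axis=1).dropna()
    j = j[(j > 0).all(axis=1)]
    report["protein_log10_pearson_r"] = float(
        np.corrcoef(np.log10(j["truth"]), np.log10(j["est"]))[0, 1]
    )

    # dark-beer rule recovery: rank of dark styles
    meta = bundle.metadata.set_index("sample_id")
    occ = occupancy_summaries.copy()
    occ["dark"] = occ["sample_id"].map(meta["dark"])
    ranks = {}
    for kind, col in (("glycation", "total"), ("proteolysis", "average")):
        sub = occ[occ["kind"] == kind]
        if len(sub) and sub["dark"].nunique() == 2:
            ranks[kind] = {
                "dark_mean": float(sub.loc[sub["dark"], col].mean()),
                "light_mean": float(sub.loc[~sub["dark"], col].mean()),
            }
    report["dark_rule"] = ranks

    # foam slope recovery
    if regression_table is not None:
        rec = {}
        for fieldname, model in bundle.truth.foam_model.items():
            if model.get("kind") != "coupled":
                continue
            row = regression_table[
                (regression_table["foam_field"] == fieldname)
                & (regression_table["protein_class"] == model["class"])
            ]
            if len(row):
                rec[fieldname] = {
                    "planted_slope": model["slope"],
                    "estimated_slope": float(row["slope"].iloc[0]),
                    "planted_target_r2": model["target_r2"],
                    "estimated_r2": float(row["r2"].iloc[0]),
                    "sign_recovered": bool(
                        np.sign(row["slope"].iloc[0]) == np.sign(model["slope"])
                    ),
                }
        report["foam_recovery"] = rec
    return report
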