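"""FDR refiltering, replicate collapse, within-family proportions and
occupancy, and protein-level abundance with two normalization modes.

Data layout
-----------
A :class:`QuantDataset` bundles two pandas DataFrames:

``forms``
    One row per peptide form, indexed by a stable ``form_id`` string, with
    columns: accession, species, peptide, start, end, cleavage, mod_kind,
    hex, hexnac, site, family (``""`` when unassignable).

``data``
    Long table with columns form_id, sample_id, replicate, intensity, fdr.
    Missing intensities are NaN and are distinct from zero: missing means
    no XIC detection and contributes 0 to family denominators and protein
    sums, while a family is "detected" in a sample only if its total is
    strictly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ptm_model import FormError, ModKind, PeptideForm, family_key, parse_form
from .seqdigest import CleavageClass, ProteinRecord, Species

logger = logging.getLogger(__name__)

__all__ = [
    "QuantDataset",
    "PTM_KINDS",
    "build_dataset",
    "fdr_filter",
    "collapse_replicates",
    "family_normalize",
    "family_normalize_per_replicate",
    "family_occupancy",
    "occupancy_summary",
    "protein_abundance",
]

#: PTM kinds summarized by occupancy_summary.
PTM_KINDS = ("glycosylation", "glycation", "proteolysis")

_KIND_COLS = {
    "glycosylation": (ModKind.O_GLYC_HEX.value, ModKind.N_GLYC.value),
    "glycation": (ModKind.GLYCATION_HEX.value,),
}

FORM_COLUMNS = [
    "accession", "species", "peptide", "start", "end",
    "cleavage", "mod_kind", "hex", "hexnac", "site", "family",
]


def _form_id(form: PeptideForm) -> str:
    loc = form.location
    parts = [f"{loc.accession}:{loc.start}-{loc.end}", form.cleavage.value]
    if form.mods:
        m = form.mods[0]
        site = "?" if m.site is None else str(m.site)
        parts.append(f"{m.composition}@{site}")
    else:
        parts.append("unmodified")
    return "|".join(parts)


@dataclass
class QuantDataset:
    forms: pd.DataFrame
    data: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def n_rejected(self) -> int:
        return len(self.rejects)


def build_dataset(
    quant: pd.DataFrame,
    db: Mapping[str, ProteinRecord],
    max_missed: int = 2,
    cleave_before_proline: bool = True,
) -> QuantDataset:
    """Parse a long quant table into a validated QuantDataset.

    Rows that cannot be located, violate the modification grammar, or are
    ambiguous are rejected with a logged reason. Forms differing only in
    common modifications (deamidation/oxidation) are summed into one form;
    their fdr is the minimum over the merged rows.
    """
    required = {"sample_id", "replicate", "accession", "peptide",
                "prev_aa", "next_aa", "mods", "intensity", "fdr"}
    missing_cols = required - set(quant.columns)
    if missing_cols:
        raise ValueError(f"quant table missing columns {sorted(missing_cols)}")

    form_meta: dict[str, dict] = {}
    form_cache: dict[tuple, tuple[str, PeptideForm] | None] = {}
    rows = []
    rejects = []
    for idx, row in enumerate(quant.itertuples(index=False)):
        key = (row.accession, row.peptide, row.prev_aa, row.next_aa, row.mods)
        if key not in form_cache:
            try:
                form = parse_form(
                    {
                        "accession": row.accession,
                        "peptide": row.peptide,
                        "prev_aa": row.prev_aa,
                        "next_aa": row.next_aa,
                        "mods": row.mods,
                    },
                    db,
                    cleave_before_proline,
                )
                form_cache[key] = (_form_id(form), form)
            except (FormError, KeyError, ValueError) as exc:
                form_cache[key] = None
                logger.warning("rejecting row %d: %s", idx, exc)
        cached = form_cache[key]
        if cached is None:
            rejects.append({"row": idx, "reason": "unparseable/invalid form"})
            continue
        fid, form = cached
        if fid not in form_meta:
            loc = form.location
            protein = db[loc.accession]
            m = form.mods[0] if form.mods else None
            fam = family_key(form, db, max_missed, cleave_before_proline)
            if fam is None:
                logger.warning("form %s: no full-tryptic anchor within "
                               "%d missed cleavages", fid, max_missed)
            form_meta[fid] = {
                "accession": loc.accession,
                "species": protein.species.value,
                "peptide": loc.sequence_in(protein),
                "start": loc.start,
                "end": loc.end,
                "cleavage": form.cleavage.value,
                "mod_kind": m.kind.value if m else "",
                "hex": m.hex if m else 0,
                "hexnac": m.hexnac if m else 0,
                "site": (m.site if m and m.site is not None else -1),
                "family": str(fam) if fam is not None else "",
            }
        rows.append(
            {
                "form_id": fid,
                "sample_id": str(row.sample_id),
                "replicate": str(row.replicate),
                "intensity": float(row.intensity),
                "fdr": float(row.fdr),
            }
        )

    data = pd.DataFrame(rows, columns=["form_id", "sample_id", "replicate",
                                       "intensity", "fdr"])
    if len(data):
        # collapse common-mod variants: same form_id, sample, replicate
        data = (
            data.groupby(["form_id", "sample_id", "replicate"], as_index=False)
            .agg(intensity=("intensity", "sum"), fdr=("fdr", "min"))
        )
    forms = pd.DataFrame.from_dict(form_meta, orient="index",
                                   columns=FORM_COLUMNS)
    forms.index.name = "form_id"
    return QuantDataset(
        forms=forms.sort_index(),
        data=data.sort_values(["form_id", "sample_id", "replicate"],
                              ignore_index=True),
        rejects=pd.DataFrame(rejects, columns=["row", "reason"]),
    )


def fdr_filter(
    data: pd.DataFrame, cutoff: float = 0.01
) -> tuple[pd.DataFrame, int]:
    """Blank (set to NaN) intensities whose fdr exceeds ``cutoff``.

    Returns the filtered copy and the number of entries removed.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    out = data.copy()
    fail = (out["fdr"] > cutoff) & out["intensity"].notna()
    out.loc[fail, "intensity"] = np.nan
    n = int(fail.sum())
    if n:
        logger.info("fdr_filter: removed %d / %d entries at cutoff %g",
                    n, len(out), cutoff)
    return out, n


def collapse_replicates(
    data: pd.DataFrame, method: str = "mean"
) -> pd.DataFrame:
    """Collapse technical replicates to one value per (form, sample).

    Returns a wide matrix (form_id x sample_id). The collapse ignores
    missing replicates; a cell is NaN only when every replicate is missing.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown collapse method {method!r}")
    wide = data.pivot_table(
        index="form_id", columns="sample_id", values="intensity",
        aggfunc=method, dropna=False,
    )
    wide.columns.name = None
    return wide.sort_index()


def family_normalize(
    per_sample: pd.DataFrame, forms: pd.DataFrame
) -> pd.DataFrame:
    """Compute within-family proportions per sample.

    ``per_sample`` is the form x sample matrix from collapse_replicates.
    Returns a tidy frame with columns family, form_id, sample_id,
    proportion, family_total. Missing intensities count 0 in the family
    denominator; families whose total is 0 in a sample get NaN proportions
    (undefined, excluded from downstream averages).
    """
    fam = forms.loc[forms["family"] != "", "family"]
    mat = per_sample.reindex(fam.index).fillna(0.0)
    mat.insert(0, "family", fam)
    long = mat.melt(id_vars="family", var_name="sample_id",
                    value_name="intensity", ignore_index=False)
    long.index.name = "form_id"
    long = long.reset_index()
    totals = long.groupby(["family", "sample_id"])["intensity"].transform("sum")
    long["family_total"] = totals
    with np.errstate(invalid="ignore", divide="ignore"):
        long["proportion"] = np.where(
            totals > 0, long["intensity"] / totals, np.nan
        )
    return long[["family", "form_id", "sample_id", "proportion",
                 "family_total"]].sort_values(
        ["family", "form_id", "sample_id"], ignore_index=True)


def family_normalize_per_replicate(
    data: pd.DataFrame, forms: pd.DataFrame, method: str = "mean"
) -> pd.DataFrame:
    """Alternative order: normalize within family per replicate, then
    collapse the proportions across replicates.

    The default pipeline collapses intensities first (ratio statistics are
    unstable across sparse replicates); this variant exists for
    sensitivity analysis. Output columns match :func:`family_normalize`,
    with family_total the across-replicate mean of the replicate totals.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown collapse method {method!r}")
    frames = []
    for rep, sub in data.groupby("replicate"):
        wide = sub.pivot_table(
            index="form_id", columns="sample_id", values="intensity",
            aggfunc="first", dropna=False,
        )
        wide.columns.name = None
        frames.append(family_normalize(wide, forms))
    merged = pd.concat(frames, ignore_index=True)
    out = (
        merged.groupby(["family", "form_id", "sample_id"], as_index=False)
        .agg(proportion=("proportion", method),
             family_total=("family_total", "mean"))
    )
    return out.sort_values(["family", "form_id", "sample_id"],
                           ignore_index=True)


def _is_modified(forms: pd.DataFrame, kind: str) -> pd.Series:
    if kind == "proteolysis":
        return forms["cleavage"] != CleavageClass.FULL_TRYPTIC.value
    if kind in _KIND_COLS:
        return forms["mod_kind"].isin(_KIND_COLS[kind])
    raise ValueError(f"unknown PTM kind {kind!r}; expected one of {PTM_KINDS}")


def family_occupancy(
    family_table: pd.DataFrame, forms: pd.DataFrame, kind: str
) -> pd.DataFrame:
    """Per (sample, family) occupancy for one PTM kind.

    Occupancy is the summed proportion of modified members (for
    proteolysis: members that are not full-tryptic). Only families that
    contain at least one member of the kind anywhere are eligible;
    family-sample cells with undefined proportions are excluded.
    """
    modified = _is_modified(forms, kind)
    eligible = set(forms.loc[modified & (forms["family"] != ""), "family"])
    if not eligible:
        return pd.DataFrame(
            columns=["sample_id", "family", "occupancy", "family_total"]
        )
    sub = family_table[family_table["family"].isin(eligible)].copy()
    sub = sub[sub["proportion"].notna()]
    sub["mod_prop"] = np.where(
        sub["form_id"].map(modified).fillna(False), sub["proportion"], 0.0
    )
    per_family = sub.groupby(["sample_id", "family"]).agg(
        occupancy=("mod_prop", "sum"),
        family_total=("family_total", "first"),
    )
    return per_family.reset_index()


def occupancy_summary(
    family_table: pd.DataFrame,
    forms: pd.DataFrame,
    kind: str,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-sample total and average occupancy for one PTM kind.

    ``total`` is the unweighted sum of per-family occupancies
    (intensity-weighted by family_total when ``weighted``); ``average``
    is their mean over families detected in the sample.
    """
    per_family = family_occupancy(family_table, forms, kind)
    if not len(per_family):
        logger.warning("occupancy_summary: no eligible families for %s", kind)
        return pd.DataFrame(
            columns=["sample_id", "kind", "total", "average", "n_families"]
        )
    per_family = per_family.set_index(["sample_id", "family"])
    def _agg(g: pd.DataFrame) -> pd.Series:
        if weighted:
            total = float((g["occupancy"] * g["family_total"]).sum()
                          / g["family_total"].sum())
        else:
            total = float(g["occupancy"].sum())
        return pd.Series({
            "total": total,
            "average": float(g["occupancy"].mean()),
            "n_families": int(len(g)),
        })
    out = per_family.groupby("sample_id").apply(_agg, include_groups=False)
    out = out.reset_index()
    out.insert(1, "kind", kind)
    out["n_families"] = out["n_families"].astype(int)
    return out


def protein_abundance(
    per_sample: pd.DataFrame,
    forms: pd.DataFrame,
    mode: str = "total",
    exclude_from_denominator: Iterable[str] = (
        Species.CONTAMINANT.value, Species.TRYPSIN.value,
    ),
) -> pd.DataFrame:
    """Protein abundance as the sum of all retained peptide forms.

    Returns a tidy frame (accession, species, sample_id, raw_sum, norm,
    log10_norm). ``mode="total"`` divides by the summed abundance of all
    proteins in the sample excluding ``exclude_from_denominator`` species;
    ``mode="trypsin"`` divides by the summed intensity of trypsin
    self-digest peptides (error if a sample has none). log10 is taken only
    on strictly positive normalized values (NaN otherwise; no pseudocount).
    """
    if mode not in ("total", "trypsin"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    excl = set(exclude_from_denominator)
    mat = per_sample.fillna(0.0)
    meta = forms.loc[mat.index]
    raw = mat.groupby(meta["accession"]).sum()
    species_of = forms.drop_duplicates("accession").set_index("accession")["species"]
    raw_species = raw.index.map(species_of)

    if mode == "total":
        keep = ~raw_species.isin(excl)
        raw, raw_species = raw.loc[keep], raw_species[keep]
        denom = raw.sum(axis=0)
        bad = denom[denom <= 0]
        if len(bad):
            raise ValueError(
                f"zero total protein abundance in samples {list(bad.index)}"
            )
    else:
        tryp_forms = meta["species"] == Species.TRYPSIN.value
        if not tryp_forms.any():
            raise ValueError("trypsin mode: no trypsin-tagged forms in dataset")
        denom = mat.loc[tryp_forms.values].sum(axis=0)
        bad = denom[denom <= 0]
        if len(bad):
            raise ValueError(
                f"trypsin mode: zero trypsin signal in samples {list(bad.index)}"
            )
    norm = raw.div(denom, axis=1)
    tidy = norm.reset_index().melt(
        id_vars="accession", var_name="sample_id", value_name="norm"
    )
    raw_tidy = raw.reset_index().melt(
        id_vars="accession", var_name="sample_id", value_name="raw_sum"
    )
    tidy = raw_tidy.merge(tidy, on=["accession", "sample_id"])
    tidy.insert(1, "species", tidy["accession"].map(species_of))
    with np.errstate(divide="ignore"):
        tidy["log10_norm"] = np.where(
            tidy["norm"] > 0, np.log10(tidy["norm"].where(tidy["norm"] > 0)),
            np.nan,
        )
    return tidy.sort_values(["accession", "sample_id"], ignore_index=True)
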