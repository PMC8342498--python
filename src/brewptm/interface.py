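"""End-to-end pipeline orchestration, configuration, and provenance."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .multivariate import explained_variance_percent, hcluster, pca, to_newick
from .quant_normalize import (
    PTM_KINDS,
    build_dataset,
    collapse_replicates,
    family_normalize,
    fdr_filter,
    occupancy_summary,
    protein_abundance,
)
from .seqdigest import read_fasta
from .stats_compare import (
    class_abundance,
    default_class_map,
    foam_regression_table,
    volcano,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_inputs"]

_CSV_KW = dict(sep="\t", index=False, float_format="%.10g",
               lineterminator="\n")


@dataclass
class PipelineConfig:
    fasta: str = ""
    quant: str = ""
    metadata: str = ""
    foam: str = ""               # optional
    outdir: str = "results"
    fdr_cutoff: float = 0.01     # peptide FDR refilter, 1%
    max_missed: int = 2          # missed cleavages for family anchors
    normalization: str = "total" # "total" | "trypsin"
    collapse: str = "mean"       # replicate collapse
    alpha: float = 0.05
    n_components: int = 2
    cluster_axes: tuple = ("cols",)
    group_column: str = "scale"
    group_order: tuple = ("independent", "multinational")
    cleave_before_proline: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cluster_axes", "group_order"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_inputs(cfg: PipelineConfig):
    db = read_fasta(cfg.fasta)
    quant = pd.read_csv(cfg.quant, sep="\t", dtype={
        "sample_id": str, "replicate": str, "mods": str})
    metadata = pd.read_csv(cfg.metadata, sep="\t", dtype={"sample_id": str})
    foam = None
    if cfg.foam:
        foam = pd.read_csv(cfg.foam, sep="\t", dtype={"sample_id": str})
    known = set(metadata["sample_id"])
    offenders = sorted(set(quant["sample_id"].astype(str)) - known)
    if offenders:
        raise ValueError(
            f"quant table references samples absent from metadata: {offenders}"
        )
    return db, quant, metadata, foam


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run parse -> FDR filter -> collapse -> family normalize -> occupancy
    -> protein abundance -> PCA/clustering -> volcano -> foam regression,
    writing every table plus a provenance JSON to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db, quant, metadata, foam = load_inputs(cfg)

    ds = build_dataset(quant, db, cfg.max_missed, cfg.cleave_before_proline)
    if not len(ds.data):
        raise ValueError("no parseable quant rows")
    filtered, n_removed = fdr_filter(ds.data, cfg.fdr_cutoff)
    per_sample = collapse_replicates(filtered, cfg.collapse)
    if not np.isfinite(per_sample.to_numpy(dtype=float)).any():
        raise ValueError("empty matrix after FDR filtering")

    famtab = family_normalize(per_sample, ds.forms)
    occ = pd.concat(
        [occupancy_summary(famtab, ds.forms, kind) for kind in PTM_KINDS],
        ignore_index=True,
    )
    pa = protein_abundance(per_sample, ds.forms, mode=cfg.normalization)

    outputs: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, **_CSV_KW)
        outputs[name] = path

    save("family_proportions", famtab)
    save("occupancy", occ)
    save("protein_abundance", pa)

    # feature matrix: log10 normalized protein abundance, proteins x samples
    mat = pa.pivot(index="accession", columns="sample_id",
                   values="log10_norm")
    mat = mat.dropna(how="all")
    scores, loadings, evr = pca(mat, cfg.n_components)
    save("pca_scores", scores.reset_index(names="sample_id"))
    save("pca_loadings", loadings.reset_index(names="accession"))

    newicks = {}
    for axis in cfg.cluster_axes:
        filled = mat.fillna(mat.min(axis=1).min())
        root, _ = hcluster(filled, axis=axis)
        path = outdir / f"dendrogram_{axis}.nwk"
        path.write_text(to_newick(root) + "\n")
        outputs[f"dendrogram_{axis}"] = path
        newicks[axis] = str(path)

    # group contrast (volcano) on log2 abundance
    contrast_info = None
    meta = metadata.set_index("sample_id")
    if cfg.group_column in meta.columns:
        labels = meta[cfg.group_column].astype(str)
        counts = labels[labels.index.isin(mat.columns)].value_counts()
        g1, g2 = cfg.group_order
        if counts.get(g1, 0) >= 2 and counts.get(g2, 0) >= 2:
            log2mat = mat * np.log2(10.0)
            contrast = volcano(log2mat, labels, (g1, g2), cfg.alpha)
            save("volcano", contrast)
            contrast_info = {"groups": [g1, g2],
                             "n": {g1: int(counts[g1]), g2: int(counts[g2])}}
        else:
            logger.warning("skipping volcano: need >=2 samples per group")

    # foam regressions
    if foam is not None:
        class_map = default_class_map(pa["accession"].unique())
        sums = class_abundance(pa, class_map)
        reg = foam_regression_table(sums, foam.set_index("sample_id"))
        save("class_abundance", sums.reset_index())
        save("foam_regression", reg)

    provenance = {
        "tool": "brewptm",
        "version": __version__,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "n_quant_rows": int(len(quant)),
        "n_rejected_rows": ds.n_rejected(),
        "n_fdr_removed": n_removed,
        "n_forms": int(len(ds.forms)),
        "n_unassigned_forms": int((ds.forms["family"] == "").sum()),
        "samples": sorted(map(str, per_sample.columns)),
        "explained_variance_percent": explained_variance_percent(evr),
        "dendrograms": newicks,
        "volcano": contrast_info,
        "notes": [
            "differential test: Welch t per feature + Benjamini-Hochberg "
            "across features; technical replicates collapsed to per-beer "
            "means before testing",
        ],
    }
    prov_path = outdir / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    outputs["provenance"] = prov_path
    return outputs
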