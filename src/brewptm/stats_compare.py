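"""Group-wise differential abundance and foam-property regressions.

Design notes: the differential test is a two-sided Welch (unequal
variance) t-test per feature with Benjamini-Hochberg adjustment across
features, with technical replicates collapsed to per-beer means upstream
(beers, not injections, are the experimental unit). The log2 fold change
is first-named group minus second-named group, so a positive value means
higher in the first group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "volcano",
    "class_abundance",
    "foam_regression",
    "FOAM_FIELDS",
]

FOAM_FIELDS = (
    "max_foam_volume",
    "foam_lifetime",
    "drainage",
    "bubbles_small",
    "bubbles_medium",
    "bubbles_large",
)


def volcano(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    group_order: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Welch t-test between two sample groups.

    ``matrix`` is features x samples on a log2 scale; ``labels`` maps
    sample id -> group. Returns a frame with columns feature, log2fc,
    p, p_adj, significant, tested. Features with no observed value in an
    entire group are excluded from testing but retained with NaN p.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    g1, g2 = group_order
    s1 = [s for s in matrix.columns if labels.get(s) == g1]
    s2 = [s for s in matrix.columns if labels.get(s) == g2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {g1}:{len(s1)} {g2}:{len(s2)}"
        )
    a = matrix[s1].to_numpy(dtype=float)
    b = matrix[s2].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    p = np.full(len(matrix), np.nan)
    if testable.any():
        t_res = stats.ttest_ind(
            a[testable], b[testable], axis=1, equal_var=False,
            nan_policy="omit",
        )
        p[testable] = t_res.pvalue
    p_adj = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        p_adj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "feature": matrix.index.astype(str),
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "significant": (p_adj <= alpha) & tested,
            "tested": tested,
        }
    )
    return out


def class_abundance(
    protein_abundance: pd.DataFrame,
    class_map: Mapping[str, str],
) -> pd.DataFrame:
    """Summed normalized abundance per (sample, protein class).

    ``protein_abundance`` is the tidy frame from
    :func:`brewptm.quant_normalize.protein_abundance` (columns accession,
    sample_id, norm). Accessions absent from ``class_map`` are ignored;
    a class with no detected member sums to 0.
    """
    pa = protein_abundance.copy()
    pa["cls"] = pa["accession"].map(dict(class_map))
    pa = pa[pa["cls"].notna()]
    classes = sorted(set(class_map.values()))
    samples = sorted(protein_abundance["sample_id"].unique())
    out = (
        pa.groupby(["sample_id", "cls"])["norm"].sum()
        .unstack("cls")
        .reindex(index=samples, columns=classes)
        .fillna(0.0)
    )
    out.index.name = "sample_id"
    return out


def default_class_map(
    accessions: Sequence[str],
    keywords: Mapping[str, str] = {
        "NLTP": "NLTP", "SERPIN": "serpin", "SPZ": "serpin",
        "PAU": "seripauperin", "SRP": "seripauperin",
    },
) -> dict[str, str]:
    """Header-keyword class assignment (first matching keyword wins)."""
    out = {}
    for acc in accessions:
        up = acc.upper()
        for kw, cls in keywords.items():
            if kw in up:
                out[acc] = cls
                break
    return out


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n >= 2 and not (np.isnan(self.r2) or 0 <= self.r2 <= 1 + 1e-12):
            raise ValueError(f"R^2 out of [0,1]: {self.r2}")


def foam_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of a foam variable on a class abundance.

    Inputs are per-beer means. Returns slope, intercept, R^2 and the
    two-sided p-value for the slope. Pairs with a missing value are
    dropped; requires >= 3 complete pairs and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=n,
    )


def foam_regression_table(
    class_sums: pd.DataFrame, foam: pd.DataFrame
) -> pd.DataFrame:
    """All (protein class x foam field) regressions as a tidy frame.

    ``foam`` is indexed by sample/beer id with FOAM_FIELDS columns;
    ``class_sums`` comes from :func:`class_abundance`.
    """
    common = class_sums.index.intersection(foam.index)
    rows = []
    for cls in class_sums.columns:
        x = class_sums.loc[common, cls]
        for fieldname in FOAM_FIELDS:
            if fieldname not in foam.columns:
                continue
            y = foam.loc[common, fieldname]
            try:
                r = foam_regression(x, y)
            except ValueError:
                continue
            rows.append(
                {
                    "protein_class": cls,
                    "foam_field": fieldname,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "r2": r.r2,
                    "p": r.p,
                    "n": r.n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["protein_class", "foam_field", "slope", "intercept",
                 "r2", "p", "n"],
    )
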