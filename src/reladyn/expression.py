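"""Expression-profile pipeline for the TNFα/RELA response.

Count matrices (genes x samples, with TNFα dose, treatment duration and
IκB-super-repressor status per sample) are filtered (<10 total counts
removed before statistics; any-zero genes flagged as excluded from
results), normalised with median-of-ratios size factors, log2-transformed
relative to the matched no-TNFα/no-super-repressor control per cell line
and timepoint, z-scored per gene across samples, and hierarchically
clustered into k response profiles (default 7) with per-cluster mean
profiles and 95% confidence ribbons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "FilterReport",
    "GeneClusterAssignment",
    "filter_genes",
    "size_factor_normalize",
    "size_factors",
    "relative_log_transform",
    "zscore_genes",
    "cluster_genes",
    "cluster_summary",
]


@dataclass
class FilterReport:
    removed_low_total: list[str]      # total < 10: dropped before statistics
    excluded_any_zero: list[str]      # some zero count: kept, excluded from results


@dataclass
class GeneClusterAssignment:
    labels: pd.Series                 # gene -> cluster id (1..k)
    k: int
    distance: str = "1 - pearson"
    linkage_method: str = "complete"
    linkage: np.ndarray | None = None

    @property
    def clusters(self) -> dict[int, list[str]]:
        return {int(c): sorted(idx) for c, idx in self.labels.groupby(self.labels).groups.items()}


# ---------------------------------------------------------------------------

def _check_counts(counts: pd.DataFrame) -> None:
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers")


def filter_genes(counts: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Two-stage gene filter.

    Stage 1 removes genes whose total over all samples is below 10 before
    any statistics.  Stage 2 flags (but retains) genes with a zero count in
    any sample; these are excluded from downstream results that require
    strictly positive normalised counts.
    """
    _check_counts(counts)
    totals = counts.sum(axis=1)
    low = sorted(counts.index[totals < 10])
    kept = counts.drop(index=low)
    if kept.empty:
        raise ValueError("no genes left after low-total filtering")
    any_zero = sorted(kept.index[(kept == 0).any(axis=1)])
    return kept, FilterReport(removed_low_total=low, excluded_any_zero=any_zero)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    For each gene with all-positive counts, the ratio of its count to its
    geometric mean across samples; the sample's size factor is the median
    of those ratios.
    """
    _check_counts(counts)
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene with all-positive counts; cannot form size factors")
    log_geo_mean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo_mean, axis=0)
    return pd.Series(np.exp(ratios.median(axis=0)), index=counts.columns,
                     name="size_factor")


def size_factor_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each sample's counts by its median-of-ratios size factor."""
    sf = size_factors(counts)
    return counts.div(sf, axis=1), sf


def relative_log_transform(
    norm: pd.DataFrame,
    meta: pd.DataFrame,
    control_query: str = "dose_ng_ml == 0 and not ikb_sr",
    match_on: tuple[str, ...] = ("cell_line", "time_hr"),
) -> pd.DataFrame:
    """log2 of normalised counts, relative to the matched control.

    For each sample, subtract log2 of the mean normalised count of its
    matched control samples (same cell line and timepoint; no TNFα, no
    IκB-SR; mean over the technical replicates).  Requires strictly
    positive values for all retained genes — exclude any-zero genes first.
    """
    if (norm.to_numpy() <= 0).any():
        raise ValueError(
            "non-positive normalised counts; drop any-zero genes before the "
            "log transform"
        )
    missing = [c for c in match_on if c not in meta.columns]
    if missing:
        raise KeyError(f"metadata lacks columns: {missing}")
    controls = meta.query(control_query)
    out = pd.DataFrame(index=norm.index, columns=norm.columns, dtype=float)
    for key, grp in meta.groupby(list(match_on)):
        ctrl_samples = controls.index.intersection(grp.index)
        if len(ctrl_samples) == 0:
            raise ValueError(f"missing matched control for {dict(zip(match_on, key if isinstance(key, tuple) else (key,)))}")
        ref = np.log2(norm[ctrl_samples].mean(axis=1))
        out[grp.index] = np.log2(norm[grp.index]).sub(ref, axis=0)
    return out


def zscore_genes(
    relative: pd.DataFrame,
    across: list[str] | None = None,
    ddof: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardise each gene across the declared sample set.

    Population-sd convention by default.  Zero-variance genes are set to 0
    and returned in the flagged list rather than dropped, preserving the
    matrix shape.
    """
    cols = list(across) if across is not None else list(relative.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 samples to z-score")
    sub = relative[cols]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=ddof)
    flagged = sorted(sub.index[sd == 0])
    if flagged:
        warnings.warn(f"{len(flagged)} zero-variance gene(s) set to 0", stacklevel=2)
    z = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z, flagged


def cluster_genes(
    z: pd.DataFrame,
    k: int = 7,
    distance: str = "1 - pearson",
    linkage_method: str = "complete",
) -> GeneClusterAssignment:
    """Hierarchical clustering of gene z-profiles cut at k clusters.

    Default distance and linkage mirror the feature-reduction convention
    (1 - Pearson r, complete linkage).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(z):
        raise ValueError(f"k={k} exceeds the number of genes ({len(z)})")
    if distance == "1 - pearson":
        corr = np.corrcoef(z.to_numpy())
        corr = np.nan_to_num(corr, nan=0.0)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        condensed = squareform((dist + dist.T) / 2, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist
        condensed = pdist(z.to_numpy())
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(condensed, method=linkage_method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return GeneClusterAssignment(
        labels=pd.Series(labels.astype(int), index=z.index, name="cluster"),
        k=k, distance=distance, linkage_method=linkage_method, linkage=Z,
    )


def cluster_summary(
    z: pd.DataFrame,
    clusters: GeneClusterAssignment,
    meta: pd.DataFrame | None = None,
    grouping: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mean z-profile per cluster and condition with a 95% CI ribbon.

    CI = mean +/- 1.96 * se across member genes (sample sd); singleton
    clusters report the mean with an undefined CI.  With ``meta`` and
    ``grouping``, samples are first averaged per gene within each condition
    group.
    """
    if meta is not None and grouping:
        prof = {}
        for key, grp in meta.groupby(list(grouping)):
            name = key if not isinstance(key, tuple) else "|".join(map(str, key))
            prof[name] = z[grp.index].mean(axis=1)
        profiles = pd.DataFrame(prof)
    else:
        profiles = z
    rows = []
    for cid, genes in clusters.clusters.items():
        sub = profiles.loc[genes]
        n = len(genes)
        mean = sub.mean(axis=0)
        if n > 1:
            se = sub.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            se = pd.Series(np.nan, index=sub.columns)
        for cond in profiles.columns:
            rows.append({
                "cluster": cid, "condition": cond, "n_genes": n,
                "mean_z": float(mean[cond]),
                "ci_lo": float(mean[cond] - 1.96 * se[cond]) if n > 1 else np.nan,
                "ci_hi": float(mean[cond] + 1.96 * se[cond]) if n > 1 else np.nan,
            })
    return pd.DataFrame(rows)
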