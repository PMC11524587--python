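"""Morphometric feature derivation, normalisation and reduction.

Per-cell measurements from high-content imaging (areas, lengths, total
intensities per segmented region) are turned into the analysis panel:
derived ratios (elongatedness, region mean intensities, actin-filament
area fraction, grouped neighbour contact), per-replicate mean
normalisation, z-scoring against untreated controls, reduction of the
full feature panel to k representatives by hierarchical clustering on the
1 - Pearson correlation distance with complete linkage, and PCA of the
z-scored matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA as _PCA

__all__ = [
    "FeatureClustering",
    "METADATA_COLUMNS",
    "feature_columns",
    "derive_features",
    "normalize_features",
    "zscore_to_control",
    "reduce_features",
    "pca",
]

METADATA_COLUMNS = (
    "cell_id", "cell_line", "dose_ng_ml", "treatment", "bio_rep", "well", "sirna",
)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Numeric non-metadata columns of a feature table."""
    return [
        c for c in table.columns
        if c not in METADATA_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
    ]


@dataclass
class FeatureClustering:
    """Assignment of features to k correlation clusters with representatives."""

    assignments: dict[str, int]          # feature -> cluster id (1..k)
    representatives: dict[int, str]      # cluster id -> medoid feature
    linkage: np.ndarray                  # scipy linkage matrix (complete)
    features: list[str]                  # order matching the linkage
    excluded: list[str] = field(default_factory=list)  # constant features

    @property
    def k(self) -> int:
        return len(self.representatives)

    def to_json(self, path) -> None:
        heights = self.linkage[:, 2].tolist()
        payload = {
            "assignments": self.assignments,
            "representatives": {str(k): v for k, v in self.representatives.items()},
            "merge_heights": heights,
            "excluded": self.excluded,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------

def _round_to_nearest_10(x: pd.Series) -> pd.Series:
    # half-up so e.g. 35 -> 40, matching the grouped-contact convention
    return np.floor(x / 10.0 + 0.5) * 10.0


def derive_features(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append derived morphometric columns to a raw per-cell table.

    Derivations: elongatedness = (2 * cell length)^2 / cell area; region
    mean intensity = total intensity / region area (for every
    ``<name>_total`` column with a matching region area); actin filament
    area fraction = actin filament area / cell area; grouped neighbour
    contact = raw percentage rounded (half-up) to the nearest multiple of
    10.  Cells with non-positive cell or nucleus area are dropped and
    reported.
    """
    required = {"cell_area"}
    missing = required - set(raw.columns)
    if missing:
        raise KeyError(f"raw table lacks columns: {sorted(missing)}")
    bad = raw["cell_area"] <= 0
    if "nucleus_area" in raw.columns:
        bad |= raw["nucleus_area"] <= 0
    dropped = raw[bad]
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} cell(s) with non-positive area",
                      stacklevel=2)
    out = raw[~bad].copy()

    if "cell_length" in out.columns:
        out["elongatedness"] = (2 * out["cell_length"]) ** 2 / out["cell_area"]
    for col in list(out.columns):
        if not col.endswith("_total"):
            continue
        stem = col[: -len("_total")]
        region = "nucleus_area" if stem.startswith("nuc") else "cell_area"
        if region in out.columns:
            out[stem + "_mean"] = out[col] / out[region]
    if "actin_filament_area" in out.columns:
        out["actin_filament_area_ratio"] = out["actin_filament_area"] / out["cell_area"]
    if "neighbour_contact" in out.columns:
        out["neighbour_contact_grouped"] = _round_to_nearest_10(out["neighbour_contact"])
    return out, dropped


def normalize_features(
    table: pd.DataFrame, per: str = "bio_rep",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Divide each feature by its grand mean within each biological replicate.

    The grand mean pools all treatments and cell lines inside the
    replicate, so each feature has replicate-wise mean exactly 1 afterwards
    (idempotent on already-normalised data).
    """
    columns = columns if columns is not None else feature_columns(table)
    out = table.copy()
    for rep, idx in table.groupby(per).groups.items():
        means = table.loc[idx, columns].mean()
        zero = means[means == 0]
        if not zero.empty:
            raise ValueError(
                f"zero grand mean in replicate {rep!r} for feature(s) "
                f"{list(zero.index)}"
            )
        out.loc[idx, columns] = table.loc[idx, columns] / means
    return out


def zscore_to_control(
    table: pd.DataFrame,
    control_query: str = "dose_ng_ml == 0",
    per: str = "bio_rep",
    columns: list[str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Standardise features against the untreated controls per replicate.

    z = (x - control mean) / control sd, computed per feature and
    biological replicate from the pooled control cells of all cell lines
    (sample sd by default).  Features whose control sd is 0 in some
    replicate are flagged with a warning and left undefined there.
    """
    columns = columns if columns is not None else feature_columns(table)
    out = table.copy()
    for rep, idx in table.groupby(per).groups.items():
        sub = table.loc[idx]
        ctrl = sub.query(control_query)
        if ctrl.empty:
            raise ValueError(f"no control cells in replicate {rep!r}")
        mu = ctrl[columns].mean()
        sd = ctrl[columns].std(ddof=ddof)
        degenerate = sd[sd == 0]
        if not degenerate.empty:
            warnings.warn(
                f"zero control sd in replicate {rep!r} for feature(s) "
                f"{list(degenerate.index)}; z left undefined", stacklevel=2,
            )
            sd = sd.replace(0, np.nan)
        out.loc[idx, columns] = (sub[columns] - mu) / sd
    return out


# ---------------------------------------------------------------------------

def reduce_features(
    table: pd.DataFrame,
    k: int = 10,
    columns: list[str] | None = None,
    max_cells: int = 20_000,
    seed: int = 0,
) -> FeatureClustering:
    """Cluster features on 1 - Pearson r (complete linkage) and cut at k.

    Correlations are computed across single cells pooled over all
    conditions (subsampled, seeded, above ``max_cells`` rows for memory).
    Constant features are excluded with a warning.  Each cluster's
    representative is its medoid — the member with the highest mean |r| to
    the other members — with ties broken lexicographically by feature name.
    """
    columns = columns if columns is not None else feature_columns(table)
    data = table[columns]
    if len(data) > max_cells:
        rng = np.random.default_rng(seed)
        data = data.iloc[np.sort(rng.choice(len(data), max_cells, replace=False))]
    sd = data.std(ddof=0)
    excluded = sorted(sd.index[sd == 0])
    if excluded:
        warnings.warn(f"excluding constant feature(s): {excluded}", stacklevel=2)
        columns = [c for c in columns if c not in excluded]
        data = data[columns]
    if len(columns) < k:
        raise ValueError(f"need at least k={k} non-constant features, "
                         f"have {len(columns)}")
    corr = data.corr().to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    assignments = {f: int(c) for f, c in zip(columns, labels)}

    representatives: dict[int, str] = {}
    for cid in sorted(set(labels)):
        members = sorted([f for f, c in assignments.items() if c == cid])
        if len(members) == 1:
            representatives[cid] = members[0]
            continue
        mi = [columns.index(m) for m in members]
        sub = np.abs(corr[np.ix_(mi, mi)])
        mean_r = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        best = max(range(len(members)),
                   key=lambda i: (mean_r[i], ), default=0)
        # lexicographic tie-break: members are sorted, keep the first maximal
        top = np.max(mean_r)
        best = next(i for i in range(len(members)) if mean_r[i] >= top - 1e-12)
        representatives[cid] = members[best]
    return FeatureClustering(
        assignments=assignments, representatives=representatives,
        linkage=Z, features=list(columns), excluded=excluded,
    )


def pca(
    table: pd.DataFrame, columns: list[str] | None = None,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a z-scored feature matrix.

    Returns (scores, loadings, explained variance ratio); components are
    ordered by decreasing explained variance and the loadings are
    orthonormal.
    """
    columns = columns if columns is not None else feature_columns(table)
    X = table[columns].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("undefined entries in feature matrix; clean before PCA")
    model = _PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i+1}" for i in range(model.n_components_)]
    scores_df = pd.DataFrame(scores, index=table.index, columns=comp_names)
    loadings_df = pd.DataFrame(model.components_.T, index=columns, columns=comp_names)
    return scores_df, loadings_df, model.explained_variance_ratio_
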