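"""Single-cell nuclear-translocation trajectory analytics.

Processing follows the study's live-imaging pipeline: interior missing
points are imputed by linear interpolation, tracks are smoothed with a
Savitzky-Golay filter (order 1, window 7 for display/knockdown tracks;
order 3, window 11 before peak detection), intensities are normalised to
the per-timepoint mean of the solvent control for the same cell line (which
cancels photobleaching and laser-power drift), the first nuclear-intensity
peak is the first post-stimulus timepoint at which the smoothed curve's
slope is <= 0, within-track stability is summarised by Pearson correlations
of t0-scaled intensities between a reference and later timepoints, and
total nuclear occupancy is the area under the linear interpolant of the
normalised track evaluated on a 1000-interval refinement.  Knockdown
effects on the AUC are normalised to the non-targeting-siRNA mean per
stratum, expressed as TNFα/control fold-changes, and tested with Wilcoxon
rank-sum (or t-) tests under Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Track",
    "PeakCall",
    "AUCResult",
    "impute_interior",
    "sg_smooth",
    "normalize_to_solvent_control",
    "detect_peak",
    "within_track_correlation",
    "compute_auc",
    "normalize_auc",
    "auc_fold_change",
    "compare_groups",
    "iter_tracks",
    "analyze_tracks",
]


@dataclass
class Track:
    """One cell's nuclear-intensity time series on a uniform grid."""

    times: np.ndarray            # min relative to stimulus; uniform spacing
    values: np.ndarray           # nuclear intensity a.u.; NaN = missing
    cell_id: str = ""
    cell_line: str = ""
    sirna: str = "NT"
    dose_ng_ml: float = 0.0
    bio_rep: str = ""
    well: str = ""
    edge_missing: bool = False   # leading/trailing gaps left unimputed

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def replace(self, values: np.ndarray, **kw) -> "Track":
        d = asdict(self)
        d["values"] = values
        d["times"] = self.times
        d.update(kw)
        return Track(**d)


@dataclass
class PeakCall:
    """First nuclear-intensity peak of a track."""

    peak_time: float             # min
    peak_amplitude: float        # smoothed value / pre-stimulus baseline
    censored: bool               # True: no non-positive slope before track end


@dataclass
class AUCResult:
    auc: float                   # intensity * min
    window: tuple[float, float]
    auc_norm: float | None = None
    fold_change: float | None = None


# ---------------------------------------------------------------------------
# Per-track operations
# ---------------------------------------------------------------------------

def impute_interior(track: Track) -> Track:
    """Linearly interpolate missing values in the centre of the track.

    Leading and trailing gaps are left missing and flagged via
    ``edge_missing`` (the study's rule imputes only the centre of tracks).
    """
    v = track.values
    obs = ~np.isnan(v)
    if obs.sum() == 0:
        raise ValueError("all-missing track")
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed points to impute")
    first, last = np.flatnonzero(obs)[[0, -1]]
    filled = v.copy()
    core = slice(first, last + 1)
    t_core = track.times[core]
    v_core = v[core]
    miss = np.isnan(v_core)
    if miss.any():
        filled[core] = np.where(
            miss, np.interp(t_core, t_core[~miss], v_core[~miss]), v_core
        )
    edge = bool(first > 0 or last < len(v) - 1)
    return track.replace(filled, edge_missing=edge or track.edge_missing)


def sg_smooth(track: Track, order: int, window: int) -> Track:
    """Savitzky-Golay smoothing (centred local least-squares polynomial).

    Edges are handled by fitting the full-window polynomial and evaluating
    it at the edge positions.  Missing values must be imputed first.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if len(track.values) < window:
        raise ValueError(f"track length {len(track.values)} < window {window}")
    if np.isnan(track.values).any():
        raise ValueError("track contains missing values; impute first")
    smoothed = savgol_filter(track.values, window, order, mode="interp")
    return track.replace(smoothed)


def detect_peak(
    track: Track, order: int = 3, window: int = 11
) -> PeakCall:
    """First post-stimulus timepoint at which the smoothed slope is <= 0.

    The track is smoothed (default order 3, window 11), the slope at t_i is
    the forward difference of the smoothed series, and the call is the
    first t_i > 0 with slope <= 0.  When no such point exists before the
    final slope, the call is censored at the last timepoint.  The amplitude
    is the smoothed value at the peak divided by the mean of the smoothed
    pre-stimulus (t < 0) values, falling back to the t = 0 value when the
    track starts at the stimulus.
    """
    smoothed = sg_smooth(track, order, window)
    s = smoothed.values
    t = smoothed.times
    pre = t < 0
    if pre.any():
        baseline = float(np.mean(s[pre]))
    else:
        baseline = float(s[np.argmin(np.abs(t))])
    if baseline == 0:
        raise ValueError("zero pre-stimulus baseline")
    slope = np.diff(s) / smoothed.dt
    candidates = np.flatnonzero((t[:-1] > 0) & (slope <= 0))
    if len(candidates) == 0:
        i = len(t) - 1
        return PeakCall(float(t[i]), float(s[i] / baseline), censored=True)
    i = int(candidates[0])
    return PeakCall(float(t[i]), float(s[i] / baseline), censored=False)


def compute_auc(
    track: Track,
    window: tuple[float, float] | None = None,
    subdivisions: int = 1000,
) -> AUCResult:
    """Area under the linear interpolant of the track over ``window``.

    The integral is a composite trapezoid on the union of a
    ``subdivisions``-interval uniform refinement of the window and the
    track's own sample times, which makes it exact for the piecewise-linear
    interpolant (and hence additive over adjacent windows).
    """
    if np.isnan(track.values).any():
        raise ValueError("track contains missing values; impute first")
    lo, hi = window if window is not None else (max(track.times[0], 0.0), track.times[-1])
    if lo < track.times[0] - 1e-9 or hi > track.times[-1] + 1e-9 or hi <= lo:
        raise ValueError(f"window [{lo}, {hi}] outside track span")
    grid = np.linspace(lo, hi, subdivisions + 1)
    knots = track.times[(track.times > lo) & (track.times < hi)]
    grid = np.unique(np.concatenate([grid, knots]))
    y = np.interp(grid, track.times, track.values)
    return AUCResult(auc=float(np.trapezoid(y, grid)), window=(lo, hi))


# ---------------------------------------------------------------------------
# Track-set operations (long-format DataFrame)
# ---------------------------------------------------------------------------

_TRACK_META = ["cell_id", "cell_line", "sirna", "dose_ng_ml", "bio_rep", "well"]


def iter_tracks(frame: pd.DataFrame):
    """Yield ``Track`` objects from a long-format track table."""
    for cell_id, grp in frame.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        meta = grp.iloc[0]
        yield Track(
            times=grp["time_min"].to_numpy(),
            values=grp["nuc_intensity"].to_numpy(),
            cell_id=str(cell_id),
            cell_line=str(meta.get("cell_line", "")),
            sirna=str(meta.get("sirna", "NT")),
            dose_ng_ml=float(meta.get("dose_ng_ml", 0.0)),
            bio_rep=str(meta.get("bio_rep", "")),
            well=str(meta.get("well", "")),
        )


def normalize_to_solvent_control(
    frame: pd.DataFrame,
    extra_strata: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Divide intensities by the solvent-control mean per cell line and timepoint.

    The control stratum is dose 0 within the same cell line (and any
    ``extra_strata``, e.g. ``("sirna",)`` for knockdown experiments); the
    division is per timepoint, so multiplicative drift shared by treated
    and control wells — photobleaching, laser-power changes — cancels.
    Control tracks have per-timepoint mean exactly 1 after the transform.
    """
    keys = ["cell_line", *extra_strata, "time_min"]
    control = frame[frame["dose_ng_ml"] == 0]
    if control.empty:
        raise ValueError("no solvent-control (dose 0) measurements present")
    means = control.groupby(keys)["nuc_intensity"].mean().rename("_ctrl_mean")
    out = frame.merge(means, on=keys, how="left")
    missing = out["_ctrl_mean"].isna() & out["nuc_intensity"].notna()
    if missing.any():
        strata = out.loc[missing, keys].drop_duplicates().to_dict(orient="records")
        raise ValueError(f"missing control stratum for: {strata[:5]}")
    out["nuc_intensity"] = out["nuc_intensity"] / out["_ctrl_mean"]
    return out.drop(columns="_ctrl_mean")


def within_track_correlation(
    frame: pd.DataFrame,
    t_ref: float = 60.0,
    t_cmp: tuple[float, ...] = (180.0, 300.0, 600.0),
) -> pd.DataFrame:
    """Pearson r between t0-scaled intensities at ``t_ref`` and later times.

    Each track is first scaled by its own t = 0 value; r is then computed
    across cells within each (cell line, dose) stratum.  Strata with fewer
    than three cells, or zero variance in either variable, are flagged
    undefined rather than reported as 0.
    """
    needed = {0.0, t_ref, *t_cmp}
    wide = (
        frame[frame["time_min"].isin(needed)]
        .pivot_table(index=["cell_line", "dose_ng_ml", "cell_id"],
                     columns="time_min", values="nuc_intensity")
    )
    if 0.0 not in wide.columns:
        raise ValueError("tracks lack a t=0 measurement")
    rows = []
    for (line, dose), grp in wide.groupby(level=["cell_line", "dose_ng_ml"]):
        t0 = grp[0.0]
        ok = t0.notna() & (t0 != 0)
        scaled = grp.loc[ok].div(t0[ok], axis=0)
        for tc in t_cmp:
            x = scaled.get(t_ref)
            y = scaled.get(tc)
            rec = {"cell_line": line, "dose_ng_ml": dose,
                   "t_ref": t_ref, "t_cmp": tc, "r": np.nan,
                   "n": 0, "undefined": True}
            if x is not None and y is not None:
                both = x.notna() & y.notna()
                rec["n"] = int(both.sum())
                if both.sum() >= 3:
                    xv, yv = x[both].to_numpy(), y[both].to_numpy()
                    if np.std(xv) > 0 and np.std(yv) > 0:
                        rec["r"] = float(np.corrcoef(xv, yv)[0, 1])
                        rec["undefined"] = False
            rows.append(rec)
    return pd.DataFrame(rows)


def normalize_auc(
    aucs: pd.DataFrame,
    reference: str = "NT",
    strata: tuple[str, ...] = ("bio_rep", "cell_line", "treatment"),
) -> pd.DataFrame:
    """Divide each AUC by the mean AUC of the reference siRNA in its stratum.

    Reference-group strata have mean ``auc_norm`` exactly 1.
    """
    ref = aucs[aucs["sirna"] == reference]
    if ref.empty:
        raise ValueError(f"no rows for reference siRNA {reference!r}")
    means = ref.groupby(list(strata))["auc"].mean().rename("_ref_mean")
    out = aucs.merge(means, on=list(strata), how="left")
    if out["_ref_mean"].isna().any():
        bad = out.loc[out["_ref_mean"].isna(), list(strata)].drop_duplicates()
        raise ValueError(
            f"reference siRNA absent for strata: {bad.to_dict(orient='records')[:5]}"
        )
    out["auc_norm"] = out["auc"] / out["_ref_mean"]
    return out.drop(columns="_ref_mean")


def auc_fold_change(
    aucs: pd.DataFrame,
    value: str = "auc",
    control_label: str = "control",
    strata: tuple[str, ...] = ("sirna", "cell_line"),
) -> pd.DataFrame:
    """Fold-change of each AUC over the mean of the no-TNFα control AUCs
    for the same siRNA and cell line."""
    ctrl = aucs[aucs["treatment"] == control_label]
    if ctrl.empty:
        raise ValueError(f"no rows with treatment == {control_label!r}")
    means = ctrl.groupby(list(strata))[value].mean().rename("_ctrl_mean")
    out = aucs.merge(means, on=list(strata), how="left")
    if out["_ctrl_mean"].isna().any():
        bad = out.loc[out["_ctrl_mean"].isna(), list(strata)].drop_duplicates()
        raise ValueError(
            f"control measurements absent for strata: {bad.to_dict(orient='records')[:5]}"
        )
    if (out["_ctrl_mean"] == 0).any():
        raise ValueError("zero control mean; fold-change undefined")
    out["fold_change"] = out[value] / out["_ctrl_mean"]
    return out.drop(columns="_ctrl_mean")


def compare_groups(
    measurements: pd.DataFrame,
    value: str,
    group: str,
    reference: str,
    test: str = "wilcoxon_rank_sum",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided tests of each group against the reference, BH-adjusted.

    ``test`` is ``wilcoxon_rank_sum`` (Mann-Whitney U; exact distribution
    for small tie-free samples, normal approximation with tie correction
    otherwise) or ``t_test``.  Groups with fewer than two observations are
    skipped and recorded with a warning flag.  The effect column is the
    difference of group medians.
    """
    if test not in ("wilcoxon_rank_sum", "t_test"):
        raise ValueError(f"unknown test {test!r}")
    ref_values = measurements.loc[measurements[group] == reference, value].dropna()
    if len(ref_values) < 2:
        raise ValueError(f"reference group {reference!r} has fewer than 2 observations")
    rows = []
    for label, grp in measurements.groupby(group, sort=True):
        if label == reference:
            continue
        x = grp[value].dropna()
        if len(x) < 2:
            rows.append({"group": label, "n": int(len(x)), "effect": np.nan,
                         "p": np.nan, "skipped": True})
            warnings.warn(f"group {label!r} has fewer than 2 observations; skipped",
                          stacklevel=2)
            continue
        if test == "wilcoxon_rank_sum":
            res = stats.mannwhitneyu(x, ref_values, alternative="two-sided",
                                     method="auto")
        else:
            res = stats.ttest_ind(x, ref_values)
        rows.append({
            "group": label, "n": int(len(x)),
            "effect": float(np.median(x) - np.median(ref_values)),
            "p": float(res.pvalue), "skipped": False,
        })
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    tested = table["p"].notna()
    if tested.any():
        table.loc[tested, "p_adj"] = multipletests(
            table.loc[tested, "p"], method="fdr_bh"
        )[1]
    table["significant"] = table["p_adj"] < alpha
    return table


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def analyze_tracks(
    frame: pd.DataFrame,
    peak_order: int = 3,
    peak_window: int = 11,
    auc_window: tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Impute, normalise, call peaks and integrate every track.

    Returns tidy ``peaks`` and ``auc`` tables, plus ``stats`` (AUC-norm
    Wilcoxon comparisons against the non-targeting siRNA) when more than
    one siRNA is present.
    """
    norm = normalize_to_solvent_control(frame)
    peak_rows, auc_rows = [], []
    for track in iter_tracks(norm):
        track = impute_interior(track)
        if np.isnan(track.values).any():  # unimputed edges: trim them
            obs = ~np.isnan(track.values)
            lo, hi = np.flatnonzero(obs)[[0, -1]]
            track = Track(track.times[lo:hi + 1], track.values[lo:hi + 1],
                          track.cell_id, track.cell_line, track.sirna,
                          track.dose_ng_ml, track.bio_rep, track.well,
                          edge_missing=True)
        meta = {k: getattr(track, k if k != "dose_ng_ml" else "dose_ng_ml")
                for k in _TRACK_META}
        treatment = "control" if track.dose_ng_ml == 0 else "TNFa"
        if len(track.values) >= peak_window:
            call = detect_peak(track, peak_order, peak_window)
            peak_rows.append({**meta, "treatment": treatment, **asdict(call)})
        res = compute_auc(track, auc_window)
        auc_rows.append({**meta, "treatment": treatment,
                         "auc": res.auc, "window_lo": res.window[0],
                         "window_hi": res.window[1]})
    peaks = pd.DataFrame(peak_rows)
    aucs = pd.DataFrame(auc_rows)
    out = {"peaks": peaks, "auc": aucs}
    if aucs["sirna"].nunique() > 1 and "NT" in set(aucs["sirna"]):
        normed = normalize_auc(aucs, reference="NT")
        out["auc"] = normed
        stats_rows = []
        for (line, treat), grp in normed.groupby(["cell_line", "treatment"]):
            if grp["sirna"].nunique() < 2:
                continue
            st = compare_groups(grp, "auc_norm", "sirna", "NT", alpha=alpha)
            st.insert(0, "treatment", treat)
            st.insert(0, "cell_line", line)
            stats_rows.append(st)
        if stats_rows:
            out["stats"] = pd.concat(stats_rows, ignore_index=True)
    return out
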