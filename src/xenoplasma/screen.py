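"""Per-analyte longitudinal statistics and marker-set selection.

The screening recipe, applied per cell line (group) and analyte:

1. log10-transform the normalized signal;
2. one-way repeated-measures ANOVA across study days with animal as the
   repeated measure (:func:`rm_anova`);
3. Benjamini–Hochberg adjustment across analytes (:func:`bh_adjust`);
4. per-day median log2 fold change against each animal's own day-0 sample
   (:func:`log2_fold_change`);
5. Pearson correlation between signal and tumor volume
   (:func:`pearson_with_volume`);
6. threshold-based selection minus analytes that also moved in control
   animals (:func:`select_markers`).

Simpler in-vitro designs (independent-groups ANOVA, unpaired t) are in
:func:`one_way_anova` / :func:`unpaired_t`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import RFUDataset


@dataclass(frozen=True)
class ScreenThresholds:
    """Selection thresholds: FDR, |median log2 fold change|, |Pearson r|."""

    q_max: float = 0.05
    min_abs_log2fc: float = 1.0
    min_abs_r: float = 0.25


@dataclass
class MarkerSet:
    """A selected analyte set with its provenance."""

    group: str
    analytes: frozenset[str]
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    control_group: str | None = None

    def __len__(self) -> int:
        return len(self.analytes)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def rm_anova(values: np.ndarray) -> tuple[float, float, tuple[int, int]]:
    """One-way within-subject ANOVA on an animals × days matrix.

    Partitions total SS into subject, time and error components;
    ``F = MS_time / MS_error`` with df ``(k-1, (k-1)(n-1))``.  Animals with
    any missing day are dropped (complete-case); fewer than 2 complete
    animals or 2 days yields ``(nan, nan)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an animals x days matrix")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        return math_nan, math_nan, (0, 0)
    grand = x.mean()
    ss_subject = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_time = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_subject - ss_time
    df_time = k - 1
    df_error = (k - 1) * (n - 1)
    ms_error = ss_error / df_error
    if ms_error <= 0:
        # all residual variance absorbed: either F undefined (flat) or inf
        f = 0.0 if ss_time == 0 else np.inf
    else:
        f = (ss_time / df_time) / ms_error
    p = float(stats.f.sf(f, df_time, df_error)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return float(f), p, (df_time, df_error)


math_nan = float("nan")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement.

    NaN entries propagate as NaN and do not count toward the number of
    tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p values")
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    m = int(valid.sum())
    if m == 0:
        return q
    pv = p[valid]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[valid] = out
    return q


def log2_fold_change(
    signal: pd.Series, samples: pd.DataFrame, baseline_day: int = 0
) -> pd.Series:
    """Median-across-animals log2 fold change per day, paired within animal.

    *signal* is indexed by sample id; *samples* supplies ``AnimalId`` and
    ``StudyDay``.  Animals lacking a baseline-day sample are excluded.
    Returns a Series indexed by the non-baseline days.
    """
    meta = samples.loc[signal.index]
    frame = pd.DataFrame({
        "animal": meta["AnimalId"],
        "day": meta["StudyDay"],
        "value": signal.astype(float),
    })
    base = frame[frame["day"] == baseline_day].set_index("animal")["value"]
    rest = frame[frame["day"] != baseline_day]
    rest = rest[rest["animal"].isin(base.index)]
    ratios = np.log2(rest["value"].to_numpy()
                     / base[rest["animal"]].to_numpy())
    return (
        pd.Series(ratios, index=rest["day"].to_numpy())
        .groupby(level=0)
        .median()
        .rename("median_log2fc")
    )


def pearson_with_volume(signal, volumes) -> float:
    """Product-moment correlation of signal with tumor volume.

    Returns NaN when either side has zero variance or fewer than 3 pairs
    (the analyte then fails the correlation filter).
    """
    x = np.asarray(signal, dtype=float)
    y = np.asarray(volumes, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math_nan
    return float(stats.pearsonr(x, y).statistic)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical independent-groups one-way ANOVA (log10 values upstream)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def unpaired_t(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# the per-group screen
# ---------------------------------------------------------------------------

def screen_group(
    dataset: RFUDataset, group: str, baseline_day: int = 0
) -> pd.DataFrame:
    """Run the per-analyte longitudinal screen for one group.

    Returns a DataFrame indexed by analyte with columns ``F``, ``p``, ``q``,
    ``max_abs_log2fc``, ``pearson_r`` plus one ``log2fc_day<d>`` column per
    non-baseline day.  Hybridization controls are excluded up front.
    """
    ds = dataset.drop_hyb_controls()
    mask = (ds.samples["Group"] == group) & (ds.samples["SampleType"] == "study")
    if not mask.any():
        raise ValueError(f"no study samples for group {group!r}")
    sub = ds.subset_samples(ds.samples.index[mask])
    meta = sub.samples
    days = np.sort(meta["StudyDay"].unique())
    animals = list(meta["AnimalId"].unique())
    # animals x days grid of row positions (-1 = no sample); a missing cell
    # becomes NaN for every analyte (complete-case handling in rm_anova)
    pos = np.full((len(animals), len(days)), -1, dtype=int)
    animal_idx = {a: i for i, a in enumerate(animals)}
    day_idx = {d: j for j, d in enumerate(days)}
    for row, (sid, srow) in enumerate(meta.iterrows()):
        pos[animal_idx[srow["AnimalId"]], day_idx[srow["StudyDay"]]] = row
    log10 = np.log10(sub.values.to_numpy(dtype=float))
    volumes = pd.to_numeric(meta["TumorVolume_mm3"]).to_numpy()

    records = []
    fc_tables = {}
    for j, aid in enumerate(sub.values.columns):
        col = log10[:, j]
        cube = np.where(pos >= 0, col[pos], np.nan)
        f, p, _ = rm_anova(cube)
        fc = log2_fold_change(sub.values[aid], meta, baseline_day)
        r = pearson_with_volume(col, volumes)
        records.append({
            "F": f,
            "p": p,
            "max_abs_log2fc": float(fc.abs().max()) if len(fc) else math_nan,
            "pearson_r": r,
        })
        fc_tables[aid] = fc
    result = pd.DataFrame(records, index=sub.values.columns)
    result["q"] = bh_adjust(result["p"].to_numpy())
    for day in days:
        if day == baseline_day:
            continue
        result[f"log2fc_day{day}"] = [
            fc_tables[a].get(day, math_nan) for a in result.index
        ]
    return result[["F", "p", "q", "max_abs_log2fc", "pearson_r"]
                  + [c for c in result.columns if c.startswith("log2fc_day")]]


def significant_set(
    screen: pd.DataFrame,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> set[str]:
    """Analytes passing the FDR and fold-change thresholds (no r filter)."""
    hits = (screen["q"] <= q_max) & (screen["max_abs_log2fc"] >= min_abs_log2fc)
    return set(screen.index[hits.fillna(False)])


def select_markers(
    screen: pd.DataFrame,
    control_screen: pd.DataFrame | None,
    group: str,
    thresholds: ScreenThresholds = ScreenThresholds(),
    control_group: str | None = None,
) -> MarkerSet:
    """Threshold-based selection with control-change exclusion.

    Keeps analytes with ``q <= q_max``, ``max |median log2FC| >=
    min_abs_log2fc`` and ``|r| >= min_abs_r``; then subtracts analytes
    that changed significantly over time in the control screen (same q
    and fold-change thresholds).  NaN statistics fail their filter.
    """
    q_ok = screen["q"] <= thresholds.q_max
    fc_ok = screen["max_abs_log2fc"] >= thresholds.min_abs_log2fc
    r_ok = screen["pearson_r"].abs() >= thresholds.min_abs_r
    selected = set(screen.index[(q_ok & fc_ok & r_ok).fillna(False)])
    if control_screen is not None:
        selected -= significant_set(
            control_screen, thresholds.q_max, thresholds.min_abs_log2fc
        )
    return MarkerSet(group, frozenset(selected), thresholds, control_group)


# ---------------------------------------------------------------------------
# set algebra over marker sets
# ---------------------------------------------------------------------------

@dataclass
class VennResult:
    intersection: frozenset[str]
    unique: dict[str, frozenset[str]]
    pairwise_shared: dict[tuple[str, str], frozenset[str]]


def venn_sets(marker_sets: dict[str, set[str] | frozenset[str]]) -> VennResult:
    """All-set intersection, per-set unique members and pairwise overlaps."""
    if len(marker_sets) < 2:
        raise ValueError("need at least two sets")
    names = list(marker_sets)
    sets = {k: frozenset(v) for k, v in marker_sets.items()}
    inter = frozenset.intersection(*sets.values())
    unique = {
        k: frozenset(
            sets[k].difference(*(sets[o] for o in names if o != k))
        )
        for k in names
    }
    pairwise = {
        (a, b): sets[a] & sets[b]
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    return VennResult(inter, unique, pairwise)
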