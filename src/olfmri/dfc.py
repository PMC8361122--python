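"""Sliding-window dynamic functional connectivity and the fractional statistic.

The core quantity is *fractional connectivity*: the fraction of the
recording during which the windowed Pearson correlation between a seed and
a target ROI exceeds a critical value (default 0.64, the two-tailed
critical correlation at alpha = 0.001 with 21 degrees of freedom). The
fraction is computed for a whole grid of window widths (default 5, 7, ...,
59 TRs, slid one TR at a time) and averaged over widths to remove the
dependence on any single width, then averaged across hemispheres
(left-seed->left-target with right-seed->right-target) to halve the number
of tests. Group contrasts on the resulting per-subject fractions are
pooled-variance t-tests; the brain-behaviour link is a Spearman rank
correlation against the composite olfactory (TDI) score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

from .prep import ROIAtlas, ROITimeSeriesMatrix
from .stats import CorrelationResult, correlate, pooled_ttest

__all__ = [
    "WindowGrid",
    "DFCParams",
    "DFCSeries",
    "critical_correlation",
    "sliding_corr",
    "fractional_connectivity",
    "multi_width_fraction",
    "hemisphere_average",
    "subject_fraction_table",
    "seed_group_contrast",
    "dfc_behavior_correlation",
]


@dataclass(frozen=True)
class WindowGrid:
    """Ensemble of sliding-window widths, in TRs.

    The default widths run from 5 TRs upward in steps of 2; the slide step
    along time is 1 TR.
    """

    widths_tr: tuple[int, ...] = tuple(range(5, 60, 2))
    slide_step_tr: int = 1

    def __post_init__(self):
        w = self.widths_tr
        if len(w) == 0 or any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError("widths must be strictly increasing and nonempty")
        if min(w) < 3:
            raise ValueError("window widths must be >= 3")
        if self.slide_step_tr < 1:
            raise ValueError("slide step must be >= 1")


@dataclass(frozen=True)
class DFCParams:
    """Threshold for calling a window 'connected'.

    ``rho_critical`` defaults to the critical Pearson correlation at
    ``alpha_ref`` = 0.001 (two-tailed) with 21 degrees of freedom, which
    prints as 0.64. Only correlations strictly above the threshold count;
    anticorrelations never do.
    """

    rho_critical: float = 0.64
    alpha_ref: float = 0.001

    def __post_init__(self):
        if not (0 < self.rho_critical < 1):
            raise ValueError("rho_critical must lie strictly between 0 and 1")


@dataclass
class DFCSeries:
    """Windowed correlations for one (seed, target, width) triple."""

    r: np.ndarray
    z: np.ndarray
    starts: np.ndarray
    width: int
    n_undefined: int = 0


def critical_correlation(alpha: float = 0.001, df: int = 21) -> float:
    """Two-tailed critical Pearson r: the |r| whose t statistic hits alpha.

    Inverts t = r * sqrt(df / (1 - r^2)) at the alpha/2 tail of Student's t.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = sps.t.ppf(1 - alpha / 2.0, df)
    return float(t / np.sqrt(t * t + df))


def expected_window_count(n: int, width: int, step: int) -> int:
    return (n - width) // step + 1


def sliding_corr(x, y, width: int, slide_step: int = 1) -> DFCSeries:
    """Pearson correlation in every window of ``width`` samples.

    Windows advance by ``slide_step``; the number of windows is
    floor((T - width) / slide_step) + 1. A window in which either series
    has zero variance gets an undefined (NaN) correlation, excluded from
    fraction denominators downstream and counted in ``n_undefined``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equally long 1-D series")
    n = x.size
    if not (3 <= width <= n):
        raise ValueError(f"width {width} invalid for series of length {n}")
    xw = sliding_window_view(x, width)[::slide_step]
    yw = sliding_window_view(y, width)[::slide_step]
    xm = xw - xw.mean(axis=1, keepdims=True)
    ym = yw - yw.mean(axis=1, keepdims=True)
    sx = np.sqrt((xm * xm).sum(axis=1))
    sy = np.sqrt((ym * ym).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xm * ym).sum(axis=1) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    starts = np.arange(0, n - width + 1, slide_step)
    return DFCSeries(
        r=r, z=z, starts=starts, width=width, n_undefined=int(np.isnan(r).sum())
    )


def fractional_connectivity(d: DFCSeries, p: DFCParams) -> float:
    """Fraction of defined windows with r strictly above the critical value.

    Thresholding the Fisher-z series at atanh(rho_critical) selects the
    identical window set (monotone transform), so the fraction is computed
    on r directly.
    """
    defined = np.isfinite(d.r)
    n_def = int(defined.sum())
    if n_def == 0:
        return float("nan")
    return float((d.r[defined] > p.rho_critical).sum() / n_def)


def multi_width_fraction(x, y, grid: WindowGrid, p: DFCParams) -> float:
    """Unweighted mean of per-width fractions over the window-width grid.

    Widths longer than the record (or with no defined window) are excluded
    from the mean.
    """
    n = np.asarray(x).size
    fracs = []
    for w in grid.widths_tr:
        if w > n:
            continue
        f = fractional_connectivity(sliding_corr(x, y, w, grid.slide_step_tr), p)
        if np.isfinite(f):
            fracs.append(f)
    if not fracs:
        return float("nan")
    return float(np.mean(fracs))


def hemisphere_average(per_hemisphere: pd.DataFrame) -> pd.DataFrame:
    """Average seed->target fractions across hemispheres.

    Input rows carry (hemisphere, seed_class, target_pair, fraction); the
    output has one row per (seed_class, target_pair) with the mean of the
    left and right homologous edges. If one hemisphere is missing, the
    available one is used and the row is flagged.
    """
    rows = []
    for (seed_class, target), sub in per_hemisphere.groupby(
        ["seed_class", "target_pair"], sort=True
    ):
        vals = sub["fraction"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        rows.append(
            {
                "seed_class": seed_class,
                "target_pair": target,
                "fraction": float(vals[ok].mean()) if ok.any() else float("nan"),
                "n_hemispheres": int(ok.sum()),
                "flag": "" if ok.sum() == 2 else "single-hemisphere",
            }
        )
    return pd.DataFrame(rows)


def subject_fraction_table(
    ts: ROITimeSeriesMatrix,
    atlas: ROIAtlas,
    grid: WindowGrid,
    params: DFCParams,
    seed_classes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Hemisphere-averaged multi-width fractions for every seed->target pair.

    Seeds are the atlas ROIs flagged ``is_seed`` (grouped by seed_class);
    targets are all other hemisphere pairs, named by the pair's base name.
    """
    meta = atlas.meta
    seeds = meta[meta["is_seed"] & (meta["hemisphere"] == "L")]
    if seed_classes is not None:
        seeds = seeds[seeds["seed_class"].isin(seed_classes)]
    if seeds.empty:
        raise ValueError("atlas declares no seed ROIs for the requested classes")
    pairs = atlas.pairs()
    rows = []
    for _, seed in seeds.iterrows():
        seed_lr = {"L": int(seed["label"]), "R": int(seed["partner_label"])}
        for _, tgt in pairs.iterrows():
            if int(tgt["label"]) == int(seed["label"]):
                continue
            tgt_lr = {"L": int(tgt["label"]), "R": int(tgt["partner_label"])}
            for hemi in ("L", "R"):
                frac = multi_width_fraction(
                    ts.row(seed_lr[hemi]), ts.row(tgt_lr[hemi]), grid, params
                )
                rows.append(
                    {
                        "hemisphere": hemi,
                        "seed_class": seed["seed_class"],
                        "target_pair": tgt["name"],
                        "fraction": frac,
                    }
                )
    return hemisphere_average(pd.DataFrame(rows))


def seed_group_contrast(
    fractions: pd.DataFrame, seed_class: str
) -> pd.DataFrame:
    """Per-target two-sample t-tests of fractional connectivity, A vs B.

    ``fractions`` is long-format with columns (subject_id, group,
    seed_class, target_pair, fraction). Both contrast directions are
    readable from the signed t (positive = group A stronger). Targets with
    degenerate variance in both groups are flagged. Rows sorted by |t|
    descending.
    """
    sub = fractions[fractions["seed_class"] == seed_class]
    if sub.empty:
        raise ValueError(f"no fractions for seed class {seed_class!r}")
    rows = []
    for target, grp in sub.groupby("target_pair", sort=True):
        a = grp.loc[grp["group"] == "A", "fraction"].to_numpy(dtype=float)
        b = grp.loc[grp["group"] == "B", "fraction"].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            raise ValueError(f"fewer than 2 subjects per group for target {target!r}")
        res = pooled_ttest(a, b)
        rows.append(
            {
                "seed_class": seed_class,
                "target_pair": target,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "mean_a": res.mean_a,
                "mean_b": res.mean_b,
                "direction": "A>B" if res.t > 0 else "B>A",
                "flag": res.note,
            }
        )
    out = pd.DataFrame(rows)
    return out.reindex(out["t"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def dfc_behavior_correlation(fc_values, tdi) -> CorrelationResult:
    """Spearman correlation between one edge's fractions and TDI scores."""
    return correlate(fc_values, tdi, method="spearman")
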