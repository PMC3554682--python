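"""MeDIP-chip differential-methylation-region (DMR) calling.

The statistic works on two-channel promoter tiling-array data. Each paired
hybridization compares a treatment MeDIP pool (cy5) against a control MeDIP
pool (cy3). Per probe the channels are converted to MA values on the log2
scale (M = cy5 - cy3, A = (cy5 + cy3)/2), dye bias is removed by
median-centering M (or a loess fit of M on A), and probe M values are
summarised as the median over 600 bp windows containing at least three
probes. Each window median is scored against an empirical null — a normal
distribution scaled to the mean and SD of all window medians in that
comparison — giving a Z-score and p-value. A window is a DMR candidate only
when significant, with a consistent sign of change, in *every* paired
comparison; overlapping candidates within a promoter are merged into one
differential methylation region ("epimutation").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ArrayDesign, HybridizationSet

__all__ = [
    "MAValues",
    "WindowConfig",
    "QPCRResult",
    "compute_ma",
    "ma_to_intensities",
    "normalize_ma",
    "window_statistics",
    "score_windows",
    "call_dmrs",
    "summarize_by_chromosome",
    "summarize_categories",
    "qpcr_fold_change",
]

WINDOW_COLUMNS = [
    "comparison_id",
    "chrom",
    "start",
    "end",
    "promoter_id",
    "gene_id",
    "probe_count",
    "median_m",
    "z",
    "p",
]

DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "promoter_id",
    "gene_id",
    "n_windows",
    "min_p",
    "mean_median_m",
    "sign",
    "per_comparison_p",
]


@dataclass
class MAValues:
    """Per-probe M/A values (log2 scale) for one or more comparisons."""

    frames: dict[str, pd.DataFrame]

    @classmethod
    def from_hybridizations(cls, hybs: HybridizationSet) -> "MAValues":
        return cls({cid: compute_ma(df) for cid, df in hybs.comparisons.items()})

    @property
    def comparison_ids(self) -> list[str]:
        return list(self.frames)


def compute_ma(channels: pd.DataFrame) -> pd.DataFrame:
    """Convert a paired channel table (probe_id, cy5, cy3) to MA values.

    M = log2(cy5) - log2(cy3) and A = (log2(cy5) + log2(cy3)) / 2, the
    standard rotation of two-channel intensities; it is exactly invertible
    (:func:`ma_to_intensities`).
    """
    for col in ("probe_id", "cy5", "cy3"):
        if col not in channels.columns:
            raise ValueError(f"channel table missing column {col!r}")
    for col in ("cy5", "cy3"):
        bad = channels[col].to_numpy() <= 0
        if bad.any():
            probe = channels.loc[bad, "probe_id"].iloc[0]
            raise ValueError(f"non-positive {col} intensity at probe {probe}")
    l5 = np.log2(channels["cy5"].to_numpy(dtype=float))
    l3 = np.log2(channels["cy3"].to_numpy(dtype=float))
    return pd.DataFrame(
        {"probe_id": channels["probe_id"].to_numpy(), "m": l5 - l3, "a": (l5 + l3) / 2.0}
    )


def ma_to_intensities(ma: pd.DataFrame) -> pd.DataFrame:
    """Invert the MA transform: cy5 = 2**(A + M/2), cy3 = 2**(A - M/2)."""
    m = ma["m"].to_numpy(dtype=float)
    a = ma["a"].to_numpy(dtype=float)
    return pd.DataFrame(
        {"probe_id": ma["probe_id"].to_numpy(), "cy5": np.exp2(a + m / 2), "cy3": np.exp2(a - m / 2)}
    )


def _normalize_frame(frame: pd.DataFrame, method: str, loess_frac: float) -> pd.DataFrame:
    out = frame.copy()
    if method == "median_center":
        out["m"] = out["m"] - out["m"].median()
    elif method == "loess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fitted = lowess(
            out["m"].to_numpy(), out["a"].to_numpy(), frac=loess_frac, return_sorted=False
        )
        resid = out["m"].to_numpy() - fitted
        out["m"] = resid - np.median(resid)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return out


def normalize_ma(ma, method: str = "median_center", loess_frac: float = 0.3):
    """Remove dye bias from M values.

    ``median_center`` subtracts the per-comparison median of M (after which
    the median is exactly 0); ``loess`` residualizes M on A with a lowess
    fit, removing intensity-dependent dye bias, and re-centers the
    residuals. Accepts a single MA frame or an :class:`MAValues` set.
    """
    if isinstance(ma, MAValues):
        if not ma.frames:
            raise ValueError("empty MAValues")
        return MAValues({cid: _normalize_frame(f, method, loess_frac) for cid, f in ma.frames.items()})
    if len(ma) == 0:
        raise ValueError("empty MA table")
    return _normalize_frame(ma, method, loess_frac)


@dataclass(frozen=True)
class WindowConfig:
    """Window construction and significance settings.

    600 bp windows with at least three member probes are the defaults; a
    window is anchored at each probe center ("sliding") or laid end to end
    across the promoter ("tiling"). Candidate windows must reach ``alpha``
    in every comparison, with a consistent direction of change when
    ``require_consistent_sign``; merged candidates closer than
    ``merge_gap_bp`` join one region.
    """

    window_bp: int = 600
    min_probes: int = 3
    alpha: float = 0.05
    two_sided: bool = True
    require_consistent_sign: bool = True
    method: str = "sliding"
    merge_gap_bp: int = 100
    normalization: str = "median_center"
    stratify_null_by_probe_count: bool = True

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("sliding", "tiling"):
            raise ValueError(f"unknown window method {self.method!r}")


def window_statistics(
    ma: MAValues, design: ArrayDesign, cfg: WindowConfig = WindowConfig()
) -> pd.DataFrame:
    """Per-comparison window medians of probe M values.

    Every emitted window lies within one promoter region, spans at most
    ``window_bp``, contains at least ``min_probes`` probes (membership by
    probe start in [start, end)), and carries the exact median of its
    members' M values. Returns a long DataFrame, one row per window per
    comparison, with ``z``/``p`` left NaN for :func:`score_windows`.
    """
    probes = design.probes.sort_values(["promoter_id", "start"], kind="stable")
    prom = design.promoters.set_index("promoter_id")
    rows = []
    groups = {
        pid: (g["probe_id"].to_numpy(), g["start"].to_numpy(), g["end"].to_numpy())
        for pid, g in probes.groupby("promoter_id", sort=False)
    }
    for cid, frame in ma.frames.items():
        m_by_probe = frame.set_index("probe_id")["m"]
        matched = False
        for pid, (pids, starts, ends) in groups.items():
            mask = np.isin(pids, m_by_probe.index.to_numpy())
            if not mask.any():
                continue
            matched = True
            pids_, starts_, ends_ = pids[mask], starts[mask], ends[mask]
            m = m_by_probe.loc[pids_].to_numpy(dtype=float)
            info = prom.loc[pid]
            region = (int(info["region_start"]), int(info["region_end"]))
            if cfg.method == "sliding":
                centers = (starts_ + ends_) // 2
                half = cfg.window_bp // 2
                seen = set()
                for c in centers:
                    w_start = max(int(c) - half, region[0])
                    w_end = min(int(c) + half, region[1])
                    lo = np.searchsorted(starts_, w_start, side="left")
                    hi = np.searchsorted(starts_, w_end, side="left")
                    if hi - lo < cfg.min_probes or (lo, hi) in seen:
                        continue
                    seen.add((lo, hi))
                    rows.append(
                        (cid, info["chrom"], w_start, w_end, pid, info["gene_id"],
                         hi - lo, float(np.median(m[lo:hi])), np.nan, np.nan)
                    )
            else:
                w_start = region[0]
                while w_start < region[1]:
                    w_end = min(w_start + cfg.window_bp, region[1])
                    lo = np.searchsorted(starts_, w_start, side="left")
                    hi = np.searchsorted(starts_, w_end, side="left")
                    if hi - lo >= cfg.min_probes:
                        rows.append(
                            (cid, info["chrom"], w_start, w_end, pid, info["gene_id"],
                             hi - lo, float(np.median(m[lo:hi])), np.nan, np.nan)
                        )
                    w_start += cfg.window_bp
        if not matched:
            raise ValueError(f"no probes of comparison {cid!r} found in the design")
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def score_windows(stats_df: pd.DataFrame, cfg: WindowConfig = WindowConfig()) -> pd.DataFrame:
    """Score window medians against the empirical null of their comparison.

    Within each comparison, z = (median_m - mean) / sd where mean and sd are
    taken over the comparison's window medians — a normal null scaled to the
    experimental mean and SD — and p is the (two-sided by default) normal
    tail probability. The null SD of a window median shrinks with the number
    of member probes, so by default mean/sd are computed within windows of
    equal probe count (falling back to the pooled statistics for counts
    represented by fewer than 10 windows); set
    ``stratify_null_by_probe_count=False`` for one pooled null per
    comparison.
    """
    _MIN_CLASS = 10
    out = stats_df.copy()
    zs = np.empty(len(out))
    ps = np.empty(len(out))
    for cid, idx in out.groupby("comparison_id").groups.items():
        sub = out.loc[idx]
        med = sub["median_m"].to_numpy(dtype=float)
        if len(med) < 2:
            raise ValueError(f"comparison {cid!r}: need >=2 windows to define the null")
        mu_all, sd_all = med.mean(), med.std(ddof=1)
        if sd_all == 0:
            raise ValueError(f"comparison {cid!r}: degenerate null distribution (sd=0)")
        z = (med - mu_all) / sd_all
        if cfg.stratify_null_by_probe_count:
            counts = sub["probe_count"].to_numpy()
            for pc in np.unique(counts):
                sel = counts == pc
                if sel.sum() < _MIN_CLASS:
                    continue
                mu_c, sd_c = med[sel].mean(), med[sel].std(ddof=1)
                if sd_c > 0:
                    z[sel] = (med[sel] - mu_c) / sd_c
        p = 2.0 * stats.norm.sf(np.abs(z)) if cfg.two_sided else stats.norm.sf(z)
        pos = out.index.get_indexer(idx)
        zs[pos] = z
        ps[pos] = p
    out["z"] = zs
    out["p"] = ps
    return out


def call_dmrs(scored: pd.DataFrame, cfg: WindowConfig = WindowConfig()) -> pd.DataFrame:
    """Intersect scored windows across comparisons and merge into DMRs.

    A window is a candidate iff p < alpha in *every* comparison (and, when
    ``require_consistent_sign``, the sign of its median is identical across
    comparisons) — the all-paired-comparisons rule is the multiple-testing
    control. Candidate windows on the same promoter that overlap or lie
    within ``merge_gap_bp`` merge into one region; each region keeps its
    smallest p (``min_p``), per-comparison minima, and direction of change.
    """
    comparisons = sorted(scored["comparison_id"].unique())
    key = ["promoter_id", "start", "end"]
    pivot_p = scored.pivot_table(index=key, columns="comparison_id", values="p")
    pivot_m = scored.pivot_table(index=key, columns="comparison_id", values="median_m")
    if pivot_p.isna().any().any():
        raise ValueError("window universes differ across comparisons")
    sig = (pivot_p < cfg.alpha).all(axis=1)
    if cfg.require_consistent_sign:
        signs = np.sign(pivot_m)
        sig &= (signs.eq(signs.iloc[:, 0], axis=0)).all(axis=1)
    cand = pivot_p[sig]
    if cand.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)

    meta = scored.drop_duplicates(subset=key).set_index(key)[["chrom", "gene_id"]]
    cand = cand.reset_index().sort_values(["promoter_id", "start"], kind="stable")
    m_mean = pivot_m.mean(axis=1)

    regions = []
    for pid, grp in cand.groupby("promoter_id", sort=False):
        cur = None
        for _, row in grp.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if cur is not None and s <= cur["end"] + cfg.merge_gap_bp:
                cur["end"] = max(cur["end"], e)
                cur["windows"].append((pid, s, e))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {"promoter_id": pid, "start": s, "end": e, "windows": [(pid, s, e)]}
        if cur is not None:
            regions.append(cur)

    rows = []
    for reg in regions:
        keys = reg["windows"]
        sub_p = pivot_p.loc[keys]
        per_comp = [float(sub_p[c].min()) for c in comparisons]
        mm = float(m_mean.loc[keys].mean())
        chrom, gene = meta.loc[keys[0]]
        rows.append(
            (
                chrom,
                reg["start"],
                reg["end"],
                reg["promoter_id"],
                gene,
                len(keys),
                float(min(per_comp)),
                mm,
                "+" if mm > 0 else "-",
                per_comp,
            )
        )
    dmrs = pd.DataFrame(rows, columns=DMR_COLUMNS)
    return dmrs.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def summarize_by_chromosome(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Count DMRs per chromosome; counts sum to len(dmrs)."""
    if dmrs.empty:
        return pd.DataFrame(columns=["chrom", "n_dmrs"])
    counts = dmrs.groupby("chrom", sort=True).size().rename("n_dmrs").reset_index()
    return counts


def summarize_categories(dmrs: pd.DataFrame, gene_categories: dict) -> pd.DataFrame:
    """Tally DMR-associated genes by functional category.

    ``gene_categories`` maps gene_id -> category; unmapped genes count as
    "unknown". Genes are counted once per DMR row.
    """
    if dmrs.empty:
        return pd.DataFrame(columns=["category", "n_genes"])
    cats = dmrs["gene_id"].map(lambda g: gene_categories.get(g, "unknown"))
    return cats.value_counts().rename_axis("category").rename("n_genes").reset_index()


@dataclass(frozen=True)
class QPCRResult:
    fold_change: float
    p: float
    test: str


def qpcr_fold_change(
    treatment_quantities, control_quantities, test: str = "mann_whitney"
) -> QPCRResult:
    """MeDIP-QPCR confirmation: fold change of mean quantities plus a test.

    fold_change = mean(treatment) / mean(control); p from the Mann-Whitney
    rank-sum test (default) or Welch's t-test.
    """
    t = np.asarray(treatment_quantities, dtype=float)
    c = np.asarray(control_quantities, dtype=float)
    if len(t) == 0 or len(c) == 0:
        raise ValueError("both groups must be non-empty")
    if (t <= 0).any() or (c <= 0).any():
        raise ValueError("quantities must be positive")
    fc = float(t.mean() / c.mean())
    if test == "mann_whitney":
        p = float(stats.mannwhitneyu(t, c, alternative="two-sided").pvalue)
    elif test == "t_test":
        p = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return QPCRResult(fold_change=fc, p=p, test=test)
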