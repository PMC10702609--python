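"""Group statistics: edgewise FDR comparison and metric/ROI-level tests.

Edgewise procedure (per scope):

1. enumerate the scope's distinct region pairs (36·35/2 = 630 within a
   hemisphere, 36×36 across hemispheres);
2. exclude pairs where more than half of all subjects' observations are 0
   (pooled over both groups; exactly half stays in);
3. transform counts x ↦ ln(x + pseudocount), pseudocount 1, so zeros map to
   0 and the heavy right skew is tamed — the log base only rescales t's
   numerator and denominator together, so t and p are base-invariant;
4. equal-variance (pooled) two-sample t per included pair with
   df = n₁ + n₂ − 2 (the pooled test, not Welch, is what a stated
   df = 9 + 10 − 2 = 17 implies);
5. Benjamini–Hochberg step-up across the included pairs only; excluded
   pairs carry missing adjusted p;
6. the signed adjusted-p matrix carries +p_adj where the KO mean exceeds WT
   and −p_adj where WT exceeds KO.

Metric-level comparisons (clustering, small-worldness, efficiencies) use
unpaired two-tailed t-tests at α = 0.05 with no multiplicity correction
(four parameters, reported individually).  Per-ROI diffusion comparisons
(volume, FA, AD, MD, RD) use unpaired t-tests with the two-stage step-up
FDR procedure of Benjamini, Krieger & Yekutieli across ROIs within each
metric family: stage 1 runs BH at q′ = q/(1+q), the rejection count
estimates the number of true nulls m₀ = m − r₁, and stage 2 reruns BH at
q′·m/m₀.

Degenerate pairs (zero pooled variance) yield t = 0, p = 1 when the group
means agree, and p = 0 with a ``degenerate`` flag otherwise, so NaNs never
reach the FDR step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import RegionAtlas
from .connectome import SubjectConnectome, scope_count_matrix, scope_pairs, _scope_sides

__all__ = [
    "StatsConfig",
    "TTestResult",
    "BkyResult",
    "EdgewiseResult",
    "log_pseudocount_transform",
    "pooled_t_test",
    "bh_adjust",
    "bky_two_stage",
    "enumerate_and_filter_pairs",
    "edgewise_compare",
    "compare_network_params",
    "compare_roi_params",
    "split_hemispheres",
]

ROI_METRIC_COLUMNS = ("volume_mm3", "FA", "AD", "MD", "RD")


@dataclass(frozen=True)
class StatsConfig:
    zero_fraction_cutoff: float = 0.5
    pseudocount: float = 1.0
    fdr_q: float = 0.05
    significance_alpha: float = 0.05
    edgewise_procedure: str = "BH"
    roi_procedure: str = "BKY"

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction_cutoff <= 1.0:
            raise ValueError("zero_fraction_cutoff must be in [0, 1]")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.edgewise_procedure != "BH":
            raise ValueError("edgewise_procedure must be 'BH'")
        if self.roi_procedure != "BKY":
            raise ValueError("roi_procedure must be 'BKY'")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float
    degenerate: bool = False


class BkyResult(NamedTuple):
    reject: np.ndarray
    m0: int
    stage1_rejections: int


def log_pseudocount_transform(counts, config: StatsConfig | None = None):
    """x ↦ ln(x + pseudocount); zeros map to ln(pseudocount) (= 0 at 1)."""
    pc = (config or StatsConfig()).pseudocount
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    return np.log(x + pc)


def _pooled_t_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorized pooled t along axis 0 of (n1, m) vs (n2, m) arrays."""
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    ss = ((a - m1) ** 2).sum(axis=0) + ((b - m2) ** 2).sum(axis=0)
    sp2 = ss / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    degenerate = (se == 0) & (diff != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
    p = np.where(np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df))
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, df, p, degenerate


def pooled_t_test(group1: Sequence[float], group2: Sequence[float]) -> TTestResult:
    """Equal-variance two-sample t with df = n₁ + n₂ − 2, two-sided p.

    Zero pooled variance: equal means give t = 0, p = 1; unequal means give
    p = 0 flagged degenerate.
    """
    a = np.asarray(group1, dtype=float).reshape(-1, 1)
    b = np.asarray(group2, dtype=float).reshape(-1, 1)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 values")
    t, df, p, degen = _pooled_t_arrays(a, b)
    return TTestResult(float(t[0]), int(df), float(p[0]), bool(degen[0]))


def _validated_p(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p, rejection at level q).

    Adjusted values are p(k)·m/k made monotone from the largest rank down
    and capped at 1; rejection ⇔ adjusted ≤ q.
    """
    p = _validated_p(pvals)
    m = p.size
    if m == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out, out <= q


def bky_two_stage(pvals, q: float = 0.05) -> BkyResult:
    """Two-stage step-up FDR (Benjamini–Krieger–Yekutieli).

    Stage 1: BH at q′ = q/(1+q), giving r₁ rejections and the true-null
    estimate m₀ = m − r₁.  r₁ = 0 → nothing rejected; m₀ = 0 → everything
    rejected; otherwise stage 2 is BH at q′·m/m₀.
    """
    p = _validated_p(pvals)
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    if m == 0:
        return BkyResult(np.zeros(0, dtype=bool), 0, 0)
    q1 = q / (1.0 + q)
    _, stage1 = bh_adjust(p, q1)
    r1 = int(stage1.sum())
    m0 = m - r1
    if r1 == 0:
        return BkyResult(np.zeros(m, dtype=bool), m0, 0)
    if m0 == 0:
        return BkyResult(np.ones(m, dtype=bool), 0, r1)
    _, reject = bh_adjust(p, q1 * m / m0)
    return BkyResult(reject, m0, r1)


def enumerate_and_filter_pairs(counts: np.ndarray,
                               config: StatsConfig | None = None) -> pd.DataFrame:
    """Zero-fraction filter over a (subjects × pairs) count array.

    The zero fraction pools all subjects regardless of group; a pair is
    included iff its zero fraction is ≤ the cutoff (strictly greater
    excludes, so exactly 50% zeros stays in at the default cutoff).
    """
    cfg = config or StatsConfig()
    c = np.asarray(counts)
    if c.ndim != 2:
        raise ValueError("counts must be (n_subjects, n_pairs)")
    zf = (c == 0).mean(axis=0)
    return pd.DataFrame({
        "pair": np.arange(c.shape[1]),
        "zero_fraction": zf,
        "included": zf <= cfg.zero_fraction_cutoff,
    })


class EdgewiseResult(NamedTuple):
    table: pd.DataFrame
    signed_p: pd.DataFrame


def edgewise_compare(
    subjects: Sequence[SubjectConnectome],
    scope: str,
    atlas: RegionAtlas,
    config: StatsConfig | None = None,
) -> EdgewiseResult:
    """Filter → log-transform → pooled t → BH, with a signed adjusted-p matrix.

    Returns the per-pair table (excluded pairs keep missing t/p) and the
    signed matrix: entries ±p_adj with + where the KO log-mean exceeds WT,
    NaN on excluded pairs and the diagonal.  Ipsilateral scopes yield a
    symmetric 36×36 matrix; contralateral scopes the seed-side × opposite-
    side cross block.
    """
    cfg = config or StatsConfig()
    groups = np.array([s.group for s in subjects])
    n_wt = int((groups == "WT").sum())
    n_ko = int((groups == "KO").sum())
    if n_wt < 2 or n_ko < 2:
        raise ValueError("need at least 2 subjects per group")
    shapes = {s.counts.shape for s in subjects}
    if len(shapes) != 1 or next(iter(shapes))[0] != len(atlas):
        raise ValueError("subjects must share the atlas node set")

    counts = scope_count_matrix(subjects, scope, atlas)
    pairs = scope_pairs(scope, atlas)
    names = atlas.abbreviations
    filt = enumerate_and_filter_pairs(counts, cfg)
    inc = filt["included"].to_numpy()

    logc = log_pseudocount_transform(counts, cfg)
    wt = logc[groups == "WT"]
    ko = logc[groups == "KO"]
    n_pairs = counts.shape[1]
    t = np.full(n_pairs, np.nan)
    p = np.full(n_pairs, np.nan)
    p_adj = np.full(n_pairs, np.nan)
    degen = np.zeros(n_pairs, dtype=bool)
    mean_wt = wt.mean(axis=0)
    mean_ko = ko.mean(axis=0)
    df = n_wt + n_ko - 2
    if inc.any():
        t_i, _, p_i, degen_i = _pooled_t_arrays(ko[:, inc], wt[:, inc])  # KO − WT
        t[inc], p[inc], degen[inc] = t_i, p_i, degen_i
        p_adj[inc], _ = bh_adjust(p_i, cfg.fdr_q)
    sign = np.where(mean_ko >= mean_wt, 1, -1)

    table = pd.DataFrame({
        "region_a": [names[i] for i, _ in pairs],
        "region_b": [names[j] for _, j in pairs],
        "zero_fraction": filt["zero_fraction"].to_numpy(),
        "included": inc,
        "mean_log_wt": mean_wt,
        "mean_log_ko": mean_ko,
        "t": t,
        "df": df,
        "p": p,
        "p_adj": p_adj,
        "sign": sign,
        "degenerate": degen,
    })

    lat, side = _scope_sides(scope)
    if lat == "ipsi":
        labels = [r.abbreviation for r in atlas.hemisphere_subset(side)]
        mat = pd.DataFrame(np.nan, index=labels, columns=labels)
        for (i, j), pa, sg, ok in zip(pairs, p_adj, sign, inc):
            if ok:
                mat.loc[names[i], names[j]] = sg * pa
                mat.loc[names[j], names[i]] = sg * pa
    else:
        rows = [r.abbreviation for r in atlas.hemisphere_subset(side)]
        cols = [r.abbreviation
                for r in atlas.hemisphere_subset("R" if side == "L" else "L")]
        mat = pd.DataFrame(np.nan, index=rows, columns=cols)
        for (i, j), pa, sg, ok in zip(pairs, p_adj, sign, inc):
            if ok:
                mat.loc[names[i], names[j]] = sg * pa
    return EdgewiseResult(table=table, signed_p=mat)


def _fmt_group(mean: float, sd: float) -> str:
    return f"{mean:.3g} ± {sd:.2g}"


def compare_network_params(values: pd.DataFrame,
                           config: StatsConfig | None = None) -> pd.DataFrame:
    """Per-metric unpaired two-tailed t between groups, no multiplicity
    correction (the four network parameters are reported individually).

    ``values`` is tidy with columns ``group`` ∈ {WT, KO}, ``metric`` and
    ``value``; metrics with missing values drop those subjects with a
    warning.  Output mirrors the in-text style ("WT: 0.021 ± 0.004").
    """
    cfg = config or StatsConfig()
    required = {"group", "metric", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"values needs columns {sorted(required)}")
    rows = []
    for metric, sub in values.groupby("metric", sort=False):
        wt = sub.loc[sub["group"] == "WT", "value"].to_numpy(dtype=float)
        ko = sub.loc[sub["group"] == "KO", "value"].to_numpy(dtype=float)
        n_nan = int(np.isnan(wt).sum() + np.isnan(ko).sum())
        if n_nan:
            warnings.warn(f"metric {metric!r}: dropping {n_nan} missing values",
                          stacklevel=2)
            wt, ko = wt[~np.isnan(wt)], ko[~np.isnan(ko)]
        if wt.size < 2 or ko.size < 2:
            warnings.warn(f"metric {metric!r}: fewer than 2 values per group; skipped",
                          stacklevel=2)
            continue
        res = pooled_t_test(wt, ko)
        rows.append({
            "metric": metric,
            "n_wt": wt.size, "n_ko": ko.size,
            "wt_mean": wt.mean(), "wt_sd": wt.std(ddof=1),
            "ko_mean": ko.mean(), "ko_sd": ko.std(ddof=1),
            "wt_summary": _fmt_group(wt.mean(), wt.std(ddof=1)),
            "ko_summary": _fmt_group(ko.mean(), ko.std(ddof=1)),
            "t": res.t, "df": res.df, "p": res.p,
            "significant": res.p < cfg.significance_alpha,
        })
    return pd.DataFrame(rows)


def compare_roi_params(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    config: StatsConfig | None = None,
    value_columns: Sequence[str] = ROI_METRIC_COLUMNS,
) -> pd.DataFrame:
    """Per-ROI unpaired t per metric with BKY two-stage FDR across ROIs.

    ``table_a`` / ``table_b`` are long tables with a ``roi`` column and the
    metric value columns (one row per subject × ROI); the two sides may be
    groups (WT vs KO) or hemispheres (left vs right within strain).  The
    BKY correction runs across ROIs within each metric family.
    """
    cfg = config or StatsConfig()
    value_columns = [c for c in value_columns if c in table_a.columns]
    rois = sorted(table_a["roi"].unique())
    if rois != sorted(table_b["roi"].unique()):
        raise ValueError("ROI sets of the two tables do not match")
    rows = []
    for metric in value_columns:
        pvals, trows = [], []
        for roi in rois:
            a = table_a.loc[table_a["roi"] == roi, metric].to_numpy(dtype=float)
            b = table_b.loc[table_b["roi"] == roi, metric].to_numpy(dtype=float)
            res = pooled_t_test(a, b)
            pvals.append(res.p)
            trows.append({"metric": metric, "roi": roi,
                          "mean_a": a.mean(), "mean_b": b.mean(),
                          "t": res.t, "df": res.df, "p": res.p})
        bky = bky_two_stage(np.array(pvals), cfg.fdr_q)
        for row, rej in zip(trows, bky.reject):
            row["reject"] = bool(rej)
            row["m0_estimate"] = bky.m0
            rows.append(row)
    return pd.DataFrame(rows)


def split_hemispheres(table: pd.DataFrame,
                      atlas: RegionAtlas) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a per-ROI table into (left, right) with right ROIs re-keyed to
    their left homologs, so left-vs-right runs through compare_roi_params."""
    hemi = table["roi"].map(atlas.hemisphere_of)
    left = table[hemi == "L"].copy()
    right = table[hemi == "R"].copy()
    right["roi"] = right["roi"].map(atlas.homolog)
    return left, right
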