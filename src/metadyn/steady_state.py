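"""Steady-state fold-change statistics of the perturbation response.

For each retained metabolite the initial steady state (pre-step
replicates) is compared with the final one (last-time replicates, 2 h
after the step): fold-change fc = final/initial of the protein-normalized
mean pools, a pooled-variance two-sample t-test, Benjamini-Hochberg
correction per cell line at 5% FDR, and a volcano significance call that
additionally requires a biologically relevant change (|fc - 1| >= 30% by
default).  Cross-line reproducibility is summarized by the Pearson
correlation matrix of log2 fold-changes over shared metabolites.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import TimeSeries

__all__ = [
    "fold_change",
    "ttest_steady_states",
    "bh_adjust",
    "steady_state_table",
    "volcano_table",
    "pearson_fc_matrix",
]


def fold_change(ts: TimeSeries) -> tuple[float, float]:
    """fc = mean(final)/mean(initial) and its log2; NaN if not evaluable."""
    pre = ts.times < 0
    if not pre.any():
        return math.nan, math.nan
    pre_vals = ts.mean[pre]
    if not np.isfinite(pre_vals).any():
        return math.nan, math.nan
    initial = float(np.nanmean(pre_vals))
    final = float(ts.mean[-1])
    if not np.isfinite(initial) or not np.isfinite(final) or initial <= 0:
        return math.nan, math.nan
    fc = final / initial
    return fc, math.log2(fc) if fc > 0 else math.nan


def ttest_steady_states(initial, final) -> float:
    """Two-sided pooled-variance (Student) two-sample t-test p-value.

    Degenerate zero-variance cases follow the convention p = 1 for equal
    means and p = 0 otherwise.
    """
    a = np.asarray(initial, dtype=float)
    b = np.asarray(final, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per steady state")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def bh_adjust(pvalues, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject, q


def _endpoint_replicates(
    panel: pd.DataFrame,
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Pre-step and last-time replicate values per (cell line, metabolite)."""
    t_pre = panel["time_min"].min()
    t_fin = panel["time_min"].max()
    sub = panel[~panel["below_lod"] & panel["time_min"].isin([t_pre, t_fin])]
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (line, met), g in sub.groupby(["cell_line", "metabolite"], sort=False):
        ini = g.loc[g["time_min"] == t_pre, "value"].to_numpy()
        fin = g.loc[g["time_min"] == t_fin, "value"].to_numpy()
        out[(line, met)] = (ini, fin)
    return out


def steady_state_table(
    series: dict[tuple[str, str], TimeSeries],
    normalized_panel: pd.DataFrame,
    outliers: pd.DataFrame | None = None,
    fdr: float = 0.05,
    fc_margin: float = 0.30,
    pooled_family: bool = False,
) -> pd.DataFrame:
    """Per-(line, metabolite) fold-change / test / significance table.

    BH correction is applied per cell line across its retained
    metabolites (``pooled_family=True`` pools all lines into one family).
    Significance requires BH rejection AND |fc - 1| >= ``fc_margin``.
    """
    from .preprocess import _drop_flagged

    panel = _drop_flagged(normalized_panel, outliers)
    endpoints = _endpoint_replicates(panel)
    rows = []
    for (line, met), ts in series.items():
        fc, l2 = fold_change(ts)
        ini, fin = endpoints.get((line, met), (np.zeros(0), np.zeros(0)))
        if ini.size >= 2 and fin.size >= 2 and np.isfinite(fc):
            p = ttest_steady_states(ini, fin)
        else:
            p = math.nan
        rows.append(
            {
                "cell_line": line,
                "metabolite": met,
                "met_class": ts.met_class,
                "fc": fc,
                "log2fc": l2,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    df["reject"] = False
    groups = [df.index] if pooled_family else [
        df.index[df["cell_line"] == ln] for ln in df["cell_line"].unique()
    ]
    for idx in groups:
        ok = idx[np.isfinite(df.loc[idx, "p"])]
        if len(ok):
            rej, q = bh_adjust(df.loc[ok, "p"].to_numpy(), fdr=fdr)
            df.loc[ok, "q"] = q
            df.loc[ok, "reject"] = rej
    df["significant"] = df["reject"] & (np.abs(df["fc"] - 1.0) >= fc_margin)
    df["direction"] = np.where(
        ~df["significant"], "unchanged", np.where(df["fc"] > 1.0, "up", "down")
    )
    return df


def volcano_table(ss: pd.DataFrame) -> pd.DataFrame:
    """Volcano coordinates: log2 fold-change vs -log10 of raw and adjusted p."""
    out = ss[["cell_line", "metabolite", "met_class", "log2fc", "significant", "direction"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(ss["p"])
        out["neg_log10_q"] = -np.log10(ss["q"])
    return out


def pearson_fc_matrix(ss: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pearson correlation of log2 fold-changes between cell lines.

    Computed over metabolites retained in both lines of each pair; pairs
    sharing fewer than ``min_shared`` metabolites are marked NaN.
    """
    lines = list(ss["cell_line"].unique())
    wide = ss.pivot_table(index="metabolite", columns="cell_line", values="log2fc")
    mat = pd.DataFrame(np.eye(len(lines)), index=lines, columns=lines)
    for i, a in enumerate(lines):
        for b in lines[i + 1 :]:
            sub = wide[[a, b]].dropna()
            if len(sub) < min_shared:
                r = math.nan
            else:
                r = float(np.corrcoef(sub[a], sub[b])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
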