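"""Cell-type discrimination from steady-state features of metabolite pairs.

For every unordered pair of cell lines and every co-retained metabolite,
three per-metabolite distances are computed — on the initial steady
state, the final steady state, and the fold-change — as the absolute
log2 ratio of the feature between the two lines (an absolute-difference
variant is selectable).  Pairs of lines of different cell types are the
positive class; a threshold sweep over each distance yields a ROC curve
and its AUC, quantifying which feature best separates cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = ["PairScore", "ROCResult", "FEATURES", "build_pairs", "roc_auc"]

FEATURES = ("initial", "final", "fold_change")


@dataclass
class PairScore:
    metabolite: str
    pair: tuple[str, str]
    label: bool  # True = lines of different cell types
    scores: dict[str, float]


@dataclass
class ROCResult:
    feature: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _features_table(ss: pd.DataFrame, normalized_panel: pd.DataFrame) -> pd.DataFrame:
    """Per-(line, metabolite) initial/final steady-state levels and fc."""
    rows = []
    for (line, met), sub in normalized_panel.groupby(["cell_line", "metabolite"], sort=False):
        sub = sub[~sub["below_lod"]]
        if sub.empty:
            continue
        ini = sub.loc[sub["time_min"] == sub["time_min"].min(), "value"].mean()
        fin = sub.loc[sub["time_min"] == sub["time_min"].max(), "value"].mean()
        rows.append({"cell_line": line, "metabolite": met, "initial": ini, "final": fin})
    feats = pd.DataFrame(rows)
    return feats.merge(
        ss[["cell_line", "metabolite", "fc"]], on=["cell_line", "metabolite"], how="inner"
    ).rename(columns={"fc": "fold_change"})


def build_pairs(
    ss: pd.DataFrame,
    normalized_panel: pd.DataFrame,
    cell_types: dict[str, str],
    distance: str = "log_ratio",
) -> list[PairScore]:
    """Score every (metabolite, line pair) instance on the three features.

    ``distance`` is ``log_ratio`` (|log2(a/b)|, default) or ``abs_diff``.
    Non-positive feature values are skipped for the log-ratio distance.
    """
    feats = _features_table(ss, normalized_panel)
    lines = sorted(ss["cell_line"].unique())
    wide = {f: feats.pivot_table(index="metabolite", columns="cell_line", values=f) for f in FEATURES}

    out: list[PairScore] = []
    for a, b in combinations(lines, 2):
        label = cell_types[a] != cell_types[b]
        mets = wide["fold_change"][[a, b]].dropna().index
        for met in mets:
            scores = {}
            for f in FEATURES:
                try:
                    va, vb = float(wide[f].loc[met, a]), float(wide[f].loc[met, b])
                except KeyError:
                    continue
                if distance == "log_ratio":
                    if va > 0 and vb > 0:
                        scores[f] = abs(np.log2(va / vb))
                else:
                    scores[f] = abs(va - vb)
            if scores:
                out.append(PairScore(met, (a, b), label, scores))
    return out


def roc_auc(pairs: list[PairScore], feature: str) -> ROCResult:
    """ROC curve and trapezoid AUC for one feature's distance scores.

    The AUC equals the Mann-Whitney probability that a different-type
    pair scores above a same-type pair, with half credit for ties.
    """
    labels, scores = [], []
    for p in pairs:
        if feature in p.scores and np.isfinite(p.scores[feature]):
            labels.append(p.label)
            scores.append(p.scores[feature])
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("need both same-type and different-type pairs")
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(feature, fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)))
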