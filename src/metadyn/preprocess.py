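"""Quality control and reduction of replicate-level quantification panels.

Stages, in order: protein normalization (µM in extract -> mol per µg of
pellet protein), leave-one-out detection of mistreated replicate samples
(replicate RSD above 10% that a single sample removal repairs, across a
breadth of metabolites), per-metabolite quality filtering (too many
below-LOD/missing time points, or replicate CV above 15%), and averaging
to per-time-point trajectories with standard deviations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "normalize_to_protein",
    "detect_outlier_samples",
    "filter_metabolites",
    "average_timepoints",
    "preprocess_panel",
]


@dataclass
class TimeSeries:
    """Averaged protein-normalized trajectory of one metabolite in one line."""

    metabolite: str
    cell_line: str
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    met_class: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def normalize_to_protein(panel: pd.DataFrame, extract_volume: float = 1.0) -> pd.DataFrame:
    """Add a ``value`` column: conc_uM * extract_volume / protein_ug.

    Records with non-positive protein are dropped with a warning (they
    cannot be normalized).  Below-LOD flags are preserved.
    """
    bad = panel["protein_ug"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} records with non-positive protein")
        panel = panel.loc[~bad]
    out = panel.copy()
    out["value"] = out["conc_uM"] * extract_volume / out["protein_ug"]
    return out


def _rsd(values: np.ndarray) -> float:
    m = np.mean(values)
    if m == 0:
        return math.inf if np.std(values) > 0 else 0.0
    return float(np.std(values, ddof=1) / abs(m))


def detect_outlier_samples(
    panel: pd.DataFrame,
    rsd_limit: float = 0.10,
    breadth: float = 0.5,
) -> pd.DataFrame:
    """Flag mistreated replicate samples by leave-one-out RSD repair.

    A sample (cell line, time, replicate) is flagged when, for at least a
    ``breadth`` fraction of metabolites measured at that time point, the
    replicate RSD of the protein-normalized value exceeds ``rsd_limit``
    with the sample included and drops to <= ``rsd_limit`` without it.
    ``breadth=1.0`` gives the literal "across all metabolites" reading.

    Returns a report with one row per flagged sample.  Raises if a time
    point would be left with fewer than 2 replicates, and warns when high
    RSDs exist that no single removal repairs.
    """
    if "value" not in panel.columns:
        raise ValueError("panel must be protein-normalized first")
    rows = []
    for (line, t), sub in panel.groupby(["cell_line", "time_min"], sort=False):
        wide = sub.pivot_table(index="metabolite", columns="replicate", values="value")
        wide = wide.dropna(axis=0)
        reps = list(wide.columns)
        if len(reps) < 3:
            raise ValueError(f"need >= 3 replicates at ({line}, {t}) for outlier detection")
        vals = wide.to_numpy()
        rsd_all = np.array([_rsd(v) for v in vals])
        high = rsd_all > rsd_limit
        repaired_by_any = np.zeros(vals.shape[0], dtype=bool)
        flagged_here = []
        for j, rep in enumerate(reps):
            keep = [k for k in range(len(reps)) if k != j]
            rsd_wo = np.array([_rsd(v[keep]) for v in vals])
            repair = high & (rsd_wo <= rsd_limit)
            repaired_by_any |= repair
            if vals.shape[0] > 0 and np.mean(repair) >= breadth:
                flagged_here.append((rep, float(np.mean(repair))))
        if len(reps) - len(flagged_here) < 2:
            raise ValueError(
                f"outlier removal would leave < 2 replicates at ({line}, {t})"
            )
        unrepaired = high & ~repaired_by_any
        if np.mean(high) >= breadth and not flagged_here and unrepaired.any():
            warnings.warn(
                f"QC: discordant replicates at ({line}, {t}) — high RSD for "
                f"{int(high.sum())}/{high.size} metabolites but no single-sample "
                "removal repairs them; nothing flagged"
            )
        for rep, frac in flagged_here:
            rows.append(
                {
                    "cell_line": line,
                    "time_min": t,
                    "replicate": rep,
                    "fraction_repaired": frac,
                }
            )
    return pd.DataFrame(rows, columns=["cell_line", "time_min", "replicate", "fraction_repaired"])


def _drop_flagged(panel: pd.DataFrame, outliers: pd.DataFrame | None) -> pd.DataFrame:
    if outliers is None or outliers.empty:
        return panel
    key = set(zip(outliers["cell_line"], outliers["time_min"], outliers["replicate"]))
    mask = [
        (ln, t, r) in key
        for ln, t, r in zip(panel["cell_line"], panel["time_min"], panel["replicate"])
    ]
    return panel.loc[~np.asarray(mask)]


def filter_metabolites(
    panel: pd.DataFrame,
    lod_max_timepoints: int | None = None,
    cv_limit: float = 0.15,
    outliers: pd.DataFrame | None = None,
    cv_across_time: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line metabolite quality filter.

    A metabolite is excluded for a cell line when (a) at least
    ``lod_max_timepoints`` time points are below the LOD or missing
    (default: ceil(0.625 * n_timepoints), i.e. 5 of 8), or (b) its CV
    statistic exceeds ``cv_limit``.  The default CV statistic is the mean
    over time points of the replicate RSD; ``cv_across_time=True``
    selects the alternative reading (RSD of the time-point means across
    time), which penalizes genuinely dynamic metabolites.

    Returns (retained, report): retained has columns (cell_line,
    metabolite), report lists each exclusion with its reason.
    """
    if "value" not in panel.columns:
        raise ValueError("panel must be protein-normalized first")
    panel = _drop_flagged(panel, outliers)
    n_tp = panel["time_min"].nunique()
    if lod_max_timepoints is None:
        lod_max_timepoints = math.ceil(0.625 * n_tp)

    kept, excluded = [], []
    for (line, met), sub in panel.groupby(["cell_line", "metabolite"], sort=False):
        by_t = sub.groupby("time_min")
        bad_tp = 0
        rsds = []
        means = []
        for _, g in by_t:
            ok = g.loc[~g["below_lod"], "value"].to_numpy()
            ok = ok[np.isfinite(ok)]
            if ok.size > g["below_lod"].size / 2:
                means.append(np.mean(ok))
                if ok.size >= 2:
                    rsds.append(_rsd(ok))
            else:
                bad_tp += 1
        n_missing_grid = n_tp - len(by_t)  # time points absent entirely
        bad_tp += n_missing_grid
        if bad_tp >= lod_max_timepoints:
            excluded.append({"cell_line": line, "metabolite": met, "reason": "LOD"})
            continue
        if cv_across_time:
            cv = _rsd(np.asarray(means)) if len(means) >= 2 else math.inf
        else:
            cv = float(np.mean(rsds)) if rsds else math.inf
        if cv > cv_limit:
            excluded.append({"cell_line": line, "metabolite": met, "reason": "CV"})
            continue
        kept.append({"cell_line": line, "metabolite": met})

    retained = pd.DataFrame(kept, columns=["cell_line", "metabolite"])
    report = pd.DataFrame(excluded, columns=["cell_line", "metabolite", "reason"])
    if retained.empty:
        warnings.warn("no metabolites retained after filtering")
    return retained, report


def average_timepoints(
    panel: pd.DataFrame,
    retained: pd.DataFrame | None = None,
    outliers: pd.DataFrame | None = None,
) -> dict[tuple[str, str], TimeSeries]:
    """Mean/SD/n per time point over surviving replicates.

    Below-LOD values are excluded from the averages; a time point with no
    surviving value is reported as NaN with n = 0.  Keys are
    (cell_line, metabolite).
    """
    if "value" not in panel.columns:
        raise ValueError("panel must be protein-normalized first")
    panel = _drop_flagged(panel, outliers)
    if retained is not None:
        keep = set(zip(retained["cell_line"], retained["metabolite"]))
        mask = [
            (ln, m) in keep for ln, m in zip(panel["cell_line"], panel["metabolite"])
        ]
        panel = panel.loc[np.asarray(mask)]

    times_all = np.sort(panel["time_min"].unique())
    out: dict[tuple[str, str], TimeSeries] = {}
    for (line, met), sub in panel.groupby(["cell_line", "metabolite"], sort=False):
        cls = sub["met_class"].iloc[0]
        mean = np.full(times_all.size, np.nan)
        sd = np.full(times_all.size, np.nan)
        n = np.zeros(times_all.size, dtype=int)
        for i, t in enumerate(times_all):
            g = sub.loc[sub["time_min"] == t]
            vals = g.loc[~g["below_lod"], "value"].to_numpy()
            vals = vals[np.isfinite(vals)]
            n[i] = vals.size
            if vals.size:
                mean[i] = np.mean(vals)
                sd[i] = np.std(vals, ddof=1) if vals.size > 1 else 0.0
        out[(line, met)] = TimeSeries(met, line, times_all, mean, sd, n, met_class=cls)
    return out


def preprocess_panel(
    panel: pd.DataFrame,
    extract_volume: float = 1.0,
    rsd_limit: float = 0.10,
    breadth: float = 0.5,
    lod_max_timepoints: int | None = None,
    cv_limit: float = 0.15,
) -> tuple[dict[tuple[str, str], TimeSeries], dict[str, pd.DataFrame]]:
    """Run the full QC chain; returns trajectories and the QC reports."""
    norm = normalize_to_protein(panel, extract_volume)
    outliers = detect_outlier_samples(norm, rsd_limit=rsd_limit, breadth=breadth)
    retained, exclusions = filter_metabolites(
        norm, lod_max_timepoints=lod_max_timepoints, cv_limit=cv_limit, outliers=outliers
    )
    series = average_timepoints(norm, retained=retained, outliers=outliers)
    reports = {"outliers": outliers, "exclusions": exclusions, "retained": retained, "normalized": norm}
    return series, reports
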