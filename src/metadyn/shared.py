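"""Cross-cell-line shared dynamics: joint fits, Venn regions, renormalization.

A metabolite has *shared dynamics* over a group of cell lines when one
set of shape parameters (scenario, tau_a and tau1/tau2 or tau/zeta) fits
every member line's trajectory, with only the steady-state gain K free
per line.  All line groups of size >= 2 are fit jointly (11 groups for
four lines: one 4-line, four 3-line, six 2-line); a group is accepted
when every member's mean fitting error is at or below the shared
threshold (4% by default).  The Venn-region assignment reports, per
metabolite, all accepted groups and the *specific* region: the unique
accepted group of maximal size (ties leave the metabolite ambiguous).

Intracellular glutamine, driven directly by the extracellular step, is
expected to share its shape across all lines; its joint fit doubles as a
per-time-point calibration — trajectories of configured lines are
renormalized by simulated/observed glutamine at each time point to
cancel sample-wise quantification artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares

from .dynamics import (
    OVERDAMPED,
    UNDERDAMPED,
    FitResult,
    ModelParams,
    _decode,
    _logit,
    _weights,
    mean_fitting_error,
    step_response,
)
from .preprocess import TimeSeries

__all__ = [
    "SharedFit",
    "VennAssignment",
    "line_groups",
    "glutamine_normalize",
    "fit_shared",
    "venn_assign",
    "threshold_sweep",
]


@dataclass
class SharedFit:
    """Joint fit of one metabolite over a group with shared shape, free gains."""

    metabolite: str
    group: tuple[str, ...]
    scenario: str | None
    shape: dict  # tau_a + tau1/tau2 or tau/zeta
    gains: dict[str, float]
    errors: dict[str, float]  # per-line mean fitting error, percent
    accepted: bool
    converged: bool = True

    def params_for(self, line: str) -> ModelParams:
        if self.scenario == OVERDAMPED:
            return ModelParams.overdamped(
                self.gains[line], self.shape["tau_a"], self.shape["tau1"], self.shape["tau2"]
            )
        return ModelParams.underdamped(
            self.gains[line], self.shape["tau_a"], self.shape["tau"], self.shape["zeta"]
        )


@dataclass
class VennAssignment:
    """Accepted Venn regions of one metabolite and its maximal specific claim."""

    metabolite: str
    accepted_regions: list[tuple[str, ...]]
    specific_region: tuple[str, ...] | None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.specific_region is not None and self.specific_region not in self.accepted_regions:
            raise ValueError("specific region must be one of the accepted regions")


def line_groups(lines: list[str], min_size: int = 2) -> list[tuple[str, ...]]:
    """All subsets of the cell lines with size >= min_size, largest first."""
    out: list[tuple[str, ...]] = []
    for k in range(len(lines), min_size - 1, -1):
        out.extend(combinations(lines, k))
    return out


def glutamine_normalize(
    ts: TimeSeries, gln_simulated: np.ndarray, gln_observed: np.ndarray
) -> TimeSeries:
    """Rescale a trajectory by simulated/observed glutamine per time point.

    Cancels sample-wise multiplicative quantification artifacts shared by
    all metabolites of a sample.  Points with non-positive observed
    glutamine become missing.
    """
    obs = np.asarray(gln_observed, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(obs > 0, np.asarray(gln_simulated, dtype=float) / obs, np.nan)
    return TimeSeries(
        ts.metabolite,
        ts.cell_line,
        ts.times,
        ts.mean * ratio,
        ts.sd * np.abs(ratio),
        ts.n,
        met_class=ts.met_class,
    )


def _joint_resid(
    theta: np.ndarray,
    scenario: str,
    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray, float, float]],
    k: int,
    weighted: bool,
) -> np.ndarray:
    """Residuals over concatenated per-line trajectories.

    theta = [K_1..K_k, tau_a, shape...]; blocks hold (t, y, w, y0, M).
    """
    parts = []
    for g, (t, y, w, y0, M) in enumerate(blocks):
        shape_theta = np.concatenate(([theta[g], theta[k]], theta[k + 1 :]))
        try:
            p = _decode(shape_theta, scenario)
        except (ValueError, OverflowError):
            parts.append(np.full(t.size, 1e6))
            continue
        r = (y0 + step_response(p, M, t)) - y
        if weighted:
            r = r * w
        parts.append(np.where(np.isfinite(r), r, 1e6))
    return np.concatenate(parts)


def fit_shared(
    series_by_line: dict[str, TimeSeries],
    M_by_line: dict[str, float],
    *,
    threshold: float = 4.0,
    n_starts: int = 4,
    seed: int = 0,
    init: FitResult | None = None,
    scenario_tie_rtol: float = 0.01,
) -> SharedFit:
    """Joint SD-weighted fit with one shape set and per-line gains.

    The scenario is chosen jointly (best joint weighted residual, ties
    toward overdamped).  ``init`` optionally seeds the shape from the
    best individual fit.  Acceptance requires every member line's mean
    fitting error <= ``threshold`` percent.
    """
    group = tuple(series_by_line)
    if len(group) < 2:
        raise ValueError("shared fit needs >= 2 cell lines")
    met = next(iter(series_by_line.values())).metabolite

    blocks = []
    K0s = []
    for line in group:
        ts = series_by_line[line]
        ok = np.isfinite(ts.mean)
        t, y, s = ts.times[ok], ts.mean[ok], ts.sd[ok]
        pre = t < 0
        if not pre.any():
            raise ValueError(f"no pre-step point for {line}")
        y0 = float(np.mean(y[pre]))
        M = M_by_line[line]
        blocks.append((t, y, _weights(s, y), y0, M))
        K0s.append((float(y[-1]) - y0) / M)
    k = len(group)
    rng = np.random.default_rng(seed)

    def starts_for(scenario: str) -> list[np.ndarray]:
        st = []
        if init is not None and init.params is not None and init.params.scenario == scenario:
            p = init.params
            if scenario == OVERDAMPED:
                shape = [p.tau_a, math.log(p.tau1), math.log(p.tau2)]
            else:
                shape = [p.tau_a, math.log(p.tau), _logit(p.zeta)]
            st.append(np.array(K0s + shape))
        if scenario == OVERDAMPED:
            st.append(np.array(K0s + [1.0, math.log(20.0), math.log(5.0)]))
        else:
            st.append(np.array(K0s + [1.0, math.log(15.0), _logit(0.6)]))
        while len(st) < n_starts:
            Ks = [K * rng.uniform(0.5, 1.5) for K in K0s]
            ta = rng.uniform(-5.0, 15.0)
            if scenario == OVERDAMPED:
                st.append(np.array(Ks + [ta, math.log(rng.uniform(5, 60)), math.log(rng.uniform(1, 20))]))
            else:
                st.append(np.array(Ks + [ta, math.log(rng.uniform(2, 40)), _logit(rng.uniform(0.15, 0.95))]))
        return st

    best: dict[str, tuple[np.ndarray | None, float]] = {}
    for scenario in (OVERDAMPED, UNDERDAMPED):
        btheta, bcost = None, math.inf
        for x0 in starts_for(scenario):
            try:  # stage 1 unweighted
                s1 = least_squares(
                    _joint_resid, x0, args=(scenario, blocks, k, False), method="lm", max_nfev=400
                )
            except Exception:
                continue
            if s1.cost < bcost:
                btheta, bcost = s1.x, s1.cost
        if btheta is not None:
            try:  # stage 2 weighted
                s2 = least_squares(
                    _joint_resid, btheta, args=(scenario, blocks, k, True), method="lm", max_nfev=400
                )
                btheta = s2.x
            except Exception:
                pass
            bcost = float(np.sum(_joint_resid(btheta, scenario, blocks, k, True) ** 2))
        best[scenario] = (btheta, bcost)

    th_o, c_o = best[OVERDAMPED]
    th_u, c_u = best[UNDERDAMPED]
    if th_o is None and th_u is None:
        return SharedFit(met, group, None, {}, {}, {ln: math.inf for ln in group}, False, False)
    if th_u is None or (th_o is not None and c_o <= c_u * (1.0 + scenario_tie_rtol)):
        scenario, theta = OVERDAMPED, th_o
    else:
        scenario, theta = UNDERDAMPED, th_u

    gains, errors = {}, {}
    shape_ref = None
    for g, line in enumerate(group):
        t, y, w, y0, M = blocks[g]
        shape_theta = np.concatenate(([theta[g], theta[k]], theta[k + 1 :]))
        p = _decode(shape_theta, scenario)
        shape_ref = p
        gains[line] = p.K
        fitted = y0 + step_response(p, M, t)
        errors[line] = mean_fitting_error(fitted, y)
    if scenario == OVERDAMPED:
        shape = {"tau_a": shape_ref.tau_a, "tau1": shape_ref.tau1, "tau2": shape_ref.tau2}
    else:
        shape = {"tau_a": shape_ref.tau_a, "tau": shape_ref.tau, "zeta": shape_ref.zeta}
    accepted = all(e <= threshold for e in errors.values())
    return SharedFit(met, group, scenario, shape, gains, errors, accepted)


def venn_assign(
    metabolite: str,
    accepted_by_group: dict[tuple[str, ...], bool],
) -> VennAssignment:
    """Assign the Venn region: all accepted groups plus the maximal claim.

    The specific region is the unique accepted group whose size is not
    matched or exceeded by any other accepted group; equal-size ties
    leave the metabolite without a specific region (ambiguous).
    """
    accepted = [g for g, ok in accepted_by_group.items() if ok]
    if not accepted:
        return VennAssignment(metabolite, [], None)
    sizes = [len(g) for g in accepted]
    top = max(sizes)
    winners = [g for g in accepted if len(g) == top]
    if len(winners) == 1:
        return VennAssignment(metabolite, accepted, winners[0])
    return VennAssignment(metabolite, accepted, None, ambiguous=True)


def threshold_sweep(
    errors_by_group: dict[str, dict[tuple[str, ...], dict[str, float]]],
    thresholds,
) -> "pd.DataFrame":
    """Accepted-metabolite counts per group across error thresholds.

    ``errors_by_group[metabolite][group]`` maps lines to per-line mean
    fitting errors; a metabolite counts for a group at a threshold when
    every member error is <= threshold.  Counts are monotone
    non-decreasing in the threshold.
    """
    import pandas as pd

    groups = sorted(
        {g for per_met in errors_by_group.values() for g in per_met}, key=lambda g: (-len(g), g)
    )
    rows = []
    for thr in thresholds:
        row = {"threshold": thr}
        for g in groups:
            row["+".join(g)] = sum(
                1
                for per_met in errors_by_group.values()
                if g in per_met and all(e <= thr for e in per_met[g].values())
            )
        rows.append(row)
    return pd.DataFrame(rows)
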