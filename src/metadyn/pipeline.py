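"""End-to-end orchestration of the dynamic-metabolomics analysis.

Chains the stages — simulate (optional), preprocess, steady-state,
individual fits, shared dynamics, cell-type classification — under one
configuration with a single seed, writing TSV tables and a run manifest
(versions, seed, config hash, per-stage record counts).  Fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discriminate import FEATURES, build_pairs, roc_auc
from .dynamics import damping_coefficient, fit_metabolite, settling_time
from .preprocess import (
    average_timepoints,
    detect_outlier_samples,
    filter_metabolites,
    normalize_to_protein,
)
from .shared import fit_shared, glutamine_normalize, line_groups, threshold_sweep, venn_assign
from .steady_state import pearson_fc_matrix, steady_state_table, volcano_table
from .synthetic import (
    DEFAULT_CELL_TYPES,
    PANEL_COLUMNS,
    SimConfig,
    generate_panel,
    ground_truth_table,
    make_metabolome,
    simulate_true_curve,
)

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    """One run: inputs, step magnitudes, type map, thresholds, seed, output."""

    out_dir: str = "metadyn_out"
    panel_path: str | None = None  # None -> simulate a synthetic panel
    simulate: bool = True
    n_metabolites: int = 201
    step_mM: dict[str, float] = field(default_factory=lambda: {ln: 12.5 for ln in DEFAULT_CELL_TYPES})
    cell_types: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    gln_initial_mM: float = 2.5
    gln_final_mM: float = 15.0
    # thresholds, all as the analysis defaults
    outlier_rsd: float = 0.10
    outlier_breadth: float = 0.5
    cv_limit: float = 0.15
    lod_max_timepoints: int | None = None
    fc_margin: float = 0.30
    fdr: float = 0.05
    fit_error_threshold: float = 5.0
    shared_error_threshold: float = 4.0
    settling_band: float = 0.05
    extract_volume: float = 1.0
    n_starts: int = 8
    shared_n_starts: int = 3
    glutamine_name: str = "Gln"
    normalize_lines: tuple[str, ...] | None = None  # default: the hNSC lines
    run_shared: bool = True
    run_classify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("outlier_rsd", 0, 1),
            ("cv_limit", 0, 1),
            ("fdr", 0, 1),
            ("fc_margin", 0, 10),
            ("settling_band", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        for ln in self.step_mM:
            if ln not in self.cell_types:
                raise ValueError(f"cell line {ln!r} has no cell-type annotation")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _sim_config(cfg: RunConfig) -> SimConfig:
    lines = tuple(cfg.step_mM)
    return SimConfig(
        cell_lines=lines,
        cell_types={ln: cfg.cell_types[ln] for ln in lines},
        step_mM=dict(cfg.step_mM),
        gln_initial_mM=cfg.gln_initial_mM,
        gln_final_mM=cfg.gln_final_mM,
        extract_volume=cfg.extract_volume,
        seed=cfg.seed,
    )


def run_all(cfg: RunConfig, metabolites=None) -> dict:
    """Execute the configured stages; returns the run manifest dict.

    ``metabolites`` optionally injects a pre-built ground-truth
    metabolome for the simulate stage (otherwise the default planted
    design of ``cfg.n_metabolites`` metabolites is used).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "metadyn_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }

    # --- stage: simulate or load -------------------------------------------
    truth = None
    if cfg.panel_path is not None:
        panel = pd.read_csv(cfg.panel_path, sep="\t")
        missing = set(PANEL_COLUMNS) - set(panel.columns)
        if missing:
            raise ValueError(f"panel is missing columns: {sorted(missing)}")
    elif cfg.simulate:
        sim = _sim_config(cfg)
        if metabolites is None:
            metabolites = make_metabolome(sim, n_total=cfg.n_metabolites)
        panel = generate_panel(sim, metabolites)
        truth = ground_truth_table(metabolites, sim)
        panel.to_csv(out / "panel.tsv", sep="\t", index=False)
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    else:
        raise ValueError("either panel_path or simulate must be set")
    manifest["stages"]["panel"] = {"records": int(len(panel))}

    # --- stage: preprocess --------------------------------------------------
    norm = normalize_to_protein(panel, cfg.extract_volume)
    outliers = detect_outlier_samples(norm, rsd_limit=cfg.outlier_rsd, breadth=cfg.outlier_breadth)
    retained, exclusions = filter_metabolites(
        norm, lod_max_timepoints=cfg.lod_max_timepoints, cv_limit=cfg.cv_limit, outliers=outliers
    )
    series = average_timepoints(norm, retained=retained, outliers=outliers)
    outliers.to_csv(out / "outlier_samples.tsv", sep="\t", index=False)
    exclusions.to_csv(out / "excluded_metabolites.tsv", sep="\t", index=False)
    retained.to_csv(out / "retained_metabolites.tsv", sep="\t", index=False)
    ts_rows = []
    for (line, met), ts in series.items():
        for i, t in enumerate(ts.times):
            ts_rows.append(
                {
                    "cell_line": line,
                    "metabolite": met,
                    "met_class": ts.met_class,
                    "time_min": t,
                    "mean": ts.mean[i],
                    "sd": ts.sd[i],
                    "n": ts.n[i],
                }
            )
    pd.DataFrame(ts_rows).to_csv(out / "timeseries.tsv", sep="\t", index=False)
    manifest["stages"]["preprocess"] = {
        "outlier_samples": int(len(outliers)),
        "excluded_metabolites": int(len(exclusions)),
        "retained": int(len(retained)),
        "retained_per_line": {
            ln: int((retained["cell_line"] == ln).sum()) for ln in cfg.step_mM
        },
    }

    # --- stage: steady state ------------------------------------------------
    ss = steady_state_table(
        series, norm, outliers=outliers, fdr=cfg.fdr, fc_margin=cfg.fc_margin
    )
    ss.to_csv(out / "steady_state.tsv", sep="\t", index=False)
    volcano_table(ss).to_csv(out / "volcano.tsv", sep="\t", index=False)
    pearson = pearson_fc_matrix(ss)
    pearson.to_csv(out / "pearson_fc.tsv", sep="\t")
    manifest["stages"]["steady_state"] = {
        "tested": int(np.isfinite(ss["p"]).sum()),
        "significant": int(ss["significant"].sum()),
    }

    # --- stage: individual fits --------------------------------------------
    fits: dict[tuple[str, str], object] = {}
    fit_rows = []
    for (line, met), ts in series.items():
        M = cfg.step_mM[line]
        try:
            fr = fit_metabolite(
                ts.times,
                ts.mean,
                ts.sd,
                M=M,
                error_threshold=cfg.fit_error_threshold,
                n_starts=cfg.n_starts,
                seed=_stable_seed(cfg.seed, line, met),
            )
        except ValueError:
            continue
        fits[(line, met)] = fr
        p = fr.params
        row = {
            "cell_line": line,
            "metabolite": met,
            "met_class": ts.met_class,
            "scenario": fr.scenario,
            "K": p.K if p else math.nan,
            "tau_a": p.tau_a if p else math.nan,
            "tau1": p.tau1 if p else None,
            "tau2": p.tau2 if p else None,
            "tau": p.tau if p else None,
            "zeta": p.zeta if p else None,
            "mean_fit_error": fr.mean_fit_error,
            "accepted": fr.accepted,
        }
        if fr.accepted and p is not None:
            row["damping"] = damping_coefficient(p)
            try:
                row["settling_time"] = settling_time(p, M, y0=fr.y0, band_frac=cfg.settling_band)
            except ValueError:
                row["settling_time"] = math.nan
        fit_rows.append(row)
    fit_table = pd.DataFrame(fit_rows)
    fit_table.to_csv(out / "fits.tsv", sep="\t", index=False)
    manifest["stages"]["fit"] = {
        "fitted": int(len(fit_table)),
        "accepted": int(fit_table["accepted"].sum()) if len(fit_table) else 0,
        "accepted_per_line": {
            ln: int(fit_table.loc[fit_table["cell_line"] == ln, "accepted"].sum())
            for ln in cfg.step_mM
        }
        if len(fit_table)
        else {},
    }

    # --- stage: shared dynamics --------------------------------------------
    if cfg.run_shared:
        manifest["stages"]["shared"] = _run_shared(cfg, series, fits, ss, out)

    # --- stage: classify ----------------------------------------------------
    if cfg.run_classify:
        pairs = build_pairs(ss, norm, cfg.cell_types)
        aucs = {}
        roc_rows = []
        for f in FEATURES:
            try:
                r = roc_auc(pairs, f)
            except ValueError:
                continue
            aucs[f] = r.auc
            for fp, tp in zip(r.fpr, r.tpr):
                roc_rows.append({"feature": f, "fpr": fp, "tpr": tp})
        pd.DataFrame(roc_rows).to_csv(out / "roc_curves.tsv", sep="\t", index=False)
        manifest["stages"]["classify"] = {"pairs": len(pairs), "auc": aucs}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stable_seed(seed: int, *parts: str) -> int:
    h = hashlib.sha256(("|".join([str(seed), *parts])).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _run_shared(cfg: RunConfig, series, fits, ss, out: Path) -> dict:
    lines = list(cfg.step_mM)
    gln = cfg.glutamine_name

    # glutamine joint fit across all lines, then per-time renormalization of
    # the configured lines (default: the hNSC lines) by simulated/observed
    gln_series = {ln: series[(ln, gln)] for ln in lines if (ln, gln) in series}
    norm_lines = cfg.normalize_lines
    if norm_lines is None:
        norm_lines = tuple(ln for ln in lines if cfg.cell_types[ln] == "hNSC")
    renorm_applied = []
    if len(gln_series) == len(lines):
        init = min(
            (fits[(ln, gln)] for ln in lines if (ln, gln) in fits),
            key=lambda fr: fr.mean_fit_error,
            default=None,
        )
        gfit = fit_shared(
            gln_series,
            cfg.step_mM,
            threshold=cfg.shared_error_threshold,
            n_starts=cfg.shared_n_starts,
            seed=_stable_seed(cfg.seed, "gln-shared"),
            init=init,
        )
        if gfit.converged and gfit.scenario is not None:
            for ln in norm_lines:
                ts_g = gln_series[ln]
                pre = ts_g.times < 0
                y0 = float(np.nanmean(ts_g.mean[pre]))
                sim = simulate_true_curve(gfit.params_for(ln), cfg.step_mM[ln], y0, ts_g.times)
                for (l2, met), ts in list(series.items()):
                    if l2 != ln:
                        continue
                    series[(l2, met)] = glutamine_normalize(ts, sim, ts_g.mean)
                renorm_applied.append(ln)

    groups = line_groups(lines)
    mets_by_line = {ln: {m for (l, m) in series if l == ln} for ln in lines}
    shared_rows = []
    errors_by_met: dict[str, dict[tuple[str, ...], dict[str, float]]] = {}
    accepted_by_met: dict[str, dict[tuple[str, ...], bool]] = {}
    all_mets = sorted(set.intersection(*mets_by_line.values())) if lines else []
    for met in all_mets:
        per_group_err: dict[tuple[str, ...], dict[str, float]] = {}
        per_group_acc: dict[tuple[str, ...], bool] = {}
        for g in groups:
            if not all(met in mets_by_line[ln] for ln in g):
                continue
            sub = {ln: series[(ln, met)] for ln in g}
            init = min(
                (fits[(ln, met)] for ln in g if (ln, met) in fits),
                key=lambda fr: fr.mean_fit_error,
                default=None,
            )
            sf = fit_shared(
                sub,
                {ln: cfg.step_mM[ln] for ln in g},
                threshold=cfg.shared_error_threshold,
                n_starts=cfg.shared_n_starts,
                seed=_stable_seed(cfg.seed, "shared", met, *g),
                init=init,
            )
            per_group_err[g] = sf.errors
            per_group_acc[g] = sf.accepted
            shared_rows.append(
                {
                    "metabolite": met,
                    "group": "+".join(g),
                    "scenario": sf.scenario,
                    "accepted": sf.accepted,
                    "max_error": max(sf.errors.values()) if sf.errors else math.nan,
                    **{f"K_{ln}": sf.gains.get(ln, math.nan) for ln in g},
                    **sf.shape,
                }
            )
        errors_by_met[met] = per_group_err
        accepted_by_met[met] = per_group_acc

    venn_rows = []
    for met in all_mets:
        va = venn_assign(met, accepted_by_met[met])
        outcome = {
            ln: ss.loc[(ss["cell_line"] == ln) & (ss["metabolite"] == met), "direction"].squeeze()
            for ln in lines
        }
        venn_rows.append(
            {
                "metabolite": met,
                "specific_region": "+".join(va.specific_region) if va.specific_region else "",
                "ambiguous": va.ambiguous,
                "accepted_regions": ";".join("+".join(g) for g in va.accepted_regions),
                "outcome_down_all": all(v == "down" for v in outcome.values()),
            }
        )
    venn_table = pd.DataFrame(venn_rows)
    venn_table.to_csv(out / "venn_assignments.tsv", sep="\t", index=False)
    pd.DataFrame(shared_rows).to_csv(out / "shared_fits.tsv", sep="\t", index=False)
    sweep = threshold_sweep(errors_by_met, thresholds=[1, 2, 3, 4, 5, 7, 10, 15, 20])
    sweep.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
    return {
        "metabolites": len(all_mets),
        "renormalized_lines": renorm_applied,
        "specific": int((venn_table["specific_region"] != "").sum()) if len(venn_table) else 0,
    }
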