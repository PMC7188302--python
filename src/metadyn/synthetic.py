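"""Synthetic perturbation-experiment panels with known ground truth.

Emulates a targeted-metabolomics time-series study of stem-cell lines
subjected to a sudden extracellular glutamine step in controlled
bioreactors: four cell lines (two hiPSC, two hNSC), eight sampling points
(one before the pulse, then 0, 5, 10, 15, 30, 60 and 120 min after),
three technical replicates per point, and ~201 metabolites from seven
Biocrates-style classes.  Each metabolite pool follows a second-order
step response with per-line gains and (possibly) per-line shape
parameters, so planted cross-line sharing structure — dynamics conserved
within a cell type, across all lines, or in no group — is known exactly
and recoverable by the downstream pipeline.

Observation model, per (cell line, metabolite, time, replicate):
multiplicative log-normal replicate noise on the true pool (mol per µg
protein), a log-normal protein draw per pellet, back-conversion to µM in
the extract (``conc = pool * protein / extract_volume``), optional
below-LOD censoring, and optional injected outlier samples (one whole
replicate sample scaled by a factor across all metabolites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import ModelParams, step_response

__all__ = [
    "SimConfig",
    "TrueMetabolite",
    "simulate_true_curve",
    "generate_panel",
    "make_metabolome",
    "ground_truth_table",
    "DEFAULT_CELL_TYPES",
]

DEFAULT_LINES = ("hiPSC_1", "hiPSC_2", "hNSC_1", "hNSC_2")
DEFAULT_CELL_TYPES = {
    "hiPSC_1": "hiPSC",
    "hiPSC_2": "hiPSC",
    "hNSC_1": "hNSC",
    "hNSC_2": "hNSC",
}

# class composition of the 201-metabolite targeted assay
CLASS_COUNTS = {
    "amino_acid": 21,
    "biogenic_amine": 21,
    "acylcarnitine": 40,
    "phosphatidylcholine": 76,
    "lysophosphatidylcholine": 14,
    "sphingomyelin": 15,
    "tca_intermediate": 14,
}

PANEL_COLUMNS = [
    "cell_line",
    "metabolite",
    "met_class",
    "time_min",
    "replicate",
    "conc_uM",
    "protein_ug",
    "below_lod",
]


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated perturbation experiment.

    Step magnitudes default to the glutamine step from 2.5 mM up to
    15 mM (M = 12.5 mM, a six-fold increase of the extracellular level).
    """

    cell_lines: tuple[str, ...] = DEFAULT_LINES
    cell_types: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    step_mM: dict[str, float] = field(
        default_factory=lambda: {ln: 12.5 for ln in DEFAULT_LINES}
    )
    gln_initial_mM: float = 2.5
    gln_final_mM: float = 15.0
    times_min: tuple[float, ...] = (-10.0, 0.0, 5.0, 10.0, 15.0, 30.0, 60.0, 120.0)
    n_replicates: int = 3
    noise_cv: float = 0.05
    protein_ug_mean: float = 100.0
    protein_cv: float = 0.10
    extract_volume: float = 1.0
    lod_censoring: bool = True
    # (cell_line, time_min, replicate, factor): one mistreated sample
    outliers: tuple[tuple[str, float, int, float], ...] = ()
    # (cell_line, time_min, factor): systematic artifact hitting every
    # replicate and metabolite of one time point (protein-quantification slip)
    timepoint_artifacts: tuple[tuple[str, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if int(np.sum(t < 0)) != 1:
            raise ValueError("time grid must contain exactly one pre-step point")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per time point")
        if self.noise_cv < 0 or self.protein_cv < 0:
            raise ValueError("CVs must be non-negative")
        for ln in self.cell_lines:
            if ln not in self.step_mM:
                raise ValueError(f"no step magnitude for cell line {ln!r}")
            if ln not in self.cell_types:
                raise ValueError(f"no cell type for cell line {ln!r}")


@dataclass
class TrueMetabolite:
    """Ground truth for one metabolite: baselines, kinetics and LOD.

    ``y0`` and ``params`` may be scalars (broadcast to every line) or
    per-cell-line mappings; the per-line form carries the planted sharing
    structure (``sharing`` label) the pipeline is meant to recover.
    """

    name: str
    met_class: str
    y0: float | dict[str, float]
    params: ModelParams | dict[str, ModelParams]
    lod: float = 0.0
    sharing: str = "all"
    noise_cv: float | None = None  # per-metabolite override of SimConfig.noise_cv

    def __post_init__(self) -> None:
        vals = self.y0.values() if isinstance(self.y0, dict) else [self.y0]
        if any(v < 0 for v in vals):
            raise ValueError("baseline y0 must be non-negative")
        if self.lod < 0:
            raise ValueError("lod must be non-negative")

    def baseline(self, line: str) -> float:
        return self.y0[line] if isinstance(self.y0, dict) else self.y0

    def line_params(self, line: str) -> ModelParams:
        return self.params[line] if isinstance(self.params, dict) else self.params


def simulate_true_curve(params: ModelParams, M: float, y0: float, times) -> np.ndarray:
    """Noiseless pool trajectory y0 + y'(t); pre-step times stay at y0."""
    times = np.asarray(times, dtype=float)
    if y0 < 0:
        raise ValueError("baseline y0 must be non-negative")
    return y0 + step_response(params, M, times)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def generate_panel(cfg: SimConfig, metabolites: list[TrueMetabolite]) -> pd.DataFrame:
    """Simulate the replicate-level quantification table (long format).

    Deterministic for a fixed ``cfg.seed``.  Outlier factors and
    time-point artifacts multiply every metabolite of the affected
    sample(s), mimicking sample-preparation mistakes.
    """
    if not metabolites:
        raise ValueError("metabolite list must not be empty")
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.times_min, dtype=float)
    nT, nR, nM = times.size, cfg.n_replicates, len(metabolites)

    frames = []
    for line in cfg.cell_lines:
        M = cfg.step_mM[line]
        protein = cfg.protein_ug_mean * _lognormal_factors(rng, cfg.protein_cv, (nT, nR))

        sample_factor = np.ones((nT, nR))
        for oline, otime, orep, fac in cfg.outliers:
            if oline == line:
                ti = int(np.argmin(np.abs(times - otime)))
                sample_factor[ti, orep] *= fac
        for aline, atime, fac in cfg.timepoint_artifacts:
            if aline == line:
                ti = int(np.argmin(np.abs(times - atime)))
                sample_factor[ti, :] *= fac

        pools = np.empty((nM, nT, nR))
        for i, met in enumerate(metabolites):
            true = simulate_true_curve(met.line_params(line), M, met.baseline(line), times)
            cv = cfg.noise_cv if met.noise_cv is None else met.noise_cv
            pools[i] = true[:, None] * _lognormal_factors(rng, cv, (nT, nR))
        pools *= sample_factor[None, :, :]

        conc = pools * protein[None, :, :] / cfg.extract_volume
        lods = np.array([m.lod for m in metabolites])
        below = cfg.lod_censoring & (conc < lods[:, None, None])

        idx = pd.MultiIndex.from_product(
            [[m.name for m in metabolites], times, range(nR)],
            names=["metabolite", "time_min", "replicate"],
        )
        df = pd.DataFrame(index=idx).reset_index()
        df.insert(0, "cell_line", line)
        class_of = {m.name: m.met_class for m in metabolites}
        df["met_class"] = df["metabolite"].map(class_of)
        df["conc_uM"] = conc.ravel()
        df["protein_ug"] = np.broadcast_to(protein, (nM, nT, nR)).ravel()
        df["below_lod"] = below.ravel()
        frames.append(df)

    return pd.concat(frames, ignore_index=True)[PANEL_COLUMNS]


# ---------------------------------------------------------------------------
# default metabolome with planted sharing structure


def _draw_shape(rng: np.random.Generator) -> tuple:
    """One random shape: (scenario, tau_a, tau1, tau2 | tau, zeta)."""
    if rng.random() < 0.7:
        tau1 = float(np.exp(rng.uniform(math.log(3.0), math.log(40.0))))
        tau2 = tau1 * rng.uniform(0.15, 0.6)
        tau_a = -rng.uniform(1.0, 5.0) if rng.random() < 0.15 else rng.uniform(0.0, 0.5) * tau2
        return ("overdamped", tau_a, tau1, tau2, None, None)
    tau = float(np.exp(rng.uniform(math.log(4.0), math.log(25.0))))
    zeta = rng.uniform(0.35, 0.85)
    tau_a = rng.uniform(0.0, 0.3) * tau
    return ("underdamped", tau_a, None, None, tau, zeta)


def _dominant_tau(shape: tuple) -> float:
    scen, _, t1, _, tau, zeta = shape
    return t1 if scen == "overdamped" else tau / zeta


def _archetype_shape(rng: np.random.Generator, kind: str) -> tuple:
    """One shape from a qualitatively distinct dynamic archetype.

    The archetypes differ in features a joint fit with shared shape
    parameters cannot reconcile: settling speed (fast vs slow), inverse
    response (negative numerator zero, shared tau_a forbids mimicking it)
    and pronounced oscillation (scenario choice is shared too).
    """
    if kind == "fast":
        tau1 = rng.uniform(4.0, 7.0)
        tau2 = tau1 * rng.uniform(0.2, 0.5)
        return ("overdamped", rng.uniform(0.0, 0.5) * tau2, tau1, tau2, None, None)
    if kind == "slow":
        tau1 = rng.uniform(28.0, 40.0)
        tau2 = tau1 * rng.uniform(0.3, 0.6)
        return ("overdamped", rng.uniform(0.0, 0.5) * tau2, tau1, tau2, None, None)
    if kind == "inverse":
        tau1 = rng.uniform(8.0, 14.0)
        tau2 = tau1 * rng.uniform(0.3, 0.6)
        return ("overdamped", -rng.uniform(12.0, 20.0), tau1, tau2, None, None)
    # oscillator: a deep overshoot-and-return swing inside the 2-h window
    tau = rng.uniform(10.0, 16.0)
    return ("underdamped", rng.uniform(0.0, 2.0), None, None, tau, rng.uniform(0.20, 0.35))


_ARCHETYPES = ("fast", "slow", "inverse", "oscillator")


def _distinct_shapes(rng: np.random.Generator, k: int) -> list[tuple]:
    """k shapes drawn from k different dynamic archetypes, shuffled."""
    kinds = list(_ARCHETYPES)
    rng.shuffle(kinds)
    return [_archetype_shape(rng, kind) for kind in kinds[:k]]


def _cross_fit_separated(
    shapes: dict[str, tuple],
    y0: dict[str, float],
    rel: dict[str, float],
    types: dict[str, str],
    cfg: SimConfig,
    margin: float = 7.0,
) -> bool:
    """True when no pair of distinct-by-design shapes can be jointly fit.

    Evaluates the noiseless cross-fit (shared shape, free gains) for every
    line pair whose planted shapes differ and requires its best per-line
    mean fitting error to stay above ``margin`` percent — the headroom the
    downstream 4% shared-fit threshold needs to reject the pair reliably
    under replicate noise.
    """
    from .preprocess import TimeSeries
    from .shared import fit_shared

    lines = list(shapes)
    times = np.asarray(cfg.times_min, dtype=float)
    for i, a in enumerate(lines):
        for b in lines[i + 1 :]:
            if shapes[a] is shapes[b] or shapes[a] == shapes[b]:
                continue
            series = {}
            for ln in (a, b):
                p = _params_from_shape(shapes[ln], rel[types[ln]] * y0[ln] / cfg.step_mM[ln])
                curve = y0[ln] + step_response(p, cfg.step_mM[ln], times)
                series[ln] = TimeSeries(
                    "probe", ln, times, curve, np.zeros_like(curve), np.full(curve.size, 3)
                )
            sf = fit_shared(
                series,
                {ln: cfg.step_mM[ln] for ln in (a, b)},
                n_starts=2,
                seed=0,
            )
            if max(sf.errors.values(), default=0.0) < margin:
                return False
    return True


def _params_from_shape(shape: tuple, K: float) -> ModelParams:
    scen, tau_a, t1, t2, tau, zeta = shape
    if scen == "overdamped":
        return ModelParams.overdamped(K, tau_a, t1, t2)
    return ModelParams.underdamped(K, tau_a, tau, zeta)


_CLASS_SCALE = {
    "amino_acid": 2.0,
    "biogenic_amine": 0.3,
    "acylcarnitine": 0.1,
    "phosphatidylcholine": 0.5,
    "lysophosphatidylcholine": 0.2,
    "sphingomyelin": 0.4,
    "tca_intermediate": 1.0,
}


def make_metabolome(
    cfg: SimConfig,
    n_total: int = 201,
    n_lod_bad: int | None = None,
    n_cv_bad: int | None = None,
    frac_flat: float = 0.15,
    frac_all_shared: float = 0.34,
    frac_type_shared: float = 0.34,
    seed: int | None = None,
    bad_noise_cv: float = 0.35,
) -> list[TrueMetabolite]:
    """Build the default ground-truth metabolome with planted structure.

    Sharing labels planted among the quantifiable metabolites:
    ``all`` (one shape for all lines), ``hiPSC`` / ``hNSC`` (shape shared
    within that type only; each other line gets its own, well-separated
    shape), ``none`` (four distinct shapes) and flat metabolites (zero
    gain everywhere, labelled ``all`` since any shape fits them).
    Glutamine is always present, all-shared and strongly increasing.
    Additionally ``n_lod_bad`` metabolites sit entirely below their LOD
    and ``n_cv_bad`` carry replicate noise far above the CV filter — the
    known "bad" set the quality filters must remove.
    """
    # bad-metabolite counts default to the 201-panel design (15 LOD, 10 CV),
    # scaled down proportionally for smaller panels
    if n_lod_bad is None:
        n_lod_bad = round(15 * n_total / 201)
    if n_cv_bad is None:
        n_cv_bad = round(10 * n_total / 201)
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    lines = list(cfg.cell_lines)
    types = cfg.cell_types
    type_names = sorted(set(types.values()))

    # names per class, scaled counts if n_total != 201
    names: list[tuple[str, str]] = []
    total = sum(CLASS_COUNTS.values())
    for cls, cnt in CLASS_COUNTS.items():
        k = max(1, round(cnt * n_total / total))
        for j in range(k):
            names.append((f"{cls}_{j:03d}", cls))
    names = names[:n_total]
    # glutamine is the first amino acid
    names[0] = ("Gln", "amino_acid")

    n_bad = n_lod_bad + n_cv_bad
    n_good = len(names) - n_bad
    if n_good < 1:
        raise ValueError("too many bad metabolites for the panel size")
    n_flat = round(frac_flat * n_good)
    n_all = max(1, round(frac_all_shared * n_good))
    n_type = round(frac_type_shared * n_good)  # split between the two types
    n_t1 = n_type // 2
    n_t2 = n_type - n_t1
    n_none = max(0, n_good - n_flat - n_all - n_t1 - n_t2)
    labels = (
        ["all"] * n_all
        + [type_names[0]] * n_t1
        + [type_names[1]] * n_t2
        + ["none"] * n_none
        + ["flat"] * n_flat
    )[:n_good]
    labels += ["none"] * (n_good - len(labels))
    labels[0] = "all"  # glutamine
    labels += ["lod_bad"] * n_lod_bad + ["cv_bad"] * n_cv_bad

    mets: list[TrueMetabolite] = []
    for (name, cls), label in zip(names, labels):
        base = _CLASS_SCALE[cls] * float(np.exp(rng.uniform(math.log(0.3), math.log(3.0))))
        y0 = {ln: base * float(_lognormal_factors(rng, 0.30, 1)[0]) for ln in lines}

        # relative steady-state response per cell type (identical inside a
        # type so fold-changes are type-structured; sign and size random).
        # metabolites planted with distinguishable dynamics respond strongly:
        # a shape difference is only visible when the transient is a sizable
        # fraction of the pool level
        lo_rel = 0.4 if label in (*type_names, "none") else 0.25
        rel = {
            tn: (rng.choice([-1.0, 1.0]) * rng.uniform(lo_rel, 0.8)) for tn in type_names
        }
        if name == "Gln":
            rel = {tn: rng.uniform(1.5, 2.5) for tn in type_names}

        if label in ("flat",):
            rel = {tn: 0.0 for tn in type_names}

        def _assign(shapes_list: list[tuple]) -> dict[str, tuple]:
            if label in type_names:
                others = [ln for ln in lines if types[ln] != label]
                return {
                    ln: shapes_list[0]
                    if types[ln] == label
                    else shapes_list[1 + others.index(ln)]
                    for ln in lines
                }
            return {ln: shapes_list[i] for i, ln in enumerate(lines)}

        if label in ("all", "flat", "lod_bad", "cv_bad"):
            shared = _draw_shape(rng)
            shapes = {ln: shared for ln in lines}
        else:
            # planted-distinct shapes are calibrated: redraw until every pair
            # of lines meant to differ cannot be cross-fit below the margin
            # even without noise (tau separation alone does not guarantee it)
            n_shapes = 3 if label in type_names else len(lines)
            shapes = None
            for _ in range(15):
                cand = _assign(_distinct_shapes(rng, n_shapes))
                if _cross_fit_separated(cand, y0, rel, types, cfg):
                    shapes = cand
                    break
            if shapes is None:
                shapes = cand

        params = {}
        for ln in lines:
            K = rel[types[ln]] * y0[ln] / cfg.step_mM[ln]
            params[ln] = _params_from_shape(shapes[ln], K)

        lod = 0.0
        noise_cv = None
        sharing = "all" if label == "flat" else label
        if label == "lod_bad":
            # put the LOD far above anything this metabolite can reach
            peak = max(
                y0[ln] * (1 + abs(rel[types[ln]])) * cfg.protein_ug_mean * 3 for ln in lines
            )
            lod = 10.0 * peak / cfg.extract_volume
            sharing = "lod_bad"
        elif label == "cv_bad":
            noise_cv = bad_noise_cv
            sharing = "cv_bad"
        mets.append(
            TrueMetabolite(
                name=name,
                met_class=cls,
                y0=y0,
                params=params,
                lod=lod,
                sharing=sharing,
                noise_cv=noise_cv,
            )
        )
    return mets


def ground_truth_table(metabolites: list[TrueMetabolite], cfg: SimConfig) -> pd.DataFrame:
    """Long-format sidecar of the generative ground truth (one row per line)."""
    rows = []
    for met in metabolites:
        for line in cfg.cell_lines:
            p = met.line_params(line)
            rows.append(
                {
                    "metabolite": met.name,
                    "met_class": met.met_class,
                    "cell_line": line,
                    "sharing": met.sharing,
                    "scenario": p.scenario,
                    "K": p.K,
                    "tau_a": p.tau_a,
                    "tau1": p.tau1,
                    "tau2": p.tau2,
                    "tau": p.tau,
                    "zeta": p.zeta,
                    "y0": met.baseline(line),
                    "lod": met.lod,
                }
            )
    return pd.DataFrame(rows)
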