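import numpy as np
import pytest

from metadyn.dynamics import ModelParams
from metadyn.synthetic import SimConfig, generate_panel, make_metabolome

STUDY_GRID = np.array([-10.0, 0.0, 5.0, 10.0, 15.0, 30.0, 60.0, 120.0])


def ode_step_response(params: ModelParams, M: float, times) -> np.ndarray:
    """Independent oracle: integrate the state-space realization of the model.

    Controllable canonical form of K*M*(tau_a*s+1)/(a2*s^2+a1*s+1) driven
    by a unit step, integrated with solve_ivp at tight tolerances.
    Deliberately does not share any code with the closed-form response.
    """
    from scipy.integrate import solve_ivp

    if params.scenario == "overdamped":
        a2 = params.tau1 * params.tau2
        a1 = params.tau1 + params.tau2
    else:
        a2 = params.tau**2
        a1 = 2.0 * params.zeta * params.tau
    KM = params.K * M
    times = np.asarray(times, dtype=float)
    t_eval = np.clip(times, 0.0, None)

    def rhs(t, x):
        return [x[1], (1.0 - x[0] - a1 * x[1]) / a2]

    sol = solve_ivp(
        rhs,
        (0.0, max(float(t_eval.max()), 1e-9)),
        [0.0, 0.0],
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-13,
        method="LSODA",
    )
    y = KM * sol.y[0] + KM * params.tau_a * sol.y[1]
    return np.where(times < 0.0, 0.0, y)


def random_params(rng: np.random.Generator) -> ModelParams:
    """One random valid parameter set from either branch."""
    K = rng.uniform(-2.0, 2.0)
    if K == 0.0:
        K = 0.5
    tau_a = rng.uniform(-10.0, 20.0)
    if rng.random() < 0.5:
        tau1 = rng.uniform(2.0, 40.0)
        tau2 = tau1 * rng.uniform(0.05, 1.0)
        return ModelParams.overdamped(K, tau_a, tau1, tau2)
    return ModelParams.underdamped(K, tau_a, rng.uniform(2.0, 40.0), rng.uniform(0.05, 0.999))


def brute_force_bh(pvalues: np.ndarray, fdr: float) -> np.ndarray:
    """Exhaustive step-up oracle: reject all p <= the largest p(k) with
    p(k) <= k*fdr/m, searching every threshold directly."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.sort(p)
    thresh = 0.0
    for k in range(m, 0, -1):
        if order[k - 1] <= k * fdr / m:
            thresh = order[k - 1]
            break
    return p <= thresh


def brute_force_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney oracle: P(score+ > score-) + 0.5*P(tie) over all pairs."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


@pytest.fixture(scope="session")
def small_panel():
    """Low-noise 30-metabolite panel, all four lines, with ground truth."""
    cfg = SimConfig(seed=42, noise_cv=0.02)
    mets = make_metabolome(cfg, n_total=30, n_lod_bad=2, n_cv_bad=2)
    return cfg, mets, generate_panel(cfg, mets)


@pytest.fixture(scope="session")
def clean_panel():
    """Zero-noise panel: protein and replicate noise off, no bad metabolites."""
    cfg = SimConfig(seed=7, noise_cv=0.0, protein_cv=0.0, lod_censoring=False)
    mets = make_metabolome(cfg, n_total=12, n_lod_bad=0, n_cv_bad=0)
    return cfg, mets, generate_panel(cfg, mets)
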