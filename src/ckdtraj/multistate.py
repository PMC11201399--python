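"""Continuous-time multistate Markov model for panel-observed stages.

Disease stages are modelled as a time-homogeneous continuous-time
Markov chain observed intermittently: the stage is known only at the
measurement times, exact transition moments are unobserved.  Covariates
act multiplicatively on the transition intensities,

    q_rs(x) = q_rs(0) * exp(beta_rs' x),

so ``exp(beta)`` is the hazard ratio for that transition; the first
design column is conventionally the exposure indicator.  The likelihood
is the product over consecutive observation pairs of the matrix
exponential entries ``P(dt; x) = expm(Q(x) dt)`` — direct jumps between
non-adjacent observed stages are thereby explained by unobserved
passage through intermediate stages.

The default transition structure is tridiagonal over the merged stage
space: G1/2 <-> G3 <-> G4/5, with no direct G1/2 <-> G4/5 intensity.

Estimation is by maximum likelihood with analytic gradients (the
Kalbfleisch–Lawless eigendecomposition form of the derivative of the
matrix exponential), quasi-Newton iteration from a crude-rate start,
and Wald intervals from the numerically differentiated observed
information.  The fit is deterministic given the data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize

from ckdtraj.eventlog import EventLog
from ckdtraj.staging import MERGED_STAGES

__all__ = [
    "DEFAULT_TRANSITIONS",
    "TransitionStructure",
    "IntensityModel",
    "FitResult",
    "PanelData",
    "make_panel",
    "build_generator",
    "transition_probability",
    "log_likelihood",
    "crude_rates",
    "fit",
]

logger = logging.getLogger(__name__)

#: The four modelled transitions between merged stages (tridiagonal).
DEFAULT_TRANSITIONS = (
    ("G1/2", "G3"),
    ("G3", "G1/2"),
    ("G3", "G4/5"),
    ("G4/5", "G3"),
)

_P_FLOOR = 1e-300       # log-guard for exactly-zero transition probabilities
_OPT_P_FLOOR = 1e-12    # optimiser-side clip keeping the objective finite
_LOGQ_BOUNDS = (-20.0, 5.0)
_BETA_BOUNDS = (-10.0, 10.0)


@dataclass(frozen=True)
class TransitionStructure:
    """State space and allowed instantaneous transitions."""

    states: tuple[str, ...] = MERGED_STAGES
    transitions: tuple[tuple[str, str], ...] = DEFAULT_TRANSITIONS

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "transitions", tuple((r, s) for r, s in self.transitions))
        seen = set()
        for r, s in self.transitions:
            if r not in self.states or s not in self.states:
                raise ValueError(f"transition ({r},{s}) uses unknown state")
            if r == s:
                raise ValueError("self-transitions have no intensity parameter")
            if (r, s) in seen:
                raise ValueError(f"duplicate transition ({r},{s})")
            seen.add((r, s))

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}

    def transition_indices(self) -> tuple[np.ndarray, np.ndarray]:
        idx = self.state_index()
        r = np.array([idx[a] for a, _ in self.transitions])
        s = np.array([idx[b] for _, b in self.transitions])
        return r, s


@dataclass(frozen=True)
class IntensityModel:
    """Parameterised intensity model q_rs(x) = q_rs(0) exp(beta_rs' x)."""

    structure: TransitionStructure
    covariate_names: tuple[str, ...]
    log_q0: np.ndarray          # (k,)
    beta: np.ndarray            # (k, p)

    def __post_init__(self):
        k, p = self.structure.n_transitions, len(self.covariate_names)
        lq = np.asarray(self.log_q0, dtype=float)
        b = np.asarray(self.beta, dtype=float).reshape(k, p) if p else np.zeros((k, 0))
        if lq.shape != (k,):
            raise ValueError(f"log_q0 must have shape ({k},)")
        object.__setattr__(self, "log_q0", lq)
        object.__setattr__(self, "beta", b)

    def intensities(self, x) -> np.ndarray:
        """Per-transition intensities at covariate vector ``x``."""
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.covariate_names),):
            raise ValueError("covariate vector has wrong length")
        if not np.all(np.isfinite(x)):
            raise ValueError("covariates must be finite")
        q = np.exp(self.log_q0 + self.beta @ x)
        if not np.all(np.isfinite(q)):
            raise ValueError("non-finite transition intensity (overflow)")
        return q

    def generator(self, x) -> np.ndarray:
        return _generator_from_q(self.intensities(x), self.structure)


def _generator_from_q(q: np.ndarray, structure: TransitionStructure) -> np.ndarray:
    n = structure.n_states
    r, s = structure.transition_indices()
    Q = np.zeros(q.shape[:-1] + (n, n))
    Q[..., r, s] = q
    diag = -Q.sum(axis=-1)
    idx = np.arange(n)
    Q[..., idx, idx] = diag
    return Q


def build_generator(model: IntensityModel, x) -> np.ndarray:
    """Generator matrix Q(x): rows sum to zero, off-diagonals are the
    covariate-scaled intensities, zeros at disallowed transitions."""
    return model.generator(x)


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Stochastic matrix ``P(t) = expm(Q t)`` for a valid generator."""
    Q = np.asarray(Q, dtype=float)
    if t < 0:
        raise ValueError("time must be non-negative")
    offdiag = Q - np.diag(np.diag(Q))
    if np.any(offdiag < 0) or np.max(np.abs(Q.sum(axis=1))) > 1e-8:
        raise ValueError("not a generator matrix (negative rate or non-zero row sum)")
    P = scipy.linalg.expm(Q * t)
    P = np.clip(P, 0.0, 1.0)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# panel data preparation

@dataclass(frozen=True)
class PanelData:
    """Consecutive observation pairs of an event log, design-matrix grouped.

    ``X`` holds the unique covariate rows; ``grp`` maps each pair to its
    row, so the matrix exponential is computed once per unique covariate
    pattern and observation gap batch.
    """

    from_idx: np.ndarray
    to_idx: np.ndarray
    dt: np.ndarray
    grp: np.ndarray
    pair_patient: np.ndarray
    X: np.ndarray               # (G, p) unique covariate rows
    covariate_names: tuple[str, ...]
    structure: TransitionStructure
    n_patients: int

    @property
    def n_pairs(self) -> int:
        return len(self.dt)


def make_panel(log: EventLog, covariates: pd.DataFrame | None = None,
               covariate_cols: tuple[str, ...] = ("exposure",),
               structure: TransitionStructure | None = None) -> PanelData:
    """Extract consecutive observation pairs and the per-pair design.

    ``covariates`` needs ``patient_id`` plus the requested columns; a
    ``group`` column with PPI/H2B labels is accepted in lieu of a
    numeric ``exposure`` column (PPI -> 1, H2B -> 0).  Pass
    ``covariate_cols=()`` for an unadjusted fit.
    """
    structure = structure or TransitionStructure()
    sidx = structure.state_index()
    ev = log.events
    unknown = set(ev["stage"]) - set(structure.states)
    if unknown:
        raise ValueError(f"log contains stages outside the model state space: {sorted(unknown)}")

    pid = ev["patient_id"].to_numpy()
    t = ev["time_months"].to_numpy(dtype=float)
    state = ev["stage"].map(sidx).to_numpy()
    same = pid[1:] == pid[:-1]
    from_idx = state[:-1][same]
    to_idx = state[1:][same]
    dt = np.diff(t)[same]
    pair_patient = pid[1:][same]

    patients = log.censoring["patient_id"].to_numpy()
    p = len(covariate_cols)
    if p:
        if covariates is None:
            raise ValueError("covariate_cols given but no covariates table")
        cov = covariates.copy()
        if "exposure" in covariate_cols and "exposure" not in cov.columns:
            if "group" not in cov.columns:
                raise ValueError("need an 'exposure' (0/1) or 'group' (PPI/H2B) column")
            cov["exposure"] = (cov["group"] == "PPI").astype(float)
        if "sex" in covariate_cols and not pd.api.types.is_numeric_dtype(cov.get("sex", pd.Series(dtype=float))):
            cov["sex"] = (cov["sex"].astype(str).str.lower().str.startswith("f")).astype(float)
        cov = cov.set_index("patient_id")
        missing = [c for c in covariate_cols if c not in cov.columns]
        if missing:
            raise ValueError(f"covariate column(s) missing: {missing}")
        Xfull = cov.loc[patients, list(covariate_cols)].to_numpy(dtype=float)
        if not np.all(np.isfinite(Xfull)):
            raise ValueError("non-finite covariate values")
        Xuniq, inverse = np.unique(Xfull, axis=0, return_inverse=True)
    else:
        Xuniq = np.zeros((1, 0))
        inverse = np.zeros(len(patients), dtype=int)

    pos = {pid_: i for i, pid_ in enumerate(patients)}
    grp = inverse[np.fromiter((pos[p_] for p_ in pair_patient), dtype=int, count=len(pair_patient))]
    return PanelData(from_idx=from_idx, to_idx=to_idx, dt=dt, grp=grp,
                     pair_patient=pair_patient, X=Xuniq,
                     covariate_names=tuple(covariate_cols), structure=structure,
                     n_patients=len(patients))


# ---------------------------------------------------------------------------
# likelihood and analytic gradient

def _pair_probabilities(theta: np.ndarray, panel: PanelData, want_grad: bool):
    """P entries for all pairs and, optionally, their derivatives.

    Uses the batched eigendecomposition of the per-group generators;
    the derivative of ``expm(Q t)`` w.r.t. each intensity parameter is
    evaluated in the eigenbasis via divided differences
    (Kalbfleisch–Lawless), with the confluent limit ``t e^{w t}`` for
    near-equal eigenvalues.  Falls back to ``expm``/``expm_frechet``
    when an eigenvector matrix is ill-conditioned.
    """
    st = panel.structure
    k, p = st.n_transitions, panel.X.shape[1]
    n = st.n_states
    log_q0 = theta[:k]
    beta = theta[k:].reshape(k, p)
    q = np.exp(log_q0[None, :] + panel.X @ beta.T)        # (G, k)
    if not np.all(np.isfinite(q)):
        return None, None, q
    Q = _generator_from_q(q, st)                          # (G, n, n)

    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        conds = (np.abs(V).max(axis=(1, 2)) * np.abs(Vinv).max(axis=(1, 2)))
        if not np.all(np.isfinite(w)) or np.max(conds) > 1e10:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return _pair_probabilities_expm(q, Q, panel, want_grad)

    g = panel.grp
    A = V[g, panel.from_idx, :]                           # (N, n)
    B = Vinv[g, :, panel.to_idx]                          # (N, n)
    wg = w[g]                                             # (N, n)
    Ew = np.exp(wg * panel.dt[:, None])
    P = np.real(np.sum(A * B * Ew, axis=1))

    if not want_grad:
        return P, None, q

    diff = wg[:, :, None] - wg[:, None, :]
    numer = Ew[:, :, None] - Ew[:, None, :]
    small = np.abs(diff) < 1e-9 * (1.0 + np.abs(wg[:, :, None]))
    Phi = np.where(small,
                   panel.dt[:, None, None] * Ew[:, :, None],
                   numer / np.where(small, 1.0, diff))
    W = A[:, :, None] * Phi * B[:, None, :]               # (N, n, n)

    r_idx, s_idx = st.transition_indices()
    dP = np.empty((k, panel.n_pairs))
    for m in range(k):
        r, s = r_idx[m], s_idx[m]
        # Vinv @ (E_rs - E_rr) @ V scaled by the intensity, per group
        Gm = q[:, m, None, None] * (Vinv[:, :, r, None]
                                    * (V[:, None, s, :] - V[:, None, r, :]))
        dP[m] = np.real(np.sum(Gm[g] * W, axis=(1, 2)))
    return P, dP, q


def _pair_probabilities_expm(q, Q, panel: PanelData, want_grad: bool):
    """Reference path via scipy expm / expm_frechet (slow, always valid)."""
    st = panel.structure
    k = st.n_transitions
    r_idx, s_idx = st.transition_indices()
    n = st.n_states
    P = np.empty(panel.n_pairs)
    dP = np.empty((k, panel.n_pairs)) if want_grad else None
    cache: dict[tuple[int, float], tuple] = {}
    for pidx in range(panel.n_pairs):
        g, t = int(panel.grp[pidx]), float(panel.dt[pidx])
        key = (g, t)
        if key not in cache:
            Qt = Q[g] * t
            if want_grad:
                mats = []
                Pm = None
                for m in range(k):
                    D = np.zeros((n, n))
                    r, s = r_idx[m], s_idx[m]
                    D[r, s] = q[g, m]
                    D[r, r] = -q[g, m]
                    Pm, F = scipy.linalg.expm_frechet(Qt, D * t)
                    mats.append(F)
                cache[key] = (Pm, mats)
            else:
                cache[key] = (scipy.linalg.expm(Qt), None)
        Pm, mats = cache[key]
        i, j = panel.from_idx[pidx], panel.to_idx[pidx]
        P[pidx] = Pm[i, j]
        if want_grad:
            for m in range(k):
                dP[m, pidx] = mats[m][i, j]
    return P, dP, q


def _loglik_grad(theta: np.ndarray, panel: PanelData, want_grad: bool = True,
                 floor: float = _OPT_P_FLOOR):
    """Total panel log-likelihood and its gradient in ``theta``."""
    P, dP, q = _pair_probabilities(theta, panel, want_grad)
    k, p = panel.structure.n_transitions, panel.X.shape[1]
    if P is None:  # overflowed intensities mid-linesearch
        grad = np.zeros(k + k * p)
        return -1e12, grad
    Pc = np.clip(P, floor, None)
    ll = float(np.sum(np.log(Pc)))
    if not want_grad:
        return ll, None
    ratio = np.where(P > floor, dP / Pc[None, :], 0.0)    # (k, N)
    grad_q0 = ratio.sum(axis=1)
    if p:
        Xg = panel.X[panel.grp]                           # (N, p)
        grad_beta = ratio @ Xg                            # (k, p)
        grad = np.concatenate([grad_q0, grad_beta.ravel()])
    else:
        grad = grad_q0
    return ll, grad


def log_likelihood(model: IntensityModel, log: EventLog,
                   covariates: pd.DataFrame | None = None) -> float:
    """Panel log-likelihood of a model on a merged-stage event log.

    Sums ``log P_{s_i, s_{i+1}}(dt; x)`` over all consecutive pairs; a
    patient with a single observation contributes 0 (empty product).
    Returns ``-inf`` (with a diagnostic naming the offending pair) if
    any observed pair has probability zero.
    """
    panel = make_panel(log, covariates, model.covariate_names, model.structure)
    theta = np.concatenate([model.log_q0, model.beta.ravel()])
    P, _, _ = _pair_probabilities(theta, panel, want_grad=False)
    if P is None:
        raise ValueError("non-finite transition intensity (overflow)")
    bad = P <= _P_FLOOR
    if np.any(bad):
        i = int(np.argmax(bad))
        st = panel.structure.states
        logger.warning("zero transition probability for patient %r pair %s -> %s (dt=%.3f)",
                       panel.pair_patient[i], st[panel.from_idx[i]],
                       st[panel.to_idx[i]], panel.dt[i])
        return -np.inf
    return float(np.sum(np.log(P)))


def crude_rates(panel: PanelData) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic crude-rate initialisation.

    For each allowed transition r -> s: the number of directly-follows
    occurrences divided by the total observed months spent with state r
    at the start of a pair.  Returns ``(rates, counts)``; a zero count
    marks the intensity as unidentified in the data.
    """
    st = panel.structure
    r_idx, s_idx = st.transition_indices()
    k = st.n_transitions
    counts = np.zeros(k)
    rates = np.zeros(k)
    time_at = np.zeros(st.n_states)
    np.add.at(time_at, panel.from_idx, panel.dt)
    for m in range(k):
        counts[m] = np.sum((panel.from_idx == r_idx[m]) & (panel.to_idx == s_idx[m]))
        rates[m] = counts[m] / time_at[r_idx[m]] if time_at[r_idx[m]] > 0 else 0.0
    return rates, counts


@dataclass
class FitResult:
    """Maximum-likelihood fit of the proportional-intensity model."""

    model: IntensityModel
    se_log_q0: np.ndarray
    se_beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_patients: int
    n_pairs: int
    unidentified: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    message: str = ""

    @property
    def hazard_ratios(self) -> np.ndarray:
        """Exposure hazard ratio exp(beta1) per transition."""
        return np.exp(self.model.beta[:, 0])

    @property
    def hr_ci(self) -> np.ndarray:
        """95% Wald CI of the exposure HR per transition, shape (k, 2)."""
        b = self.model.beta[:, 0]
        se = self.se_beta[:, 0]
        return np.exp(np.stack([b - 1.96 * se, b + 1.96 * se], axis=1))

    def hr_table(self) -> pd.DataFrame:
        rows = []
        ci = self.hr_ci
        for m, (r, s) in enumerate(self.model.structure.transitions):
            rows.append({
                "transition": f"{r} -> {s}",
                "q0_per_month": float(np.exp(self.model.log_q0[m])),
                "hazard_ratio": float(self.hazard_ratios[m]),
                "ci_low": float(ci[m, 0]),
                "ci_high": float(ci[m, 1]),
                "identified": (r, s) not in self.unidentified,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Multistate model fit (proportional transition intensities)",
            f"  patients: {self.n_patients}   observation pairs: {self.n_pairs}",
            f"  log-likelihood: {self.loglik:.3f}   converged: {self.converged}"
            f" ({self.n_iter} iterations)",
            f"  covariates: {', '.join(self.model.covariate_names) or '(none)'}",
            "",
            f"  {'transition':<14} {'q0/month':>10} {'HR (exposure)':>14} {'95% CI':>16}",
        ]
        ci = self.hr_ci
        for m, (r, s) in enumerate(self.model.structure.transitions):
            tag = "" if (r, s) not in self.unidentified else "   [unidentified]"
            hr = f"{self.hazard_ratios[m]:.2f}" if self.model.beta.shape[1] else "-"
            ci_s = (f"({ci[m,0]:.2f}, {ci[m,1]:.2f})"
                    if self.model.beta.shape[1] and np.isfinite(ci[m]).all() else "-")
            lines.append(f"  {r + ' -> ' + s:<14} {np.exp(self.model.log_q0[m]):>10.4f}"
                         f" {hr:>14} {ci_s:>16}{tag}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        st = self.model.structure
        return {
            "states": list(st.states),
            "transitions": [list(t) for t in st.transitions],
            "covariates": list(self.model.covariate_names),
            "log_q0": self.model.log_q0.tolist(),
            "beta": self.model.beta.tolist(),
            "se_log_q0": self.se_log_q0.tolist(),
            "se_beta": self.se_beta.tolist(),
            "hazard_ratio_exposure": self.hazard_ratios.tolist() if self.model.beta.size else [],
            "hr_ci95": self.hr_ci.tolist() if self.model.beta.size else [],
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_patients": self.n_patients,
            "n_pairs": self.n_pairs,
            "unidentified": [list(t) for t in self.unidentified],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def fit(log: EventLog, covariates: pd.DataFrame | None = None,
        structure: TransitionStructure | None = None,
        covariate_cols: tuple[str, ...] = ("exposure",),
        gtol: float = 1e-8, maxiter: int = 500) -> FitResult:
    """Maximum-likelihood fit of the multistate model on an event log.

    Parameters
    ----------
    log : EventLog
        Merged-stage event log (or any log whose labels match
        ``structure.states``).
    covariates : DataFrame
        Per-patient covariates (``patient_id`` + columns); the first
        entry of ``covariate_cols`` is the exposure whose per-transition
        hazard ratio is reported.
    gtol : float
        Gradient-norm tolerance on the per-observation (mean) scale.

    Transitions with no observed directly-follows occurrence are warned
    about, their baseline intensity pinned near zero and their
    covariate effects fixed at zero; SEs for them are reported absent.
    """
    structure = structure or TransitionStructure()
    panel = make_panel(log, covariates, covariate_cols, structure)
    k, p = structure.n_transitions, len(covariate_cols)
    nparam = k + k * p

    rates, counts = crude_rates(panel)
    unidentified = tuple(structure.transitions[m] for m in range(k) if counts[m] == 0)
    for tr in unidentified:
        warnings.warn(f"transition {tr[0]} -> {tr[1]} never observed; "
                      "its intensity is unidentified and fixed near zero")
    theta0 = np.concatenate([
        np.log(np.where(counts > 0, np.maximum(rates, 1e-8), 1e-6)),
        np.zeros(k * p),
    ])

    bounds = []
    fixed = np.zeros(nparam, dtype=bool)
    for m in range(k):
        if counts[m] == 0:
            bounds.append((theta0[m], theta0[m]))
            fixed[m] = True
        else:
            bounds.append(_LOGQ_BOUNDS)
    for m in range(k):
        for c in range(p):
            j = k + m * p + c
            if counts[m] == 0:
                bounds.append((0.0, 0.0))
                fixed[j] = True
            else:
                bounds.append(_BETA_BOUNDS)

    scale = max(panel.n_pairs, 1)

    def objective(theta):
        ll, grad = _loglik_grad(theta, panel)
        return -ll / scale, -grad / scale

    res = minimize(objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14})
    theta = res.x
    ll_hat, _ = _loglik_grad(theta, panel, want_grad=False)
    ll0, _ = _loglik_grad(theta0, panel, want_grad=False)
    if ll_hat < ll0 - 1e-6:
        logger.warning("optimiser did not improve on the crude-rate start (%.4f < %.4f)",
                       ll_hat, ll0)

    se = _wald_se(theta, panel, fixed)
    model = IntensityModel(structure=structure, covariate_names=tuple(covariate_cols),
                           log_q0=theta[:k], beta=theta[k:].reshape(k, p))
    return FitResult(model=model,
                     se_log_q0=se[:k], se_beta=se[k:].reshape(k, p),
                     loglik=ll_hat, converged=bool(res.success),
                     n_iter=int(res.nit), n_patients=panel.n_patients,
                     n_pairs=panel.n_pairs, unidentified=unidentified,
                     message=str(res.message))


def _wald_se(theta: np.ndarray, panel: PanelData, fixed: np.ndarray) -> np.ndarray:
    """SEs from the observed information: central finite differences of
    the analytic gradient, free parameters only; absent (NaN) when the
    information matrix is singular."""
    free = ~fixed
    nfree = int(free.sum())
    se = np.full(theta.shape, np.nan)
    if nfree == 0:
        return se
    H = np.empty((nfree, nfree))
    free_idx = np.flatnonzero(free)
    for a, j in enumerate(free_idx):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _loglik_grad(tp, panel)
        _, gm = _loglik_grad(tm, panel)
        H[a] = ((gm - gp) / (2 * h))[free_idx]   # negative log-lik Hessian
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0):
            raise np.linalg.LinAlgError
        se[free_idx] = np.sqrt(d)
    except np.linalg.LinAlgError:
        logger.warning("observed information singular or indefinite; SEs reported absent")
    return se
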