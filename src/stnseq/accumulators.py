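"""Evidence-accumulation models of choice in the expanded judgment task.

Four nested accumulator models describe how the decision variable DV is
updated by each cue S_t (L = -1, R = +1), with DV_0 = 0:

    M1: DV_t = DV_{t-1} + S_t                       (perfect integration)
    M2: DV_t = (1-lam) DV_{t-1} + S_t               (forgetting)
    M3: DV_t = DV_{t-1} + (1 + omega SA_t) S_t      (repetition bonus)
    M4: DV_t = (1-lam) DV_{t-1} + (1 + omega SA_t) S_t

SA_t = 1 when cue t repeats cue t-1 and 0 otherwise; it is undefined for
the first cue of a trial, where the bonus term is not applied.  Choices are
linked to the decision variable through a logistic model,
ln P(R)/P(L) = beta0 + beta1 * DV_t, fitted by maximum likelihood; models
are compared by BIC = k ln(n) - 2 ln(L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from .task import TrialRecord, cues_to_array

__all__ = [
    "MODEL_IDS",
    "AccumulatorParams",
    "DVTrace",
    "ChoiceModelFit",
    "CommitmentFit",
    "FittingError",
    "compute_dv",
    "dv_final_batch",
    "choice_loglik",
    "fit_choice_model",
    "select_model",
    "commitment_regression",
]

MODEL_IDS = ("M1", "M2", "M3", "M4")
_HAS_LAMBDA = {"M2", "M4"}
_HAS_OMEGA = {"M3", "M4"}


class FittingError(RuntimeError):
    """Raised when maximum-likelihood fitting fails to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class AccumulatorParams:
    """Parameters of one accumulator model.

    ``lam`` (forgetting rate, in [0, 1]) is free only for M2/M4 and ``omega``
    (same-pair bonus weight) only for M3/M4; for other models they are
    pinned at 0.
    """

    model_id: str = "M1"
    lam: float = 0.0
    omega: float = 0.0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")
        if self.model_id not in _HAS_LAMBDA and self.lam != 0.0:
            raise ValueError(f"{self.model_id} has no forgetting term; lam must be 0")
        if self.model_id not in _HAS_OMEGA and self.omega != 0.0:
            raise ValueError(f"{self.model_id} has no bonus term; omega must be 0")

    @property
    def n_free_shape(self) -> int:
        return (self.model_id in _HAS_LAMBDA) + (self.model_id in _HAS_OMEGA)


@dataclass
class DVTrace:
    """Per-cue decision variable and repetition indicator for one trial."""

    dv: np.ndarray   # DV_t, t = 1..n
    sa: np.ndarray   # SA_t in {0,1}; SA_1 stored as 0 (undefined)
    s: np.ndarray    # cue coding S_t in {-1,+1}


def compute_dv(cues: Sequence, params: AccumulatorParams) -> DVTrace:
    """Run the selected accumulator recurrence over one cue sequence."""
    s = cues_to_array(cues).astype(float)
    n = len(s)
    sa = np.zeros(n)
    if n > 1:
        sa[1:] = (s[1:] == s[:-1]).astype(float)
    dv = np.empty(n)
    prev = 0.0
    lam, omega = params.lam, params.omega
    for t in range(n):
        bonus = 1.0 + omega * sa[t]  # sa[0] = 0: no bonus on the first cue
        prev = (1.0 - lam) * prev + bonus * s[t]
        dv[t] = prev
    return DVTrace(dv=dv, sa=sa.astype(np.int8), s=s.astype(np.int8))


def _pad_trials(trials: Sequence[TrialRecord]):
    completed = [t for t in trials if t.completed]
    n = len(completed)
    if n == 0:
        raise ValueError("no completed trials")
    max_len = max(t.n_sampled for t in completed)
    cues = np.zeros((n, max_len), dtype=float)
    lengths = np.empty(n, dtype=int)
    y = np.empty(n, dtype=float)
    for i, t in enumerate(completed):
        cues[i, : t.n_sampled] = t.cues
        lengths[i] = t.n_sampled
        y[i] = 1.0 if t.choice == 1 else 0.0
    return cues, lengths, y


def dv_final_batch(cues: np.ndarray, lengths: np.ndarray, lam: float, omega: float) -> np.ndarray:
    """Decision variable at the final sampled cue, vectorized over trials.

    ``cues`` is a zero-padded (n_trials, max_len) array of -1/+1 codes.
    """
    n, max_len = cues.shape
    dv = np.zeros(n)
    prev_s = np.zeros(n)
    out = np.zeros(n)
    for t in range(max_len):
        active = t < lengths
        s = cues[:, t]
        sa = (t >= 1) & (s == prev_s) & active
        dv = np.where(active, (1.0 - lam) * dv + (1.0 + omega * sa) * s, dv)
        out = np.where(lengths == t + 1, dv, out)
        prev_s = np.where(active, s, prev_s)
    return out


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log P = y*eta - log(1 + e^eta), stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def choice_loglik(
    trials: Sequence[TrialRecord],
    params: AccumulatorParams,
    beta0: float,
    beta1: float,
    *,
    per_stimulus: bool = False,
) -> float:
    """Log likelihood of the observed choices under the logistic link.

    By default each trial contributes one Bernoulli term for the final
    choice, evaluated at the final decision variable.  With
    ``per_stimulus=True`` every sampled cue t >= 1 contributes a term
    P(final choice | DV_t), the alternative reading of fitting "after all
    stimuli shown".
    """
    total = 0.0
    for tr in trials:
        if not tr.completed:
            continue
        trace = compute_dv(tr.cues, params)
        y_val = 1.0 if tr.choice == 1 else 0.0
        if per_stimulus:
            eta = beta0 + beta1 * trace.dv
            total += _bernoulli_loglik(eta, np.full(len(eta), y_val))
        else:
            eta = np.array([beta0 + beta1 * trace.dv[-1]])
            total += _bernoulli_loglik(eta, np.array([y_val]))
    return total


def _logit_mle(x: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100):
    """Newton-Raphson MLE of logistic y ~ 1 + x; returns (b0, b1, ll, cov)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (y - p) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(2)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen huge steps (near-separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if norm < 1e-10:
            break
    eta = X @ beta
    ll = _bernoulli_loglik(eta, y) - 0.5 * ridge * float(beta @ beta)
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X + ridge * np.eye(2)
    cov = np.linalg.pinv(H)
    return beta[0], beta[1], ll, cov


@dataclass
class ChoiceModelFit:
    """Maximum-likelihood fit of one accumulator model with logistic link."""

    params: AccumulatorParams
    beta0: float
    beta1: float
    loglik: float
    bic: float
    n_obs: int
    converged: bool = True
    n_restarts: int = 0
    se_beta1: float = float("nan")

    @property
    def k(self) -> int:
        return 2 + self.params.n_free_shape

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        d["k"] = self.k
        return d


# deterministic multistart grid (lam, omega) for the shape parameters
_STARTS = [(0.05, 0.0), (0.3, 0.5), (0.6, -0.5), (0.9, 1.0), (0.15, -1.0)]


def fit_choice_model(
    trials: Sequence[TrialRecord],
    model_id: str = "M1",
    *,
    n_starts: int = 5,
    tol: float = 1e-8,
) -> ChoiceModelFit:
    """Fit (beta0, beta1, and lam/omega where free) by maximum likelihood.

    The shape parameters are optimized by bounded L-BFGS-B from ``n_starts``
    deterministic start points; for each candidate (lam, omega) the logistic
    link parameters are profiled out exactly by Newton-Raphson, so the
    profile optimum coincides with the joint MLE.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    cues, lengths, y = _pad_trials(trials)
    n = len(y)
    if n < 20:
        raise ValueError(f"need >= 20 completed trials, got {n}")

    has_lam = model_id in _HAS_LAMBDA
    has_omega = model_id in _HAS_OMEGA

    def unpack(theta):
        i = 0
        lam = 0.0
        omega = 0.0
        if has_lam:
            lam = theta[i]
            i += 1
        if has_omega:
            omega = theta[i]
        return lam, omega

    cache = {}

    def neg_profile_ll(theta):
        lam, omega = unpack(theta)
        dv = dv_final_batch(cues, lengths, lam, omega)
        b0, b1, ll, cov = _logit_mle(dv, y)
        cache["last"] = (lam, omega, b0, b1, ll, cov)
        return -ll

    if not (has_lam or has_omega):
        dv = dv_final_batch(cues, lengths, 0.0, 0.0)
        b0, b1, ll, cov = _logit_mle(dv, y)
        params = AccumulatorParams(model_id=model_id)
        bic = 2 * np.log(n) - 2 * ll
        return ChoiceModelFit(params, b0, b1, ll, bic, n, True, 0, float(np.sqrt(cov[1, 1])))

    bounds = []
    if has_lam:
        bounds.append((0.0, 1.0))
    if has_omega:
        bounds.append((-2.0, 2.0))

    best = None
    n_fail = 0
    for start in _STARTS[:n_starts]:
        x0 = []
        if has_lam:
            x0.append(start[0])
        if has_omega:
            x0.append(start[1])
        res = optimize.minimize(
            neg_profile_ll,
            np.asarray(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8},
        )
        if not res.success and not np.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError(
            f"{model_id}: all {n_starts} restarts failed",
            {"model_id": model_id, "n_failures": n_fail, "n_obs": n},
        )

    lam, omega = unpack(best.x)
    dv = dv_final_batch(cues, lengths, lam, omega)
    b0, b1, ll, cov = _logit_mle(dv, y)
    params = AccumulatorParams(
        model_id=model_id,
        lam=float(lam) if has_lam else 0.0,
        omega=float(omega) if has_omega else 0.0,
    )
    k = 2 + has_lam + has_omega
    bic = k * np.log(n) - 2 * ll
    return ChoiceModelFit(
        params, b0, b1, ll, bic, n, bool(best.success), n_fail, float(np.sqrt(cov[1, 1]))
    )


def select_model(
    trials: Sequence[TrialRecord], models: Sequence[str] = MODEL_IDS
) -> list[ChoiceModelFit]:
    """Fit every candidate model on the same trials; rank ascending by BIC.

    The first element is the BIC winner.  Models whose fit fails are
    excluded with a warning.
    """
    fits = []
    for mid in models:
        try:
            fits.append(fit_choice_model(trials, mid))
        except FittingError as exc:
            warnings.warn(f"model {mid} excluded from selection: {exc}")
    if not fits:
        raise FittingError("all candidate models failed to fit")
    fits.sort(key=lambda f: f.bic)
    return fits


@dataclass
class CommitmentFit:
    """Logistic regression of choice commitment on evidence and repetition.

    For every cue t >= 2 the binary outcome D_t indicates whether the
    response was made after that cue; predictors are the evidence for the
    eventually chosen option (DV_t signed toward the final choice) and the
    repetition indicator SA_t.
    """

    coef_evidence: float
    coef_same: float
    p_evidence: float
    p_same: float
    classification: str
    n_obs: int
    separation: bool = False
    alpha: float = 0.05


def commitment_regression(
    trials: Sequence[TrialRecord],
    params: AccumulatorParams | None = None,
    *,
    alpha: float = 0.05,
) -> CommitmentFit:
    """Which factors drive the decision to stop sampling and respond?

    Fits D_t ~ evidence_for_chosen + SA_t over all cues t >= 2 of completed
    trials (the first cue has no defined SA_t).  Wald p-values at ``alpha``
    classify the stopper as evidence_only, same_only, both or neither.
    Complete separation triggers a ridge-penalized refit and is flagged.
    """
    if params is None:
        params = AccumulatorParams("M1")
    rows_ev, rows_sa, rows_d = [], [], []
    for tr in trials:
        if not tr.completed or tr.n_sampled < 2:
            continue
        trace = compute_dv(tr.cues, params)
        for t in range(1, tr.n_sampled):  # 0-based; cue index t+1 >= 2
            rows_ev.append(trace.dv[t] * tr.choice)
            rows_sa.append(trace.sa[t])
            rows_d.append(1.0 if t == tr.n_sampled - 1 else 0.0)
    if len(rows_d) < 10:
        raise ValueError("too few stimulus observations for commitment regression")

    import statsmodels.api as sm
    from scipy import stats as sps

    X = sm.add_constant(np.column_stack([rows_ev, rows_sa]))
    y = np.asarray(rows_d)
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coefs = res.params
        pvals = res.pvalues
        if not np.all(np.isfinite(pvals)) or np.max(np.abs(coefs)) > 25.0:
            raise RuntimeError("separation suspected")
    except Exception:
        separation = True
        # ridge-penalized Newton refit; Wald p-values from penalized Hessian
        beta = np.zeros(3)
        ridge = 1.0
        for _ in range(200):
            eta = X @ beta
            p = expit(eta)
            w = np.clip(p * (1 - p), 1e-12, None)
            grad = X.T @ (y - p) - ridge * beta
            H = (X * w[:, None]).T @ X + ridge * np.eye(3)
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X + ridge * np.eye(3)
        cov = np.linalg.pinv(H)
        coefs = beta
        z = beta / np.sqrt(np.diag(cov))
        pvals = 2 * sps.norm.sf(np.abs(z))

    sig_ev = pvals[1] < alpha
    sig_sa = pvals[2] < alpha
    if sig_ev and sig_sa:
        cls = "both"
    elif sig_ev:
        cls = "evidence_only"
    elif sig_sa:
        cls = "same_only"
    else:
        cls = "neither"
    return CommitmentFit(
        coef_evidence=float(coefs[1]),
        coef_same=float(coefs[2]),
        p_evidence=float(pvals[1]),
        p_same=float(pvals[2]),
        classification=cls,
        n_obs=len(y),
        separation=separation,
        alpha=alpha,
    )
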