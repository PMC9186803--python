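"""Per-timepoint GLMs, condition contrasts and cluster-based permutation tests.

Band-power epochs are regressed (ordinary least squares) on z-scored per-cue
regressors at every timepoint, or contrasted between "same" and "different"
cues.  Multiple comparisons across time (and frequency) are corrected with
the cluster-based permutation approach: contiguous runs of
supra-threshold statistics form clusters, the cluster statistic is the sum
of the pointwise statistics (mass), and family-wise error is controlled by
the permutation null distribution of the maximum cluster mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .spectral import BandPowerEpochs

__all__ = [
    "GLMResult",
    "Cluster",
    "ClusterResult",
    "ContrastResult",
    "build_design",
    "timepoint_glm",
    "contrast_cluster_test",
    "glm_cluster_test",
    "group_cluster_test",
    "same_different_contrast",
]

DESIGN_COLUMNS = ("cue_identity", "bayes_norm", "abs_evidence", "cue_number")

_T_CAP = 1e8


# ---------------------------------------------------------------------------
# design + GLM

def build_design(
    epochs: BandPowerEpochs,
    regressors: pd.DataFrame,
    columns: Sequence[str] = DESIGN_COLUMNS,
):
    """Assemble (Y, X, names) for the combined per-timepoint GLM.

    Joins the epoch table with the per-cue regressor table on
    (trial, cue_index), drops the first and last cue of every trial, recodes
    cue identity as different = 1 / same = 0, and z-scores every column.
    Returns the matching power matrix, the standardized design and the
    regressor names.
    """
    info = epochs.info.reset_index(drop=True).copy()
    info["row"] = np.arange(len(info))
    reg = regressors.copy()
    reg["cue_identity"] = 1.0 - reg["cue_identity_same"]
    merged = info.merge(
        reg, left_on=["trial", "cue_index"], right_on=["trial", "cue_index"], how="inner"
    )
    keep = ~(merged["is_first"] | merged["is_last"])
    merged = merged.loc[keep]
    X = np.column_stack([merged[c].to_numpy(dtype=float) for c in columns])
    if np.isnan(X).any():
        raise ValueError("design contains missing values after exclusions")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(columns, sd) if s == 0]
        raise ValueError(f"constant regressor column(s): {bad}")
    X = (X - X.mean(axis=0)) / sd
    Y = epochs.data[merged["row"].to_numpy()]
    return Y, X, list(columns)


@dataclass
class GLMResult:
    """OLS coefficients and t statistics per regressor and timepoint."""

    coef: np.ndarray   # (n_regressors, n_times)
    se: np.ndarray
    t: np.ndarray
    names: list[str]
    df: int


def _check_rank(Xd: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        r = np.abs(np.diag(np.linalg.qr(Xd, mode="r")))
        bad = [names[i - 1] for i in range(1, Xd.shape[1]) if r[i] < 1e-10 * r.max()]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")


def timepoint_glm(Y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None) -> GLMResult:
    """Independent OLS fit of the epoch power at every timepoint.

    ``Y`` is (n_epochs, n_times), ``X`` (n_epochs, n_regressors) already
    standardized; an intercept is added internally.  t statistics are capped
    where the fit is exact (zero residual variance).
    """
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if n <= p + 10:
        raise ValueError(f"need more than {p + 10} epochs, got {n}")
    Xd = np.column_stack([np.ones(n), X])
    _check_rank(Xd, names)
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    B = xtx_inv @ Xd.T @ Y                     # (p+1, n_times)
    resid = Y - Xd @ B
    df = n - (p + 1)
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, np.sign(B) * _T_CAP)
    t = np.clip(t, -_T_CAP, _T_CAP)
    return GLMResult(coef=B[1:], se=se[1:], t=t[1:], names=list(names), df=df)


# ---------------------------------------------------------------------------
# cluster machinery

@dataclass
class Cluster:
    """One supra-threshold cluster: boolean mask, signed mass, FWE p-value."""

    mask: np.ndarray
    mass: float
    p_fwe: float
    sign: int
    cohen_d: float = float("nan")

    @property
    def extent(self) -> int:
        return int(self.mask.sum())


@dataclass
class ClusterResult:
    """Observed statistic map with permutation-corrected clusters."""

    stat: np.ndarray
    threshold: float
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    n_perm: int
    df: int = 0

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe < alpha]

    def any_significant(self, alpha: float = 0.05) -> bool:
        return len(self.significant(alpha)) > 0

    def to_dict(self, times: np.ndarray | None = None) -> dict:
        out = {
            "threshold": float(self.threshold),
            "n_perm": int(self.n_perm),
            "clusters": [],
        }
        for c in self.clusters:
            d = {
                "mass": float(c.mass),
                "p_fwe": float(c.p_fwe),
                "sign": int(c.sign),
                "extent": c.extent,
                "cohen_d": float(c.cohen_d),
            }
            if times is not None and c.mask.ndim == 1:
                idx = np.where(c.mask)[0]
                d["window_ms"] = [float(times[idx[0]] * 1000), float(times[idx[-1]] * 1000)]
            out["clusters"].append(d)
        return out


def _batch_structure(ndim: int) -> np.ndarray:
    """Connectivity that never joins clusters across the leading (perm) axis."""
    if ndim == 2:
        return np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])
    s = np.zeros((3, 3, 3), dtype=int)
    s[1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    return s


def _null_max_mass(tmaps: np.ndarray, threshold: float) -> np.ndarray:
    """Max |cluster mass| per permutation, vectorized over the stack."""
    n_perm = tmaps.shape[0]
    out = np.zeros(n_perm)
    structure = _batch_structure(tmaps.ndim)
    for sign in (1, -1):
        mask = (sign * tmaps) > threshold
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        masses = ndimage.sum_labels(np.abs(tmaps), labels, index=np.arange(1, n + 1))
        rows = np.array([slc[0].start for slc in ndimage.find_objects(labels)])
        np.maximum.at(out, rows, masses)
    return out


def _observed_clusters(stat: np.ndarray, threshold: float):
    found = []
    for sign in (1, -1):
        mask = (sign * stat) > threshold
        if not mask.any():
            continue
        labels, n = ndimage.label(mask)
        for i in range(1, n + 1):
            m = labels == i
            found.append((m, float(stat[m].sum()), sign))
    return found


def _assemble(stat, threshold, found, null_max, n_perm, df) -> ClusterResult:
    clusters = []
    for mask, mass, sign in found:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(Cluster(mask=mask, mass=mass, p_fwe=float(p), sign=sign))
    clusters.sort(key=lambda c: c.p_fwe)
    return ClusterResult(
        stat=stat, threshold=threshold, clusters=clusters,
        null_max_mass=null_max, n_perm=n_perm, df=df,
    )


def _two_sample_t(sumA, sumA2, nA, sum_tot, sum2_tot, n):
    nB = n - nA
    sumB = sum_tot - sumA
    sumB2 = sum2_tot - sumA2
    mA = sumA / nA
    mB = sumB / nB
    ssA = np.maximum(sumA2 - nA * mA**2, 0.0)
    ssB = np.maximum(sumB2 - nB * mB**2, 0.0)
    sp2 = (ssA + ssB) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mA - mB) / denom, 0.0)
    return t


def contrast_cluster_test(
    Y: np.ndarray,
    labels: np.ndarray,
    *,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    rng: np.random.Generator | int = 0,
) -> ClusterResult:
    """Cluster-corrected two-sample t contrast (labels True = condition A).

    The cluster-forming threshold is the two-sided parametric t critical
    value at ``cluster_alpha``; cluster mass is the sum of t values; the
    null is the permutation (label-shuffle) distribution of the maximum
    cluster mass; p_fwe = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse")
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    nA = int(labels.sum())
    if nA == 0 or nA == n:
        raise ValueError("both conditions must be non-empty")
    df = n - 2
    threshold = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df))

    flatY = Y.reshape(n, -1)
    flatY2 = flatY**2
    lab_f = labels.astype(float)
    sum_tot = flatY.sum(axis=0)
    sum2_tot = flatY2.sum(axis=0)
    obs_t = _two_sample_t(lab_f @ flatY, lab_f @ flatY2, nA, sum_tot, sum2_tot, n)
    obs_t = obs_t.reshape(Y.shape[1:])

    P = rng.permuted(np.tile(lab_f, (n_perm, 1)), axis=1)
    perm_t = _two_sample_t(
        P @ flatY, P @ flatY2, nA, sum_tot, sum2_tot, n
    ).reshape((n_perm,) + Y.shape[1:])

    null_max = _null_max_mass(perm_t, threshold)
    found = _observed_clusters(obs_t, threshold)
    res = _assemble(obs_t, threshold, found, null_max, n_perm, df)
    # Cohen's d: cluster-mean difference over pooled SD across epochs
    for c in res.clusters:
        xm = Y.reshape(n, -1)[:, c.mask.ravel()].mean(axis=1)
        a, b = xm[labels], xm[~labels]
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df)
        c.cohen_d = float((a.mean() - b.mean()) / sp) if sp > 0 else float("nan")
    return res


def glm_cluster_test(
    Y: np.ndarray,
    X: np.ndarray,
    regressor: int,
    *,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int = 0,
    scheme: str = "row_shuffle",
    names: Sequence[str] | None = None,
) -> ClusterResult:
    """Cluster-corrected test of one regressor's t series from the GLM.

    scheme "row_shuffle" permutes the rows of the full design jointly
    against the data (preserving inter-regressor correlation);
    "freedman_lane" permutes the residuals of the reduced model.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    res = timepoint_glm(Y, X, names)
    obs_t = res.t[regressor]
    threshold = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, res.df))

    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    pinv = xtx_inv @ Xd.T
    cjj = xtx_inv[regressor + 1, regressor + 1]
    df = res.df

    if scheme == "freedman_lane":
        reduced = np.delete(Xd, regressor + 1, axis=1)
        Hr = reduced @ np.linalg.inv(reduced.T @ reduced) @ reduced.T
        fit_r = Hr @ Y
        resid_r = Y - fit_r
    elif scheme != "row_shuffle":
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    perm_t = np.empty((n_perm,) + obs_t.shape)
    for i in range(n_perm):
        idx = rng.permutation(n)
        Yp = (fit_r + resid_r[idx]) if scheme == "freedman_lane" else Y[idx]
        B = pinv @ Yp
        sigma2 = ((Yp - Xd @ B) ** 2).sum(axis=0) / df
        denom = np.sqrt(cjj * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            perm_t[i] = np.where(denom > 0, B[regressor + 1] / denom, 0.0)

    null_max = _null_max_mass(perm_t, threshold)
    found = _observed_clusters(obs_t, threshold)
    out = _assemble(obs_t, threshold, found, null_max, n_perm, df)
    for c in out.clusters:
        tbar = float(np.mean(obs_t[c.mask]))
        out_d = 2.0 * tbar / np.sqrt(df)
        c.cohen_d = out_d
    return out


def group_cluster_test(
    subject_traces: np.ndarray,
    *,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int = 0,
) -> ClusterResult:
    """One-sample t across subjects with sign-flip permutations.

    ``subject_traces`` is (n_subjects, ...) of per-subject effect maps
    (e.g. different-minus-same difference traces); exchangeability follows
    from symmetry of the per-subject effect under the null.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    Xs = np.asarray(subject_traces, dtype=float)
    ns = Xs.shape[0]
    if ns < 2:
        raise ValueError("need at least 2 subjects")
    df = ns - 1
    threshold = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df))

    def one_sample_t(data):
        m = data.mean(axis=0)
        s = data.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, m / (s / np.sqrt(ns)), 0.0)

    obs_t = one_sample_t(Xs)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, ns))
    flat = Xs.reshape(ns, -1)
    perm_t = np.empty((n_perm, flat.shape[1]))
    for i in range(n_perm):
        perm_t[i] = one_sample_t(signs[i][:, None] * flat)
    perm_t = perm_t.reshape((n_perm,) + Xs.shape[1:])

    null_max = _null_max_mass(perm_t, threshold)
    found = _observed_clusters(obs_t, threshold)
    out = _assemble(obs_t, threshold, found, null_max, n_perm, df)
    for c in out.clusters:
        xm = flat[:, c.mask.ravel()].mean(axis=1)
        sd = xm.std(ddof=1)
        c.cohen_d = float(xm.mean() / sd) if sd > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# same / different contrast with carry-over

@dataclass
class ContrastResult:
    """Different-minus-same power difference with cluster statistics."""

    times: np.ndarray
    difference: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    mean_same: np.ndarray
    mean_different: np.ndarray
    cluster: ClusterResult
    n_same: int
    n_different: int
    data: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def same_different_contrast(
    epochs: BandPowerEpochs,
    regressors: pd.DataFrame,
    *,
    carryover: bool = True,
    exclude_next_last: bool = True,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int = 0,
    min_epochs: int = 10,
) -> ContrastResult:
    """Contrast cues that repeat vs differ from their predecessor.

    Cues with index i > 1 that are not the trial's final cue are labelled
    "same" or "different" by their relation to cue i-1.  With ``carryover``
    (default) each observation concatenates the power at cue i (0-750 ms)
    with the following cue's epoch (800-1600 ms, labelled by the relation at
    cue i), covering the 0-1600 ms span; otherwise only 0-800 ms of cue i is
    used.  By default observations whose following cue is the trial's final
    cue are excluded as well (``exclude_next_last``): their carry-over
    window abuts the response period and post-trial silence, whose proximity
    is condition-dependent for evidence-sensitive stoppers and would
    masquerade as a late power effect.  Returns the difference trace with a
    pointwise 95% CI and the cluster-permutation result.
    """
    info = epochs.info.reset_index(drop=True)
    reg = regressors.set_index(["trial", "cue_index"])["cue_identity_same"]
    row_of = {(r.trial, r.cue_index): i for i, r in info.iterrows()}
    last_cue = info.groupby("trial")["cue_index"].transform("max")

    i0 = int(np.argmin(np.abs(epochs.times)))          # index of t = 0
    n_within = int(round(0.8 / (epochs.times[1] - epochs.times[0])))  # 16 steps to 0.75

    obs_rows, obs_labels = [], []
    for i, r in info.iterrows():
        if r.is_first or r.is_last:
            continue
        key = (r.trial, r.cue_index)
        if key not in reg.index:
            continue
        sa = reg.loc[key]
        if not np.isfinite(sa):
            continue
        if exclude_next_last and r.cue_index + 1 == last_cue[i]:
            continue
        if carryover:
            nxt = row_of.get((r.trial, r.cue_index + 1))
            if nxt is None:
                continue
            x = np.concatenate(
                [epochs.data[i, i0 : i0 + n_within], epochs.data[nxt, i0 : i0 + n_within + 1]]
            )
        else:
            x = epochs.data[i, i0 : i0 + n_within + 1]
        obs_rows.append(x)
        obs_labels.append(sa == 0.0)  # True = "different"

    Y = np.asarray(obs_rows)
    labels = np.asarray(obs_labels, dtype=bool)
    n_diff = int(labels.sum())
    n_same = int((~labels).sum())
    if n_diff < min_epochs or n_same < min_epochs:
        raise ValueError(
            f"need >= {min_epochs} epochs per condition, got same={n_same}, different={n_diff}"
        )

    step = float(epochs.times[1] - epochs.times[0])
    times = np.arange(Y.shape[1]) * step

    mean_d = Y[labels].mean(axis=0)
    mean_s = Y[~labels].mean(axis=0)
    diff = mean_d - mean_s
    se = np.sqrt(Y[labels].var(axis=0, ddof=1) / n_diff + Y[~labels].var(axis=0, ddof=1) / n_same)
    tcrit = stats.t.ppf(0.975, n_diff + n_same - 2)

    cluster = contrast_cluster_test(
        Y, labels, n_perm=n_perm, cluster_alpha=cluster_alpha, rng=rng
    )
    return ContrastResult(
        times=times,
        difference=diff,
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        mean_same=mean_s,
        mean_different=mean_d,
        cluster=cluster,
        n_same=n_same,
        n_different=n_diff,
        data=Y,
        labels=labels,
    )
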