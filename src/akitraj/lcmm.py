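"""Latent class mixed models for longitudinal percent-change trajectories.

A finite mixture of linear mixed models: subject *i* in latent class *g*
has

    y_i = X_i beta_g + Z_i b_i + eps_i,
    b_i ~ N(0, D),   eps_i ~ N(0, sigma^2 I),
    P(class = g) = pi_g = softmax(xi)_g,

with class-specific polynomial fixed effects of normalized time,
random-effect structure shared across classes (intercept, or
intercept+slope) and a shared residual variance.  The marginal
log-likelihood

    sum_i log sum_g pi_g N(y_i; X_i beta_g, Z_i D Z_i' + sigma^2 I)

is maximized by EM treating both the class label and the random effects
as missing data, so the observed-data log-likelihood is non-decreasing
across iterations.  Per-subject Gaussian terms use the Woodbury
identity, vectorized over all observations with segment reductions, so
fitting scales linearly in the number of measurements.

Model selection over a range of class counts uses the Bayesian
Information Criterion, BIC = -2 loglik + k log(n_subjects), with the
subject count as sample size (the growth-mixture literature default).
Classes are relabeled in increasing order of the fitted mean trajectory
at t = 0 so labels are stable across random starts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

_LOG2PI = np.log(2.0 * np.pi)
MODEL_SCHEMA_VERSION = 1


@dataclass
class LCMMSpec:
    """Model structure: class count, fixed-effect degree, random effects."""

    G: int
    fixed_degree: int = 3
    random_structure: str = "intercept"      # "intercept" | "intercept+slope"
    time_normalization: float = 96.0         # hours mapped to [0, 1]

    def __post_init__(self):
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.fixed_degree < 1:
            raise ValueError("fixed_degree must be >= 1")
        if self.random_structure not in ("intercept", "intercept+slope"):
            raise ValueError(
                f"unknown random structure {self.random_structure!r}")

    @property
    def n_random(self) -> int:
        return 1 if self.random_structure == "intercept" else 2

    def n_params(self) -> int:
        q = self.n_random
        return (self.G * (self.fixed_degree + 1)   # class fixed effects
                + q * (q + 1) // 2                 # free entries of D
                + 1                                # sigma^2
                + (self.G - 1))                    # membership logits


@dataclass
class LCMMFit:
    spec: LCMMSpec
    beta: np.ndarray          # (G, p) class fixed effects
    re_cov: np.ndarray        # (q, q) random-effect covariance D
    sigma2: float
    xi: np.ndarray            # (G,) membership logits, last fixed at 0
    loglik: float
    n_params: int
    bic: float
    posterior: np.ndarray     # (n_subjects, G)
    converged: bool
    n_subjects: int
    subject_ids: list = field(default_factory=list)
    loglik_history: list = field(default_factory=list)

    @property
    def class_probs(self) -> np.ndarray:
        e = np.exp(self.xi - self.xi.max())
        return e / e.sum()

    def to_json(self) -> str:
        """Serialize the trained model (without posteriors) for shipping."""
        return json.dumps({
            "schema_version": MODEL_SCHEMA_VERSION,
            "spec": {"G": self.spec.G, "fixed_degree": self.spec.fixed_degree,
                     "random_structure": self.spec.random_structure,
                     "time_normalization": self.spec.time_normalization},
            "beta": self.beta.tolist(),
            "re_cov": self.re_cov.tolist(),
            "sigma2": self.sigma2,
            "xi": self.xi.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LCMMFit":
        d = json.loads(text)
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        spec = LCMMSpec(**d["spec"])
        return cls(spec=spec, beta=np.asarray(d["beta"], float),
                   re_cov=np.asarray(d["re_cov"], float),
                   sigma2=float(d["sigma2"]), xi=np.asarray(d["xi"], float),
                   loglik=float(d["loglik"]), n_params=int(d["n_params"]),
                   bic=float(d["bic"]),
                   posterior=np.zeros((0, spec.G)),
                   converged=bool(d["converged"]),
                   n_subjects=int(d["n_subjects"]))


@dataclass
class ClassAssignment:
    patient_id: str
    assigned_class: int       # 1-based
    max_posterior: float


@dataclass
class DiscriminationReport:
    mpcmp: np.ndarray         # per-class mean posterior membership prob
    class_sizes: np.ndarray


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

class _Stacked:
    """Trajectory data stacked over subjects for segment reductions."""

    def __init__(self, ids, t_hours, y, spec: LCMMSpec):
        ids = np.asarray(ids)
        t_hours = np.asarray(t_hours, float)
        y = np.asarray(y, float)
        order = np.lexsort((t_hours, ids))
        ids, t_hours, y = ids[order], t_hours[order], y[order]
        uniq, start = np.unique(ids, return_index=True)
        # np.unique sorts; keep that subject order
        self.subject_ids = [str(u) for u in uniq]
        self.starts = start
        self.n_subjects = len(uniq)
        self.n_i = np.diff(np.append(start, len(ids)))
        if np.any(self.n_i < 1):
            raise ValueError("every subject needs >= 1 observation")
        self.y = y
        u = t_hours / spec.time_normalization
        self.X = np.vander(u, spec.fixed_degree + 1, increasing=True)
        q = spec.n_random
        self.Z = self.X[:, :q].copy()
        self.obs_subject = np.repeat(np.arange(self.n_subjects), self.n_i)
        # per-subject Z'Z, stacked (n, q, q)
        ZZ = self.Z[:, :, None] * self.Z[:, None, :]
        self.ZtZ = np.add.reduceat(ZZ.reshape(len(y), q * q),
                                   self.starts, axis=0).reshape(-1, q, q)

    def segsum(self, v):
        return np.add.reduceat(v, self.starts, axis=0)


def stack_trajectories(data, spec: LCMMSpec) -> _Stacked:
    """Accept a (patient_id, t_hours, pct) DataFrame or TrajectorySeries list."""
    if isinstance(data, _Stacked):
        return data
    if isinstance(data, pd.DataFrame):
        return _Stacked(data["patient_id"].to_numpy(),
                        data["t_hours"].to_numpy(),
                        data["pct"].to_numpy(), spec)
    ids, ts, ys = [], [], []
    for series in data:
        for t, p in series.points:
            ids.append(series.patient_id)
            ts.append(t)
            ys.append(p)
    return _Stacked(np.asarray(ids), np.asarray(ts), np.asarray(ys), spec)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _component_logdens(st: _Stacked, beta, D, sigma2):
    """log N(y_i; X_i beta_g, Z_i D Z_i' + sigma^2 I) for all i, g.

    Woodbury / matrix-determinant lemma on the q-dimensional random
    effect: with M_i = Z_i'Z_i, C_i = (sigma^2 D^{-1} + M_i)^{-1},

      quad_i  = (||r_i||^2 - r'Z C Z'r) / sigma^2
      logdet_i = n_i log sigma^2 + log det(I + D M_i / sigma^2)
    """
    G = beta.shape[0]
    q = D.shape[0]
    n, n_i = st.n_subjects, st.n_i
    Dinv = np.linalg.inv(D)
    A = sigma2 * Dinv[None, :, :] + st.ZtZ          # (n, q, q)
    C = np.linalg.inv(A)
    sign, logdet_A = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        raise ValueError("random-effect covariance not positive definite")
    _, logdet_D = np.linalg.slogdet(D)
    # log det V_i = n_i log s2 + log det(D) + log det(A) - q log s2
    logdet_V = (n_i - q) * np.log(sigma2) + logdet_D + logdet_A
    out = np.empty((n, G))
    for g in range(G):
        r = st.y - st.X @ beta[g]
        ssr = st.segsum(r * r)
        Ztr = st.segsum(st.Z * r[:, None])          # (n, q)
        corr = np.einsum("nq,nqr,nr->n", Ztr, C, Ztr)
        quad = (ssr - corr) / sigma2
        out[:, g] = -0.5 * (n_i * _LOG2PI + logdet_V + quad)
    return out


def loglik(params: dict, data, spec: Optional[LCMMSpec] = None) -> float:
    """Observed-data log-likelihood of an LCMM parameter set.

    ``params`` needs ``beta`` (G, p), ``re_cov`` (q, q), ``sigma2`` and
    ``xi`` (G,); returns sum_i log sum_g pi_g N_ig.
    """
    beta = np.atleast_2d(np.asarray(params["beta"], float))
    D = np.atleast_2d(np.asarray(params["re_cov"], float))
    sigma2 = float(params["sigma2"])
    xi = np.asarray(params["xi"], float)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if np.any(np.linalg.eigvalsh(D) <= 0):
        raise ValueError("random-effect covariance not positive definite")
    if spec is None:
        spec = LCMMSpec(G=beta.shape[0], fixed_degree=beta.shape[1] - 1,
                        random_structure="intercept" if D.shape[0] == 1
                        else "intercept+slope")
    st = stack_trajectories(data, spec)
    logpi = xi - logsumexp(xi)
    ld = _component_logdens(st, beta, D, sigma2)
    return float(logsumexp(ld + logpi[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _em_run(st: _Stacked, spec: LCMMSpec, beta0, D0, s20, xi0,
            tol: float, max_iter: int):
    """One EM run; returns (beta, D, sigma2, xi, loglik, posterior, converged)."""
    G, q = spec.G, spec.n_random
    beta = beta0.copy()
    D = D0.copy()
    sigma2 = float(s20)
    xi = xi0.copy()
    n, n_i, N = st.n_subjects, st.n_i, len(st.y)
    ll_old = -np.inf
    converged = False
    history = []
    W = np.full((n, G), 1.0 / G)
    for _ in range(max_iter):
        logpi = xi - logsumexp(xi)
        ld = _component_logdens(st, beta, D, sigma2)
        joint = ld + logpi[None, :]
        ll = float(logsumexp(joint, axis=1).sum())
        history.append(ll)
        W = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        if np.max(W, axis=0).min() < 1e-6:
            return beta, D, sigma2, xi, ll, W, False, True, history
        # posterior moments of b_i | y, class g
        Dinv = np.linalg.inv(D)
        C = np.linalg.inv(Dinv[None] + st.ZtZ / sigma2)     # (n, q, q)
        M = np.empty((n, G, q))
        for g in range(G):
            r = st.y - st.X @ beta[g]
            Ztr = st.segsum(st.Z * r[:, None])
            M[:, g] = np.einsum("nqr,nr->nq", C, Ztr) / sigma2
        # M-step
        xi = np.log(np.maximum(W.mean(axis=0), 1e-300))
        xi = xi - xi[-1]
        Ebb = (np.einsum("ng,ngq,ngr->qr", W, M, M)
               + np.einsum("ng,nqr->qr", W, C))
        D = Ebb / n
        sse = 0.0
        for g in range(G):
            w_obs = W[st.obs_subject, g]
            offset = (st.Z * M[st.obs_subject, g]).sum(axis=1)
            A = st.X.T @ (w_obs[:, None] * st.X)
            bvec = st.X.T @ (w_obs * (st.y - offset))
            beta[g] = np.linalg.solve(A, bvec)
            r2 = st.y - st.X @ beta[g] - offset
            sse += float(w_obs @ (r2 * r2))
        trZCZ = np.einsum("nqr,nrq->n", C, st.ZtZ)          # tr(C_i Z'Z)
        sigma2 = (sse + float((W * trZCZ[:, None]).sum())) / N
        sigma2 = max(sigma2, 1e-10)
        D = D + 1e-10 * np.eye(q)
        if ll - ll_old < tol * (abs(ll_old) + 1.0) and np.isfinite(ll_old):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    # final E-step at the returned parameters
    logpi = xi - logsumexp(xi)
    ld = _component_logdens(st, beta, D, sigma2)
    joint = ld + logpi[None, :]
    ll = float(logsumexp(joint, axis=1).sum())
    history.append(ll)
    W = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    return beta, D, sigma2, xi, ll, W, converged, False, history


def _single_class_fit(st: _Stacked, spec: LCMMSpec):
    """OLS + moment estimates; the seed for perturbed EM starts."""
    beta, *_ = np.linalg.lstsq(st.X, st.y, rcond=None)
    r = st.y - st.X @ beta
    means = st.segsum(r) / st.n_i
    tau2 = max(float(np.var(means)), 1e-3)
    s2 = max(float(np.var(r)) - tau2, 1e-3)
    return beta, tau2, s2


def _kmeans_start(st: _Stacked, spec: LCMMSpec, rng):
    """k-means on per-subject binned trajectory summaries.

    A heterogeneous start in the spirit of grid-search initialization
    for growth-mixture models; bins at 0-32-64-96 h of normalized time
    summarize each subject's level and shape.
    """
    u = st.X[:, 1] if st.X.shape[1] > 1 else np.zeros(len(st.y))
    nbins = 4
    edges = np.linspace(0.0, 1.0, nbins + 1)
    edges[-1] += 1e-9
    feats = np.zeros((st.n_subjects, nbins))
    overall = st.segsum(st.y) / st.n_i
    for b in range(nbins):
        mask = (u >= edges[b]) & (u < edges[b + 1])
        num = st.segsum(np.where(mask, st.y, 0.0))
        den = st.segsum(mask.astype(float))
        feats[:, b] = np.where(den > 0, num / np.maximum(den, 1), overall)
    # plain Lloyd iterations, best of a few inits, deterministic given rng
    k = spec.G
    best_labels, best_ss = None, np.inf
    for _ in range(8):
        idx = rng.choice(st.n_subjects, size=k, replace=False)
        centers = feats[idx]
        labels = np.zeros(st.n_subjects, int)
        for _ in range(25):
            d = ((feats[:, None, :] - centers[None]) ** 2).sum(axis=2)
            labels = d.argmin(axis=1)
            for j in range(k):
                if np.any(labels == j):
                    centers[j] = feats[labels == j].mean(axis=0)
        ss = float(((feats - centers[labels]) ** 2).sum())
        if ss < best_ss:
            best_ss, best_labels = ss, labels.copy()
    labels = best_labels
    p = st.X.shape[1]
    beta0 = np.zeros((k, p))
    for j in range(k):
        sel = np.isin(st.obs_subject, np.where(labels == j)[0])
        if sel.sum() > p:
            beta0[j], *_ = np.linalg.lstsq(st.X[sel], st.y[sel], rcond=None)
        else:
            beta0[j], *_ = np.linalg.lstsq(st.X, st.y, rcond=None)
    return beta0


def fit_lcmm(data, spec: LCMMSpec, n_starts: int = 10, tol: float = 1e-8,
             max_iter: int = 500, seed: int = 0) -> LCMMFit:
    """Maximum-likelihood LCMM fit over multiple EM starts.

    The first start is seeded by k-means on binned subject summaries,
    the rest by random perturbations of a single-class fit; the
    best-log-likelihood solution is returned with classes relabeled in
    increasing order of the fitted mean at t = 0.
    """
    st = stack_trajectories(data, spec)
    G, q, p = spec.G, spec.n_random, spec.fixed_degree + 1
    if st.n_subjects < G * p:
        raise ValueError("too few subjects for the requested class count")
    rng = np.random.default_rng(seed)
    beta1, tau2, s2 = _single_class_fit(st, spec)
    D0 = np.eye(q) * tau2
    if q == 2:
        D0[1, 1] = tau2 / 4.0
    scale = max(np.std(st.y), 1.0)
    best = None
    attempts = 0
    start = 0
    while start < n_starts and attempts < 3 * n_starts:
        attempts += 1
        if start < max(1, n_starts // 2) and G > 1:
            beta0 = _kmeans_start(st, spec, rng)
        else:
            beta0 = beta1[None, :] + rng.normal(0, 0.5 * scale, size=(G, p))
        xi0 = np.zeros(G)
        res = _em_run(st, spec, beta0, D0, s2, xi0, tol, max_iter)
        beta, D, sigma2, xi, ll, W, converged, empty, history = res
        if empty:
            continue  # degenerate start: retry with a fresh perturbation
        start += 1
        if best is None or ll > best[4]:
            best = res
    if best is None:
        raise RuntimeError("all EM starts collapsed to empty classes")
    beta, D, sigma2, xi, ll, W, converged, _, history = best
    if not converged:
        warnings.warn("LCMM EM did not converge in any start", RuntimeWarning)
    # stable labels: ascending fitted mean at t = 0
    order = np.argsort(beta[:, 0], kind="stable")
    beta, xi, W = beta[order], xi[order], W[:, order]
    xi = xi - xi[-1]
    k = spec.n_params()
    bic = -2.0 * ll + k * np.log(st.n_subjects)
    return LCMMFit(spec=spec, beta=beta, re_cov=D, sigma2=float(sigma2),
                   xi=xi, loglik=ll, n_params=k, bic=float(bic),
                   posterior=W, converged=converged,
                   n_subjects=st.n_subjects, subject_ids=st.subject_ids,
                   loglik_history=history)


# ---------------------------------------------------------------------------
# model selection, assignment, external application
# ---------------------------------------------------------------------------

def select_model(data, spec_template: LCMMSpec,
                 G_range: Sequence[int] = range(2, 11),
                 n_starts: int = 10, tol: float = 1e-8,
                 max_iter: int = 500, seed: int = 0):
    """Fit every class count in ``G_range``; return the lowest-BIC fit.

    Also returns the full (G, loglik, n_params, bic, converged) table;
    class counts that fail to fit get a missing BIC and are skipped.
    """
    G_range = list(G_range)
    if not G_range:
        raise ValueError("G_range must be non-empty")
    rows, fits = [], {}
    for G in G_range:
        spec = LCMMSpec(G=G, fixed_degree=spec_template.fixed_degree,
                        random_structure=spec_template.random_structure,
                        time_normalization=spec_template.time_normalization)
        try:
            fit = fit_lcmm(data, spec, n_starts=n_starts, tol=tol,
                           max_iter=max_iter, seed=seed + G)
        except Exception as exc:   # noqa: BLE001 - recorded, not silenced
            warnings.warn(f"G={G} failed to fit: {exc}", RuntimeWarning)
            rows.append({"G": G, "loglik": np.nan, "n_params": np.nan,
                         "bic": np.nan, "converged": False})
            continue
        fits[G] = fit
        rows.append({"G": G, "loglik": fit.loglik, "n_params": fit.n_params,
                     "bic": fit.bic, "converged": fit.converged})
    table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("no class count could be fitted")
    best_G = table.loc[table["bic"].idxmin(), "G"]
    return fits[int(best_G)], table


def assign_classes(fit: LCMMFit):
    """Modal class assignment plus per-class discrimination (MPCMP).

    Ties in the posterior argmax break to the lowest class index.  The
    mean posterior class-membership probability of class g averages
    ``max_posterior`` over the subjects assigned to g.
    """
    W = fit.posterior
    idx = W.argmax(axis=1)                 # argmax takes the first maximum
    maxp = W[np.arange(len(W)), idx]
    ids = fit.subject_ids or [str(i) for i in range(len(W))]
    assignments = [ClassAssignment(patient_id=pid, assigned_class=int(c) + 1,
                                   max_posterior=float(p))
                   for pid, c, p in zip(ids, idx, maxp)]
    G = fit.spec.G
    mpcmp = np.full(G, np.nan)
    sizes = np.zeros(G, int)
    for g in range(G):
        sel = idx == g
        sizes[g] = sel.sum()
        if sizes[g]:
            mpcmp[g] = maxp[sel].mean()
    return assignments, DiscriminationReport(mpcmp=mpcmp, class_sizes=sizes)


def apply_lcmm(fit: LCMMFit, new_data):
    """Classify an external cohort with frozen trained parameters.

    Posterior membership probabilities are evaluated under the trained
    model (no refitting); subjects with zero usable points are skipped
    with a warning.
    """
    st = stack_trajectories(new_data, fit.spec)
    logpi = fit.xi - logsumexp(fit.xi)
    ld = _component_logdens(st, fit.beta, fit.re_cov, fit.sigma2)
    joint = ld + logpi[None, :]
    W = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    applied = LCMMFit(spec=fit.spec, beta=fit.beta, re_cov=fit.re_cov,
                      sigma2=fit.sigma2, xi=fit.xi, loglik=float("nan"),
                      n_params=fit.n_params, bic=float("nan"), posterior=W,
                      converged=fit.converged, n_subjects=st.n_subjects,
                      subject_ids=st.subject_ids)
    return assign_classes(applied)


def marginal_trajectories(fit: LCMMFit, time_grid: Sequence[float]
                          ) -> np.ndarray:
    """Per-class marginal mean curves x(t)' beta_g on an hour grid.

    Random effects have mean zero, so the fixed-effect polynomial is the
    marginal projection of the class mean.  Returns (G, len(grid)).
    """
    t = np.asarray(time_grid, float)
    u = t / fit.spec.time_normalization
    X = np.vander(u, fit.spec.fixed_degree + 1, increasing=True)
    return fit.beta @ X.T
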