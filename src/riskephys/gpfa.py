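"""Gaussian-process factor analysis of simultaneously recorded populations.

Model: square-rooted spike counts ``y_t`` (q units) at bin ``t`` are a
linear-Gaussian readout of a low-dimensional latent state ``x_t`` (p dims),

    y_t | x_t ~ N(C x_t + d, R),        R diagonal,

and each latent dimension follows an independent Gaussian process over the
T bins of a trial with squared-exponential covariance

    K_i(t1, t2) = (1 - s_n) exp(-(t1 - t2)^2 / (2 tau_i^2)) + s_n delta,

with a small innovation floor ``s_n = 1e-3``.  Parameters (C, d, R, tau)
are fitted by EM: the E-step posterior over the stacked latents is jointly
Gaussian and closed-form; C, d, R have closed-form M-steps and each
timescale is optimized numerically (accepted only if it improves its
expected-likelihood term, so the marginal likelihood is non-decreasing).
The marginal log-likelihood is evaluated with the Woodbury identity from
E-step byproducts, so tracking it per iteration is essentially free.

Latent dimensionality is chosen by cross-validated likelihood with a
one-standard-error plateau rule; fitted loadings are orthonormalized
(SVD of C) for PCA-like trajectories, and single-trial trajectory
deviations from the block-1 mean trajectory are correlated with log
response time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from sklearn.decomposition import FactorAnalysis

from .core import PeriEventTensor, TrialTable

GP_NOISE_FLOOR = 1e-3
LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GPFAModel:
    C: np.ndarray                 # q x p loading map
    d: np.ndarray                 # q offsets
    R: np.ndarray                 # q diagonal observation noise variances
    taus: np.ndarray              # p GP timescales, seconds
    bin_centers: np.ndarray       # T bin centers, seconds
    loglik_history: list = field(default_factory=list)
    converged: bool = True

    @property
    def p(self) -> int:
        return self.C.shape[1]

    @property
    def q(self) -> int:
        return self.C.shape[0]

    def gp_kernel(self, i: int) -> np.ndarray:
        return _se_kernel(self.bin_centers, self.taus[i])

    def log_likelihood(self, Y: np.ndarray) -> float:
        """Total marginal log-likelihood of trials Y (n_trials, q, T)."""
        e = _estep(Y, self.C, self.d, self.R, self.taus, self.bin_centers)
        return e["loglik"]

    def trajectories(self, Y: np.ndarray) -> np.ndarray:
        """Posterior mean latents E[x|y], (n_trials, p, T)."""
        e = _estep(Y, self.C, self.d, self.R, self.taus, self.bin_centers)
        return e["mu"]


def _se_kernel(t: np.ndarray, tau: float,
               noise: float = GP_NOISE_FLOOR) -> np.ndarray:
    d2 = (t[:, None] - t[None, :]) ** 2
    return (1.0 - noise) * np.exp(-0.5 * d2 / tau ** 2) + noise * np.eye(t.size)


def tensor_to_observations(tensor: PeriEventTensor, sqrt: bool = True) -> np.ndarray:
    """(units, trials, bins) counts -> (trials, units, bins) observations,
    square-root transformed by default to stabilize Poisson variance."""
    y = np.transpose(tensor.data, (1, 0, 2)).astype(float)
    return np.sqrt(y) if sqrt else y


def _estep(Y: np.ndarray, C: np.ndarray, d: np.ndarray, R: np.ndarray,
           taus: np.ndarray, t: np.ndarray) -> dict:
    """Joint-Gaussian posterior over stacked latents, plus marginal LL.

    Time-major stacking: latent index = t*p + i.  The posterior covariance
    is shared across trials; means are computed for all trials at once.
    """
    n_trials, q, T = Y.shape
    p = C.shape[1]
    Rin = 1.0 / R
    CtRi = C.T * Rin[None, :]                       # p x q
    A_block = CtRi @ C                              # p x p

    Kinv = np.zeros((p * T, p * T))
    logdet_K = 0.0
    for i in range(p):
        K = _se_kernel(t, taus[i])
        cf = cho_factor(K)
        logdet_K += 2.0 * np.sum(np.log(np.diag(cf[0])))
        idx = i + p * np.arange(T)
        Kinv[np.ix_(idx, idx)] = cho_solve(cf, np.eye(T))

    M = Kinv + np.kron(np.eye(T), A_block)
    cf_m = cho_factor(M)
    logdet_M = 2.0 * np.sum(np.log(np.diag(cf_m[0])))
    Sigma = cho_solve(cf_m, np.eye(p * T))

    resid = Y - d[None, :, None]                    # trials x q x T
    Z = np.einsum("pq,nqt->ntp", CtRi, resid)       # trials x T x p
    z_vec = Z.reshape(n_trials, p * T)
    mu_vec = z_vec @ Sigma.T                        # Sigma symmetric
    mu = mu_vec.reshape(n_trials, T, p).transpose(0, 2, 1)  # trials x p x T

    logdet_V = T * np.sum(np.log(R)) + logdet_K + logdet_M
    quad = np.einsum("nqt,q->n", resid ** 2, Rin) - np.einsum(
        "nk,nk->n", z_vec, mu_vec)
    loglik = float(-0.5 * np.sum(q * T * LOG2PI + logdet_V + quad))
    return {"mu": mu, "Sigma": Sigma, "loglik": loglik, "resid": resid}


def _tau_objective(log_tau: float, t: np.ndarray, S: np.ndarray,
                   n_trials: int) -> float:
    K = _se_kernel(t, np.exp(log_tau))
    try:
        cf = cho_factor(K)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return n_trials * logdet + np.trace(cho_solve(cf, S))


def gpfa_fit(Y: np.ndarray | PeriEventTensor, p: int, *, max_iter: int = 500,
             tol: float = 1e-8, tau_init: float = 0.1, seed: int = 0,
             fit_taus: bool = True, verbose: bool = False) -> GPFAModel:
    """Fit the GPFA model by EM on square-rooted spike counts.

    ``Y`` is (n_trials, q, T) observations or a population PeriEventTensor
    (square-rooted internally).  Requires at least 10 units and p < q.
    Emits a warning (model flagged non-converged) if the likelihood is
    still improving at ``max_iter``.
    """
    if isinstance(Y, PeriEventTensor):
        t = Y.bin_centers
        Y = tensor_to_observations(Y)
    else:
        Y = np.asarray(Y, float)
        t = None
    n_trials, q, T = Y.shape
    if t is None:
        t = 0.02 * np.arange(T)
    if p >= q:
        raise ValueError(f"latent dimensionality p={p} must be < q={q}")
    if q < 10:
        raise ValueError("need at least 10 simultaneously recorded units")

    flat = Y.transpose(0, 2, 1).reshape(-1, q)
    d = flat.mean(0)
    fa = FactorAnalysis(n_components=p, random_state=seed, max_iter=200)
    fa.fit(flat)
    C = fa.components_.T.copy()
    if np.allclose(C, 0):
        C = np.random.default_rng(seed).standard_normal((q, p)) * 0.1
    R = np.maximum(fa.noise_variance_.copy(), 1e-6)
    taus = np.full(p, float(tau_init))

    logliks: list[float] = []
    converged = False
    for it in range(max_iter):
        e = _estep(Y, C, d, R, taus, t)
        logliks.append(e["loglik"])
        if verbose:
            print(f"iter {it}: loglik {e['loglik']:.6f}")
        if it >= 1 and abs(logliks[-1] - logliks[-2]) < tol * (
                1.0 + abs(logliks[-2])):
            converged = True
            break

        mu, Sigma = e["mu"], e["Sigma"]
        N = n_trials * T
        blocks = Sigma.reshape(T, p, T, p)
        Sigma_tt = np.array([blocks[ti, :, ti, :] for ti in range(T)])
        Sxx = n_trials * Sigma_tt.sum(0) + np.einsum("npt,nmt->pm", mu, mu)
        Sx = mu.sum(axis=(0, 2))
        Sxy = np.einsum("nqt,npt->qp", Y, mu)
        Sy = Y.sum(axis=(0, 2))
        G = np.zeros((p + 1, p + 1))
        G[:p, :p] = Sxx
        G[:p, p] = Sx
        G[p, :p] = Sx
        G[p, p] = N
        B = np.column_stack([Sxy, Sy])
        Cd = np.linalg.solve(G, B.T).T
        C, d = Cd[:, :p], Cd[:, p]
        sum_yy = np.einsum("nqt,nqt->q", Y, Y)
        R = np.maximum((sum_yy - np.einsum("qk,qk->q", Cd, B)) / N, 1e-8)

        if fit_taus:
            for i in range(p):
                idx = i + p * np.arange(T)
                S_i = (n_trials * Sigma[np.ix_(idx, idx)]
                       + np.einsum("nt,ns->ts", mu[:, i, :], mu[:, i, :]))
                cur = _tau_objective(np.log(taus[i]), t, S_i, n_trials)
                res = minimize_scalar(_tau_objective,
                                      bounds=(np.log(5e-3), np.log(2.0)),
                                      args=(t, S_i, n_trials),
                                      method="bounded",
                                      options={"maxiter": 25})
                if res.fun < cur:  # generalized EM: accept only improvements
                    taus[i] = float(np.exp(res.x))
    if not converged:
        import warnings
        warnings.warn(f"GPFA EM did not converge in {max_iter} iterations")
    return GPFAModel(C=C, d=d, R=R, taus=taus, bin_centers=t,
                     loglik_history=logliks, converged=converged)


def sample_from_model(model: GPFAModel, n_trials: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (Y, X) from a GPFA model; used as simulation ground truth."""
    T, p, q = model.bin_centers.size, model.p, model.q
    X = np.empty((n_trials, p, T))
    for i in range(p):
        K = model.gp_kernel(i)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(T))
        X[:, i, :] = rng.standard_normal((n_trials, T)) @ L.T
    noise = rng.standard_normal((n_trials, q, T)) * np.sqrt(model.R)[None, :, None]
    Y = np.einsum("qp,npt->nqt", model.C, X) + model.d[None, :, None] + noise
    return Y, X


def select_dimensionality(Y: np.ndarray, candidates: list[int],
                          n_folds: int = 4, seed: int = 0,
                          max_iter: int = 200, tol: float = 1e-6) -> dict:
    """Cross-validated latent dimensionality with the 1-SE plateau rule.

    Trials are shuffled into folds by seed; for each candidate p the model
    is fitted on the training folds and scored by held-out marginal
    log-likelihood.  Returns the smallest p whose mean per-trial held-out
    likelihood lies within one standard error of the best candidate's.
    """
    Y = np.asarray(Y, float)
    n_trials = Y.shape[0]
    candidates = sorted(candidates)
    if len(candidates) == 1:
        return {"p_star": candidates[0], "cv_loglik": {}, "se": 0.0}
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    folds = np.array_split(order, n_folds)
    if min(len(f) for f in folds) < max(candidates):
        raise ValueError("a fold has fewer trials than the largest candidate p")

    fold_means = {p: [] for p in candidates}
    for p in candidates:
        for k in range(n_folds):
            test_idx = folds[k]
            train_idx = np.concatenate([folds[j] for j in range(n_folds)
                                        if j != k])
            model = gpfa_fit(Y[train_idx], p, max_iter=max_iter, tol=tol,
                             seed=seed)
            fold_means[p].append(model.log_likelihood(Y[test_idx])
                                 / len(test_idx))
    means = {p: float(np.mean(v)) for p, v in fold_means.items()}
    best = max(means, key=means.get)
    se = float(np.std(fold_means[best], ddof=1) / np.sqrt(n_folds))
    p_star = min(p for p in candidates if means[p] >= means[best] - se)
    return {"p_star": p_star, "cv_loglik": means, "fold_loglik": fold_means,
            "se": se, "best": best}


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectorySet:
    """Per-trial latent trajectories in the orthonormalized readout space."""

    ortho: np.ndarray            # n_trials x p x T, orthonormalized latents
    raw: np.ndarray              # n_trials x p x T, E[x|y]
    basis: np.ndarray            # q x p orthonormal columns
    bin_centers: np.ndarray
    blocks: np.ndarray | None = None
    deviations: np.ndarray | None = None


def orthonormalize(model: GPFAModel, trajectories: np.ndarray,
                   blocks: np.ndarray | None = None) -> TrajectorySet:
    """Re-express latents in the orthonormalized column space of C.

    With C = U S V', the basis is U and the latents become S V' x, so the
    readout C x = U (S V' x) is preserved exactly.  Rank-deficient C yields
    a reduced basis with a warning.
    """
    u, s, vt = np.linalg.svd(model.C, full_matrices=False)
    rank = int(np.sum(s > 1e-12 * s[0])) if s.size else 0
    if rank < model.p:
        import warnings
        warnings.warn(f"C is rank deficient ({rank} < {model.p}); "
                      "using reduced basis")
        u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    transform = s[:, None] * vt                      # p' x p
    ortho = np.einsum("ij,njt->nit", transform, trajectories)
    return TrajectorySet(ortho=ortho, raw=trajectories, basis=u,
                         bin_centers=model.bin_centers, blocks=blocks)


def trajectory_deviation(trajset: TrajectorySet,
                         reference_block: int = 1) -> np.ndarray:
    """Per-trial mean-over-bins Euclidean distance to the reference-block
    mean trajectory, in the full orthonormalized space."""
    if trajset.blocks is None:
        raise ValueError("trajectory set carries no block labels")
    ref = trajset.ortho[trajset.blocks == reference_block].mean(0)  # p x T
    diff = trajset.ortho - ref[None]
    dev = np.sqrt((diff ** 2).sum(1)).mean(1)
    trajset.deviations = dev
    return dev


def trajectory_rt_correlation(trajset: TrajectorySet, trials: TrialTable,
                              reference_block: int = 1) -> dict:
    """Correlate single-trial trajectory deviation with RT deviation.

    Neural deviation: distance of each trial's trajectory from the block-1
    mean trajectory; behavioral deviation: log RT minus the block-1 mean
    log RT (RT is log transformed for proper scaling).  Pearson r and
    two-sided p are returned pooled over trials and per block.
    """
    if len(trials) != trajset.ortho.shape[0]:
        raise ValueError("trials and trajectories are misaligned")
    trajset.blocks = trials.blocks
    dev = trajectory_deviation(trajset, reference_block)
    log_rt = np.log(trials.df["rt"].to_numpy(float))
    rt_dev = log_rt - log_rt[trials.blocks == reference_block].mean()
    r_tot, p_tot = stats.pearsonr(dev, rt_dev)
    per_block = {}
    for b in np.unique(trials.blocks):
        m = trials.blocks == b
        if m.sum() < 3 or dev[m].std() == 0:
            per_block[int(b)] = {"r": np.nan, "p": np.nan, "flagged": True}
        else:
            r, pv = stats.pearsonr(dev[m], rt_dev[m])
            per_block[int(b)] = {"r": float(r), "p": float(pv), "flagged": False}
    return {"r_total": float(r_tot), "p_total": float(p_tot),
            "per_block": per_block, "deviation": dev, "rt_deviation": rt_dev}
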