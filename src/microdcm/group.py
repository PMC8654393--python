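"""Hierarchical group inference.

Bayesian model reduction (BMR) re-derives the evidence and posterior a fit
would have had under different priors, without refitting.  Parametric
empirical Bayes (PEB) places a between-subject linear model on first-level
posteriors, with a between-subject precision hyperparameter estimated by
empirical Bayes; per-effect posterior probabilities come from BMR switch-off
of each second-level effect.  Random-effects Bayesian model selection (BMS)
estimates population model frequencies with a Dirichlet-multinomial scheme
and reports protected exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln

from .cmc import ModelError, PriorSpec
from .inversion import Posterior

# -- Bayesian model reduction ------------------------------------------------


class ReductionError(RuntimeError):
    pass


def _as_cov(v, p):
    v = np.asarray(v, float)
    return np.diag(v) if v.ndim == 1 else v.reshape(p, p)


def bayesian_model_reduction(post_mean, post_cov, prior_mean, prior_cov,
                             reduced_mean, reduced_cov):
    """Posterior and evidence change under reduced priors, in closed form.

    Given a Gaussian posterior obtained under ``prior``, returns
    ``(reduced_post_mean, reduced_post_cov, dF)`` where ``dF`` is the log
    evidence of the reduced model minus that of the full model.  Pinning a
    parameter is expressed as a reduced prior variance near zero.
    """
    mu = np.asarray(post_mean, float)
    p = mu.size
    S = _as_cov(post_cov, p)
    m0 = np.asarray(prior_mean, float)
    S0 = _as_cov(prior_cov, p)
    mr = np.asarray(reduced_mean, float)
    Sr = _as_cov(reduced_cov, p)
    try:
        P = np.linalg.inv(S)
        P0 = np.linalg.inv(S0)
        Pr = np.linalg.inv(Sr)
    except np.linalg.LinAlgError as exc:
        raise ReductionError(
            "singular covariance; apply a prior-variance floor") from exc
    A = P + Pr - P0
    b = P @ mu + Pr @ mr - P0 @ m0
    sign, ldA = np.linalg.slogdet(A)
    if sign <= 0:
        raise ReductionError(
            "reduced precision not positive definite; "
            "apply a prior-variance floor")
    Sa = np.linalg.inv(A)
    mu_r = Sa @ b
    c = float(mu @ P @ mu + mr @ Pr @ mr - m0 @ P0 @ m0)
    ld = (np.linalg.slogdet(P)[1] + np.linalg.slogdet(Pr)[1]
          - np.linalg.slogdet(P0)[1] - ldA)
    dF = 0.5 * (ld + float(b @ Sa @ b) - c)
    return mu_r, 0.5 * (Sa + Sa.T), float(dF)


def reduce_posterior(post: Posterior, reduced: PriorSpec):
    """Apply BMR to a fit's posterior under a reduced PriorSpec."""
    names = post.names
    mr = np.array([reduced[n].mean for n in names])
    vr = np.array([max(reduced[n].var, 1e-8) for n in names])
    mu_r, S_r, dF = bayesian_model_reduction(
        post.mean, post.cov, post.prior_mean, post.prior_cov, mr, vr)
    return Posterior(names=names, mean=mu_r, cov=S_r, prior_mean=mr,
                     prior_cov=np.diag(vr), hyper_mean=post.hyper_mean,
                     hyper_cov=post.hyper_cov,
                     free_energy=post.free_energy + dF), dF


# -- design matrices ---------------------------------------------------------


@dataclass
class DesignMatrix:
    """Subjects-by-regressors design; first regressor is the constant."""

    X: np.ndarray
    names: list

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, float))
        if len(self.names) != self.X.shape[1]:
            raise ModelError("regressor names do not match design columns")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ModelError("first regressor must be the constant (all 1)")
        r = np.linalg.matrix_rank(self.X)
        if r < self.X.shape[1]:
            # name the offending columns for the error message
            bad = []
            for j in range(1, self.X.shape[1]):
                keep = [c for c in range(self.X.shape[1]) if c != j]
                if np.linalg.matrix_rank(self.X[:, keep]) == r:
                    bad.append(self.names[j])
            raise ModelError(f"design matrix rank deficient; "
                             f"collinear columns: {bad or self.names}")


def build_design(groups, scheme="case-control", covariates=None,
                 covariate_names=None, symptom=None):
    """Design matrix from group labels (Con/PScz/Rel) and covariates.

    ``scheme``: 'case-control' codes PScz>Con and Rel>Con contrasts;
    'risk-diagnosis' codes genetic risk (PScz+Rel>Con) and diagnosis
    (PScz>Rel).  Covariate columns are mean-centered.
    """
    groups = list(groups)
    n = len(groups)
    cols = [np.ones(n)]
    names = ["mean"]
    g = np.array(groups)
    if scheme == "case-control":
        if "PScz" in g:
            cols.append((g == "PScz").astype(float))
            names.append("PScz>Con")
        if "Rel" in g:
            cols.append((g == "Rel").astype(float))
            names.append("Rel>Con")
    elif scheme == "risk-diagnosis":
        cols += [np.isin(g, ("PScz", "Rel")).astype(float)]
        names += ["risk:PScz+Rel>Con"]
        if "PScz" in g and "Rel" in g:
            cols.append((g == "PScz").astype(float))
            names.append("diagnosis:PScz>Rel")
    else:
        raise ModelError(f"unknown contrast scheme {scheme!r}")
    if symptom is not None:
        sc = np.asarray(symptom, float)
        cols.append(sc - sc.mean())
        names.append("symptom")
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        for j in range(cov.shape[1]):
            c = cov[:, j]
            cols.append(c - c.mean())
            names.append(covariate_names[j] if covariate_names
                         else f"cov{j + 1}")
    return DesignMatrix(np.column_stack(cols), names)


# -- parametric empirical Bayes ----------------------------------------------


@dataclass
class PebResult:
    """Second-level effects: (regressor x parameter) estimates and
    posterior probabilities that each effect is nonzero (via BMR)."""

    parameters: list
    regressors: list
    beta_mean: np.ndarray        # (k, p)
    beta_var: np.ndarray         # (k, p) marginal posterior variances
    probability: np.ndarray      # (k, p)
    free_energy: float
    gamma: float                 # log between-subject precision scaling
    bma_mean: np.ndarray = None  # (k, p) after pruning/averaging


def peb_fit(subject_posteriors, design: DesignMatrix,
            parameter_selection=None, between_var_scale=1.0 / 16.0,
            gamma_prior_var=1.0, prune=True):
    """Hierarchical (random-effects) linear model on first-level posteriors.

    Each subject contributes its posterior mean and covariance over the
    selected parameters; the between-subject covariance is diagonal --
    the first-level prior variances scaled by ``between_var_scale`` and a
    shared precision factor exp(gamma) estimated by empirical Bayes.
    Deterministic.
    """
    posts = list(subject_posteriors)
    if len(posts) != design.X.shape[0]:
        raise ModelError("design rows do not match number of subjects")
    names = list(posts[0].names)
    sel = list(parameter_selection) if parameter_selection else names
    idx = [names.index(s) for s in sel]
    p = len(sel)
    n = len(posts)
    k = design.X.shape[1]
    X = design.X
    v0 = posts[0].prior_cov.diagonal()[idx]

    # recover each subject's likelihood in natural (precision) form by
    # removing the first-level prior from its posterior: this undoes the
    # shrinkage of the posterior means before pooling across subjects
    Lam = []                      # (p, p) likelihood precisions, PSD
    eta = []                      # (p,) likelihood precision-means
    for po in posts:
        Sp = po.cov[np.ix_(idx, idx)]
        Pp = np.linalg.inv(Sp)
        P0 = np.diag(1.0 / po.prior_cov.diagonal()[idx])
        m0 = po.prior_mean[idx]
        L_i = Pp - P0
        # project to PSD against numerical noise
        w, V = np.linalg.eigh(0.5 * (L_i + L_i.T))
        L_i = (V * np.clip(w, 0.0, None)) @ V.T
        Lam.append(L_i)
        eta.append(Pp @ po.mean[idx] - P0 @ m0)
    Vb = v0 * between_var_scale

    # prior over effects: every regressor's effect gets the first-level
    # prior variance (log-scale deltas)
    beta_var0 = np.concatenate([v0 for _ in range(k)])        # (k*p,)

    def evidence(gamma, want_post=False):
        Q = np.diag(np.exp(gamma) / Vb)    # between-subject precision
        ld_Q = float(np.sum(np.log(np.exp(gamma) / Vb)))
        const = 0.0
        H = np.zeros((k * p, k * p))
        g = np.zeros(k * p)
        for i in range(n):
            P_i = Lam[i] + Q
            sign, ld_Pi = np.linalg.slogdet(P_i)
            if sign <= 0:
                return -np.inf if not want_post else (None, None, -np.inf)
            PiInv = np.linalg.inv(P_i)
            const += 0.5 * (ld_Q - ld_Pi + float(eta[i] @ PiInv @ eta[i]))
            A_i = Q - Q @ PiInv @ Q
            g_i = Q @ PiInv @ eta[i]
            Xi = np.kron(X[i], np.eye(p))                     # (p, k*p)
            H += Xi.T @ A_i @ Xi
            g += Xi.T @ g_i
        Pb = H + np.diag(1.0 / beta_var0)
        sign, ld_Pb = np.linalg.slogdet(Pb)
        if sign <= 0:
            return -np.inf if not want_post else (None, None, -np.inf)
        mu = np.linalg.solve(Pb, g)
        F = (const + 0.5 * float(g @ mu) - 0.5 * ld_Pb
             - 0.5 * float(np.sum(np.log(beta_var0)))
             - 0.5 * gamma ** 2 / gamma_prior_var)
        if want_post:
            return mu, np.linalg.inv(Pb), F
        return F

    opt = minimize_scalar(lambda gmm: -evidence(gmm), bounds=(-6.0, 6.0),
                          method="bounded",
                          options=dict(xatol=1e-4))
    gamma = float(opt.x)
    mu, Sb, F = evidence(gamma, want_post=True)
    if mu is None:
        raise ModelError("PEB evidence not defined at optimal gamma")

    # per-effect posterior probabilities by BMR switch-off
    prob = np.empty(k * p)
    for j in range(k * p):
        vr = beta_var0.copy()
        vr[j] = 1e-8
        _, _, dF = bayesian_model_reduction(
            mu, Sb, np.zeros(k * p), beta_var0, np.zeros(k * p), vr)
        prob[j] = 1.0 / (1.0 + np.exp(dF))

    bma = None
    if prune:
        bma = _prune_and_average(mu, Sb, beta_var0)
    order = "kp"  # mu is ordered regressor-major: [k0 params..., k1 params...]
    beta_mean = mu.reshape(k, p)
    beta_var = Sb.diagonal().reshape(k, p)
    return PebResult(parameters=sel, regressors=list(design.names),
                     beta_mean=beta_mean, beta_var=beta_var,
                     probability=prob.reshape(k, p), free_energy=float(F),
                     gamma=gamma,
                     bma_mean=None if bma is None else bma.reshape(k, p))


def _prune_and_average(mu, Sb, var0):
    """Greedy BMR pruning with Bayesian model averaging over visited models."""
    m = mu.size
    pinned = np.zeros(m, bool)
    models = []                   # (dF, posterior mean)

    def reduced(pin):
        vr = np.where(pin, 1e-8, var0)
        return bayesian_model_reduction(mu, Sb, np.zeros(m), var0,
                                        np.zeros(m), vr)

    mu_c, _, dF_c = reduced(pinned)
    models.append((dF_c, mu_c))
    improved = True
    while improved:
        improved = False
        best = None
        for j in range(m):
            if pinned[j]:
                continue
            trial = pinned.copy()
            trial[j] = True
            mu_t, _, dF_t = reduced(trial)
            if dF_t > dF_c and (best is None or dF_t > best[0]):
                best = (dF_t, mu_t, trial)
        if best is not None:
            dF_c, mu_c, pinned = best
            models.append((dF_c, mu_c))
            improved = True
    ws = np.exp([d - max(d for d, _ in models) for d, _ in models])
    ws /= ws.sum()
    return np.sum([w * mm for w, (_, mm) in zip(ws, models)], axis=0)


# -- random-effects model selection -------------------------------------------


@dataclass
class BmsResult:
    expected_p: np.ndarray       # expected model frequencies
    exceedance_p: np.ndarray
    protected_xp: np.ndarray
    bor: float                   # Bayesian omnibus risk
    alpha: np.ndarray            # Dirichlet posterior counts


def bms_random_effects(log_evidence, n_samples=100_000, seed=0, alpha0=1.0):
    """Random-effects Bayesian model selection over subjects x models.

    Variational Dirichlet-multinomial estimation of population model
    frequencies; exceedance probabilities by seeded Monte Carlo over the
    Dirichlet posterior; protected version blends with chance using the
    Bayesian omnibus risk (the posterior probability that model frequencies
    are all equal).
    """
    L = np.atleast_2d(np.asarray(log_evidence, float))
    n, K = L.shape
    if K < 2:
        raise ModelError("model selection requires at least two models")
    if not np.all(np.isfinite(L)):
        raise ModelError("log evidences must be finite")
    alpha = np.full(K, alpha0)
    for _ in range(200):
        w = L + digamma(alpha) - digamma(alpha.sum())
        w = np.exp(w - w.max(axis=1, keepdims=True))
        u = w / w.sum(axis=1, keepdims=True)
        new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new - alpha)) < 1e-8:
            alpha = new
            break
        alpha = new

    # free energy of H1 (frequencies vary) vs H0 (all equal)
    E_ln_r = digamma(alpha) - digamma(alpha.sum())
    F1 = float(np.sum(u * (L + E_ln_r)) - np.sum(u * np.log(u + 1e-300))
               + gammaln(K * alpha0) - K * gammaln(alpha0)
               - gammaln(alpha.sum()) + np.sum(gammaln(alpha))
               - np.sum((alpha - alpha0) * E_ln_r))
    F0 = float(np.sum(np.log(np.mean(np.exp(L - L.max(axis=1, keepdims=True)),
                                     axis=1)) + L.max(axis=1)))
    bor = 1.0 / (1.0 + np.exp(F1 - F0))

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    xp = np.bincount(np.argmax(draws, axis=1), minlength=K) / draws.shape[0]
    pxp = (1.0 - bor) * xp + bor / K
    return BmsResult(expected_p=alpha / alpha.sum(), exceedance_p=xp,
                     protected_xp=pxp, bor=float(bor), alpha=alpha)
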