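"""Variational Laplace model inversion.

Fits a (generally nonlinear) generative model ``g(theta)`` to a data vector
under Gaussian priors on the log-scaling parameters and Gaussian observation
noise with unknown precision, by Gauss-Newton ascent on the Laplace free
energy

    F = -1/2 e' Pi e + 1/2 ln|Pi| - n/2 ln 2pi
        - 1/2 (theta-mu0)' Pi0 (theta-mu0) + 1/2 ln|Sigma Pi0|
        - 1/2 (lam-m)' Pl (lam-m) + 1/2 ln|Sigma_lam Pl|

where ``Pi = sum_b exp(lam_b) I_b`` has one log-precision hyperparameter per
data block.  Accepted steps never decrease F (trust-region damping rejects
and re-damps otherwise); hyperparameters are updated in alternation with the
parameters.  For models linear in theta and fixed hyperparameters the scheme
is exact: the posterior equals the conjugate closed form and F equals the
log evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cmc import ModelError, PriorSpec


@dataclass
class Observation:
    """Real-valued data vector with noise-precision block structure."""

    y: np.ndarray
    blocks: list = None          # list of index arrays, partitioning y
    paradigm: str = ""
    mask: np.ndarray = None      # boolean, same length as y

    def __post_init__(self):
        self.y = np.asarray(self.y, float).ravel()
        if not np.all(np.isfinite(self.y)):
            raise ModelError("observation contains non-finite values")
        if self.blocks is None:
            self.blocks = [np.arange(self.y.size)]
        if self.mask is None:
            self.mask = np.ones(self.y.size, bool)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.size != self.y.size:
            raise ModelError("mask length must equal data length")


def csd_observation(csd, log_diag=False):
    """Vectorize a CrossSpectrum: real diagonal, then re/im upper triangle.

    One noise block per channel-pair component.  ``log_diag`` fits the
    diagonal on a log-amplitude scale (off by default).
    """
    v = csd.values
    n = v.shape[1]
    parts, blocks, k = [], [], 0
    for i in range(n):
        d = np.real(v[:, i, i])
        parts.append(np.log(d) if log_diag else d)
        blocks.append(np.arange(k, k + d.size))
        k += d.size
    for i in range(n):
        for j in range(i + 1, n):
            re, im = np.real(v[:, i, j]), np.imag(v[:, i, j])
            parts.append(re)
            parts.append(im)
            blocks.append(np.arange(k, k + re.size + im.size))
            k += re.size + im.size
    return Observation(np.concatenate(parts), blocks, paradigm="csd")


def erp_observation(erp, channels=None, decimate=1):
    """Vectorize an ErpTimeSeries: conditions concatenated, one block each."""
    parts, blocks, k = [], [], 0
    for cond in sorted(erp.traces):
        tr = np.asarray(erp.traces[cond])
        if channels is not None:
            tr = tr[channels]
        x = tr[:, ::decimate].ravel()
        parts.append(x)
        blocks.append(np.arange(k, k + x.size))
        k += x.size
    return Observation(np.concatenate(parts), blocks, paradigm="erp")


@dataclass
class Posterior:
    """Gaussian posterior over free parameters plus noise hyperposterior."""

    names: list
    mean: np.ndarray
    cov: np.ndarray
    prior_mean: np.ndarray
    prior_cov: np.ndarray
    hyper_mean: np.ndarray
    hyper_cov: np.ndarray
    free_energy: float
    trace: list = field(default_factory=list)
    converged: bool = True


@dataclass
class FitResult:
    posterior: Posterior
    prediction: np.ndarray
    r2: float

    @property
    def free_energy(self):
        return self.posterior.free_energy


@dataclass
class FitSettings:
    max_iter: int = 128
    tol_nats: float = 0.01
    converge_runs: int = 3
    fd_step: float = 1e-3
    init_damping: float = 1.0
    hyper_prior_var: float = 16.0
    hyper_prior_mean: np.ndarray = None    # default: matched to data variance
    fix_hyper: bool = False


def fit_quality(prediction, y):
    """R-squared: 1 - RSS/TSS about the data mean."""
    y = np.asarray(y, float).ravel()
    prediction = np.asarray(prediction, float).ravel()
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ModelError("zero data variance; R-squared undefined")
    return float(1.0 - np.sum((y - prediction) ** 2) / tss)


def _jacobian(predict, theta, g0, step):
    J = np.empty((g0.size, theta.size))
    for i in range(theta.size):
        tp = theta.copy()
        tp[i] += step
        tm = theta.copy()
        tm[i] -= step
        J[:, i] = (predict(tp) - predict(tm)) / (2 * step)
    return J


def _logdet(A):
    sign, ld = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD matrix in log-determinant")
    return ld


def fit_variational_laplace(predict, data: Observation, priors,
                            settings: FitSettings = None):
    """Invert a generative model by variational Laplace.

    ``predict`` maps a vector of free-parameter values (log-scalings, in the
    order of the priors' free names) to a prediction of ``data.y``; it may
    raise to signal an unusable (e.g. unstable) parameter set, in which case
    the step is rejected and damping increased.  Deterministic.
    """
    s = settings or FitSettings()
    if isinstance(priors, PriorSpec):
        names = priors.free_names()
        mu0 = priors.means(names)
        v0 = priors.variances(names)
    else:
        names, mu0, v0 = priors
        mu0 = np.asarray(mu0, float)
        v0 = np.asarray(v0, float)
    if len(names) == 0:
        raise ModelError("at least one free parameter is required")
    if np.any(v0 <= 0):
        raise ModelError("free parameters need positive prior variance")
    mask = data.mask
    y = data.y[mask]
    blocks = []
    pos = np.cumsum(mask) - 1
    for b in data.blocks:
        bb = pos[np.asarray(b)[mask[np.asarray(b)]]]
        if bb.size:
            blocks.append(bb)
    nb = len(blocks)
    n = y.size
    Pi0 = np.diag(1.0 / v0)
    ld_Pi0 = float(np.sum(-np.log(v0)))

    g_full = predict(mu0)
    g = np.asarray(g_full, float).ravel()[mask]
    if g.size != n:
        raise ModelError(f"prediction length {g.size} != data length {n}")

    if s.hyper_prior_mean is not None:
        m_l = np.broadcast_to(np.asarray(s.hyper_prior_mean, float), (nb,)).copy()
    else:
        m_l = np.array([-np.log(max(np.var(y[b]), 1e-12)) for b in blocks])
    v_l = s.hyper_prior_var
    lam = m_l.copy()

    theta = mu0.copy()
    damping = s.init_damping

    def hyper_terms(e, J, Sig, lam):
        """Gradient/curvature pieces and F-contributions of the blocks."""
        tr_bits = np.empty(nb)
        ess = np.empty(nb)
        for bi, b in enumerate(blocks):
            Jb = J[b]
            ess[bi] = float(e[b] @ e[b])
            tr_bits[bi] = float(np.sum((Jb @ Sig) * Jb))
        return ess, tr_bits

    def free_energy(e, J, Sig, lam, th):
        pi_vec = np.empty(n)
        for bi, b in enumerate(blocks):
            pi_vec[b] = np.exp(lam[bi])
        acc = -0.5 * float(e @ (pi_vec * e)) + 0.5 * float(
            np.sum([b.size * lam[bi] for bi, b in enumerate(blocks)])) \
            - 0.5 * n * np.log(2 * np.pi)
        dth = th - mu0
        comp = -0.5 * float(dth @ Pi0 @ dth) + 0.5 * (_logdet(Sig) + ld_Pi0)
        dl = lam - m_l
        ess, tr_bits = hyper_terms(e, J, Sig, lam)
        h_curv = 0.5 * np.exp(lam) * (ess + tr_bits) + 1.0 / v_l
        hyp = -0.5 * float(dl @ dl) / v_l \
            + 0.5 * float(np.sum(-np.log(h_curv) - np.log(v_l)))
        return acc + comp + hyp

    def posterior_cov(J, lam):
        JPJ = np.zeros((theta.size, theta.size))
        for bi, b in enumerate(blocks):
            Jb = J[b]
            JPJ += np.exp(lam[bi]) * (Jb.T @ Jb)
        P = JPJ + Pi0
        return np.linalg.inv(P), JPJ

    def update_hyper(e, J, Sig, lam):
        lam = lam.copy()
        for _ in range(8 if not s.fix_hyper else 0):
            ess, tr_bits = hyper_terms(e, J, Sig, lam)
            grad = np.array([0.5 * (blocks[bi].size
                                    - np.exp(lam[bi]) * (ess[bi] + tr_bits[bi]))
                             for bi in range(nb)]) - (lam - m_l) / v_l
            curv = -0.5 * np.exp(lam) * (ess + tr_bits) - 1.0 / v_l
            step = -grad / curv
            step = np.clip(step, -4.0, 4.0)
            lam = lam + step
            if np.max(np.abs(step)) < 1e-6:
                break
        return lam

    e = y - g
    J = _jacobian(lambda t: np.asarray(predict(t), float).ravel()[mask],
                  theta, g, s.fd_step)
    Sig, _ = posterior_cov(J, lam)
    lam = update_hyper(e, J, Sig, lam)
    Sig, _ = posterior_cov(J, lam)
    F = free_energy(e, J, Sig, lam, theta)
    trace = [F]
    best = dict(theta=theta.copy(), lam=lam.copy(), F=F, g=g.copy(),
                J=J.copy(), Sig=Sig.copy())
    run = 0
    converged = False

    for _ in range(s.max_iter):
        # Gauss-Newton step with Levenberg damping
        pi_grad = np.zeros(theta.size)
        JPJ = np.zeros((theta.size, theta.size))
        for bi, b in enumerate(blocks):
            Jb = J[b]
            pi_grad += np.exp(lam[bi]) * (Jb.T @ e[b])
            JPJ += np.exp(lam[bi]) * (Jb.T @ Jb)
        grad = pi_grad - Pi0 @ (theta - mu0)
        H = JPJ + Pi0
        accepted = False
        for _try in range(12):
            try:
                dtheta = np.linalg.solve(H + damping * np.diag(np.diag(H)),
                                         grad)
            except np.linalg.LinAlgError:
                damping *= 8
                continue
            cand = theta + dtheta
            try:
                g_c = np.asarray(predict(cand), float).ravel()[mask]
                if not np.all(np.isfinite(g_c)):
                    raise FloatingPointError
                e_c = y - g_c
                J_c = _jacobian(lambda t: np.asarray(predict(t), float)
                                .ravel()[mask], cand, g_c, s.fd_step)
                Sig_c, _ = posterior_cov(J_c, lam)
                lam_c = update_hyper(e_c, J_c, Sig_c, lam)
                Sig_c, _ = posterior_cov(J_c, lam_c)
                F_c = free_energy(e_c, J_c, Sig_c, lam_c, cand)
            except (FloatingPointError, OverflowError, ValueError,
                    np.linalg.LinAlgError, RuntimeError):
                damping *= 8
                continue
            if F_c >= F - 1e-9:
                accepted = True
                dF = F_c - F
                theta, lam, e, g, J, Sig, F = (cand, lam_c, e_c, g_c, J_c,
                                               Sig_c, F_c)
                damping = max(damping / 2, 1e-8)
                break
            damping *= 8
        trace.append(F)
        if F >= best["F"]:
            best = dict(theta=theta.copy(), lam=lam.copy(), F=F, g=g.copy(),
                        J=J.copy(), Sig=Sig.copy())
        if accepted and abs(dF) < s.tol_nats:
            run += 1
            if run >= s.converge_runs:
                converged = True
                break
        elif accepted:
            run = 0
        else:
            converged = True  # no improving step found: local optimum
            break

    theta, lam, F = best["theta"], best["lam"], best["F"]
    g, J, Sig = best["g"], best["J"], best["Sig"]
    e = y - g
    ess, tr_bits = hyper_terms(e, J, Sig, lam)
    h_curv = 0.5 * np.exp(lam) * (ess + tr_bits) + 1.0 / v_l
    hyper_cov = np.diag(1.0 / h_curv)
    post = Posterior(names=list(names), mean=theta, cov=Sig,
                     prior_mean=mu0, prior_cov=np.diag(v0),
                     hyper_mean=lam, hyper_cov=hyper_cov,
                     free_energy=float(F), trace=trace, converged=converged)
    pred_full = np.asarray(predict(theta), float).ravel()
    return FitResult(post, pred_full, fit_quality(g, y))
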