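"""Canonical microcircuit neural mass model.

A cortical column contains four populations -- spiny stellate (ss),
superficial pyramidal (sp), inhibitory interneuron (ii) and deep pyramidal
(dp) cells -- coupled by ten intrinsic connections: an inhibitory self-loop
per population (its synaptic gain: stronger self-inhibition means lower
responsiveness to input) and six between-population connections
(ss->sp, ss->ii, sp->ii, ii->sp, dp->ii, ii->dp).  Each population has
second-order synaptic dynamics

    dv/dt = u
    du/dt = kappa^2 (I - v) - 2 kappa u,      kappa = 1/T

where ``I`` is the summed presynaptic drive: connection gains times the
sigmoid-transformed (rate) deviation of the source populations, plus any
exogenous input (which enters spiny stellate cells).  With the centred
sigmoid the zero state is the exact fixed point of an undriven column.

Multi-area networks add extrinsic forward connections (sp origin; ss and dp
targets) and backward connections (dp origin; sp and ii targets), with
transmission delays, plus condition-specific parameter modulations ``B``.

All parameters are log-scalings of the prior means in :mod:`.constants`
(effective value = prior mean * exp(log-scaling)).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import constants as K

POPULATIONS = K.POPULATIONS
N_POP = len(POPULATIONS)
STATES_PER_AREA = 2 * N_POP

#: MMN model space: which intrinsic connections each model frees.
MMN_MODEL_SPACE = {
    "6G": ("sp->ii", "ii->sp", "dp->ii", "ii->dp", "sp->sp", "ii->ii"),
    "4Ga": ("sp->ii", "ii->sp", "sp->sp", "ii->ii"),
    "4Gb": ("dp->ii", "ii->dp", "sp->sp", "ii->ii"),
    "4Gc": ("sp->ii", "dp->ii", "sp->sp", "ii->ii"),
    "4Gd": ("ii->sp", "ii->dp", "sp->sp", "ii->ii"),
    "6G,D,T": ("sp->ii", "ii->sp", "dp->ii", "ii->dp", "sp->sp", "ii->ii"),
}

ASSR_MODEL_SPACE = ("full", "-J(1)", "-S", "-T", "-w")

#: Connections freed in the ASSR models (per area).
ASSR_FREE_G = ("sp->ii", "ii->sp", "sp->sp", "ii->ii")


class ModelError(ValueError):
    """Raised for invalid model structure or unknown labels."""


@dataclass
class MicrocircuitParams:
    """Log-scaling parameters of one cortical column."""

    G: dict = field(default_factory=lambda: {name: 0.0 for name in K.INTRINSIC})
    T: dict = field(default_factory=lambda: {p: 0.0 for p in POPULATIONS})
    S: float = 0.0
    J: dict = field(default_factory=lambda: {p: 0.0 for p in POPULATIONS})

    def __post_init__(self):
        missing = set(K.INTRINSIC) - set(self.G)
        if missing:
            raise ModelError(f"missing intrinsic connections: {sorted(missing)}")
        for d in (self.G, self.T, self.J):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ModelError(f"non-finite parameter {k!r}")


@dataclass
class NetworkModel:
    """One or more cortical columns with extrinsic coupling and modulations.

    ``a_fwd``/``a_bwd`` map directed area pairs to extrinsic log-scalings,
    ``C`` maps input areas to exogenous gain log-scalings, ``D`` holds
    intrinsic/extrinsic delay log-scalings and ``B`` maps condition labels to
    additive parameter deltas (keyed by parameter path).
    """

    areas: tuple
    columns: dict = None
    a_fwd: dict = field(default_factory=dict)
    a_bwd: dict = field(default_factory=dict)
    C: dict = None
    D: dict = field(default_factory=lambda: {"intrinsic": 0.0, "extrinsic": 0.0})
    B: dict = field(default_factory=dict)

    def __post_init__(self):
        self.areas = tuple(self.areas)
        if len(set(self.areas)) != len(self.areas):
            raise ModelError("duplicate area names")
        if self.columns is None:
            self.columns = {a: MicrocircuitParams() for a in self.areas}
        if self.C is None:
            self.C = {self.areas[0]: 0.0}
        for edges, label in ((self.a_fwd, "forward"), (self.a_bwd, "backward")):
            for (src, dst) in edges:
                if src == dst:
                    raise ModelError(f"self-loop {src}->{dst} in {label} edges")
                if src not in self.areas or dst not in self.areas:
                    raise ModelError(f"unknown area in {label} edge {src}->{dst}")
        overlap = set(self.a_fwd) & set(self.a_bwd)
        if overlap:
            raise ModelError(f"edges in both forward and backward sets: {overlap}")
        valid = set(self.parameter_paths())
        for cond, deltas in self.B.items():
            for path in deltas:
                if path not in valid:
                    raise ModelError(
                        f"condition {cond!r} modulates unknown parameter {path!r}")

    # -- parameter addressing ------------------------------------------------
    def parameter_paths(self):
        """All structural parameter paths of this network (excluding B)."""
        paths = []
        for a in self.areas:
            paths += [f"{a}.G.{c}" for c in K.INTRINSIC]
            paths += [f"{a}.T.{p}" for p in POPULATIONS]
            paths.append(f"{a}.S")
            paths += [f"{a}.J.{p}" for p in POPULATIONS]
        paths += [f"A_fwd.{s}->{d}" for (s, d) in self.a_fwd]
        paths += [f"A_bwd.{s}->{d}" for (s, d) in self.a_bwd]
        paths += [f"C.{a}" for a in self.C]
        paths.append("D.intrinsic")
        if self.a_fwd or self.a_bwd:
            paths.append("D.extrinsic")
        return paths

    def get_param(self, path):
        parts = path.split(".")
        if parts[0] == "B":
            return self.B[parts[1]].get(".".join(parts[2:]), 0.0)
        if parts[0] in ("A_fwd", "A_bwd"):
            src, dst = parts[1].split("->")
            return getattr(self, parts[0].lower())[(src, dst)]
        if parts[0] == "C":
            return self.C[parts[1]]
        if parts[0] == "D":
            return self.D[parts[1]]
        col = self.columns[parts[0]]
        if parts[1] == "S":
            return col.S
        return getattr(col, parts[1])[parts[2]]

    def set_param(self, path, value):
        parts = path.split(".")
        if parts[0] == "B":
            self.B.setdefault(parts[1], {})[".".join(parts[2:])] = value
        elif parts[0] in ("A_fwd", "A_bwd"):
            src, dst = parts[1].split("->")
            getattr(self, parts[0].lower())[(src, dst)] = value
        elif parts[0] == "C":
            self.C[parts[1]] = value
        elif parts[0] == "D":
            self.D[parts[1]] = value
        elif parts[1] == "S":
            self.columns[parts[0]].S = value
        else:
            getattr(self.columns[parts[0]], parts[1])[parts[2]] = value

    def copy(self):
        return copy.deepcopy(self)

    def with_condition(self, condition):
        """Return a copy with the condition's B deltas added to parameters."""
        net = self.copy()
        if condition is None:
            return net
        if condition not in self.B:
            raise ModelError(
                f"unknown condition {condition!r}; known: {sorted(self.B)}")
        for path, delta in self.B[condition].items():
            net.set_param(path, net.get_param(path) + delta)
        net.B = {}
        return net

    @property
    def n_states(self):
        return STATES_PER_AREA * len(self.areas)


# -- standard networks -------------------------------------------------------

def rest_network():
    """Single cortical column driven by broadband input (resting EEG)."""
    return NetworkModel(areas=("ctx",))


def mmn_network():
    """Three-source auditory hierarchy A1 -> STG -> IFG with backward edges.

    The deviant condition modulates superficial pyramidal self-inhibition in
    every area (deltas default to 0 until set).
    """
    net = NetworkModel(
        areas=("A1", "STG", "IFG"),
        a_fwd={("A1", "STG"): 0.0, ("STG", "IFG"): 0.0},
        a_bwd={("STG", "A1"): 0.0, ("IFG", "STG"): 0.0},
        C={"A1": 0.0},
    )
    net.B["standard"] = {}
    net.B["deviant"] = {f"{a}.G.sp->sp": 0.0 for a in net.areas}
    return net


def assr_network():
    """Bilateral primary auditory cortex driven by 40-Hz thalamic input."""
    return NetworkModel(areas=("A1L", "A1R"), C={"A1L": 0.0, "A1R": 0.0})


# -- priors ------------------------------------------------------------------

@dataclass
class Prior:
    mean: float = 0.0
    var: float = 0.0
    fixed: bool = True

    def __post_init__(self):
        if self.var < 0:
            raise ModelError("prior variance must be >= 0")
        if self.fixed and self.var != 0.0:
            raise ModelError("fixed parameters must have zero variance")


class PriorSpec(dict):
    """Mapping parameter path -> Prior, with free/fixed bookkeeping."""

    def free_names(self):
        return [k for k, p in self.items() if not p.fixed]

    def set_free(self, path, var, mean=0.0):
        self[path] = Prior(mean=mean, var=var, fixed=False)

    def means(self, names=None):
        names = self.free_names() if names is None else names
        return np.array([self[n].mean for n in names])

    def variances(self, names=None):
        names = self.free_names() if names is None else names
        return np.array([self[n].var for n in names])


def _fixed_priors_for(net, extra=()):
    spec = PriorSpec()
    for path in list(net.parameter_paths()) + list(extra):
        spec[path] = Prior()
    for cond, deltas in net.B.items():
        for path in deltas:
            spec[f"B.{cond}.{path}"] = Prior()
    return spec


def default_priors(paradigm, model_id):
    """Prior specification implementing one model of a paradigm's model space.

    MMN models free subsets of the intrinsic connections (in every area) plus
    the deviant-condition effect on superficial pyramidal self-inhibition;
    "6G,D,T" additionally frees delays and time constants.  ASSR models use
    informative prior means for the spiny stellate lead-field contribution
    J(1), sigmoid gain S and time constants T, dropped one at a time in the
    "-J(1)"/"-S"/"-T" variants; "-w" narrows the thalamic-drive bump width
    prior from 4 Hz to 1 Hz.
    """
    vG, vT, vS, vJ, vD, vB, vIn = (K.PRIOR_VARIANCE[f] for f in
                                   ("G", "T", "S", "J", "D", "B", "input"))
    if paradigm == "rest":
        if model_id != "standard":
            raise ModelError(
                f"unknown rest model {model_id!r}; valid: ['standard']")
        net = rest_network()
        spec = _fixed_priors_for(net, extra=("input.amplitude", "input.exponent"))
        for c in K.INTRINSIC:
            spec.set_free(f"ctx.G.{c}", vG)
        spec.set_free("input.amplitude", vIn)
        return spec

    if paradigm == "mmn":
        if model_id not in MMN_MODEL_SPACE:
            raise ModelError(f"unknown MMN model {model_id!r}; "
                             f"valid: {sorted(MMN_MODEL_SPACE)}")
        net = mmn_network()
        spec = _fixed_priors_for(net)
        for a in net.areas:
            for c in MMN_MODEL_SPACE[model_id]:
                spec.set_free(f"{a}.G.{c}", vG)
            spec.set_free(f"B.deviant.{a}.G.sp->sp", vB)
        if model_id == "6G,D,T":
            spec.set_free("D.intrinsic", vD)
            spec.set_free("D.extrinsic", vD)
            for a in net.areas:
                for p in POPULATIONS:
                    spec.set_free(f"{a}.T.{p}", vT)
        return spec

    if paradigm == "assr":
        if model_id not in ASSR_MODEL_SPACE:
            raise ModelError(f"unknown ASSR model {model_id!r}; "
                             f"valid: {list(ASSR_MODEL_SPACE)}")
        net = assr_network()
        spec = _fixed_priors_for(
            net, extra=("input.amplitude", "input.width"))
        emp = dict(K.ASSR_EMPIRICAL_PRIOR_MEANS)
        if model_id == "-J(1)":
            emp["J.ss"] = 0.0
        if model_id == "-S":
            emp["S"] = 0.0
        if model_id == "-T":
            emp["T"] = 0.0
        for a in net.areas:
            for c in ASSR_FREE_G:
                spec.set_free(f"{a}.G.{c}", vG)
            spec.set_free(f"{a}.S", vS, mean=emp["S"])
            spec.set_free(f"{a}.J.ss", vJ, mean=emp["J.ss"])
            for p in POPULATIONS:
                spec.set_free(f"{a}.T.{p}", vT, mean=emp["T"])
        spec.set_free("D.intrinsic", vD)
        spec.set_free("input.amplitude", vIn)
        # width is parameterized as log-scaling of the 4-Hz base width
        width_mean = 0.0 if model_id != "-w" else float(
            np.log(K.ASSR_BUMP_WIDTH_NARROW_HZ / K.ASSR_BUMP_WIDTH_HZ))
        spec.set_free("input.width", vIn, mean=width_mean)
        return spec

    raise ModelError(
        f"unknown paradigm {paradigm!r}; valid: ['rest', 'mmn', 'assr']")


def priors_to_config(spec):
    """Declarative form: {parameter path: {mean, variance, fixed}}.

    JSON-serializable with bit-exact float round trip.
    """
    return {path: dict(mean=p.mean, variance=p.var, fixed=p.fixed)
            for path, p in spec.items()}


def priors_from_config(config):
    spec = PriorSpec()
    for path, d in config.items():
        spec[path] = Prior(mean=d["mean"], var=d["variance"],
                           fixed=d["fixed"])
    return spec


def apply_priors(net, priors, theta=None, names=None):
    """Return a network copy with prior means (plus optional offsets) applied.

    ``theta``/``names`` set the named free parameters to the given values
    (absolute log-scalings, not offsets from the prior mean).
    """
    out = net.copy()
    extras = {}
    values = {k: p.mean for k, p in priors.items()}
    if theta is not None:
        values.update(dict(zip(names, np.asarray(theta, float))))
    for path, val in values.items():
        if path.startswith("input.") or path.startswith("noise."):
            extras[path] = val
        else:
            out.set_param(path, val)
    return out, extras


# -- dynamics ----------------------------------------------------------------

def sigmoid_rate(voltage, slope_scaling=0.0):
    """Population firing rate in [0, 1] for a membrane potential in mV.

    The logistic activation is centred at 0 mV; its slope at the inflection is
    ``SIGMOID_SLOPE * exp(slope_scaling) / 4`` per mV.
    """
    rho = K.SIGMOID_SLOPE * np.exp(slope_scaling)
    return 1.0 / (1.0 + np.exp(-rho * np.asarray(voltage, float)))


@dataclass
class CompiledNetwork:
    """Numeric arrays realizing a NetworkModel's flow (effective values)."""

    areas: tuple
    kappa: np.ndarray        # (N,) inverse time constants, 1/ms
    rho: np.ndarray          # (N,) sigmoid slopes
    w_self: np.ndarray       # (N, N) undelayed (self-inhibition) gains
    w_intr: np.ndarray       # (N, N) intrinsic delayed gains
    w_extr: np.ndarray       # (N, N) extrinsic delayed gains
    tau_intr: float          # ms
    tau_extr: float          # ms
    d_in: np.ndarray         # (N, n_areas) exogenous drive gains
    lead: np.ndarray         # (n_areas, N) observation weights on potentials

    @property
    def n(self):
        return self.kappa.size

    @property
    def w_total(self):
        return self.w_self + self.w_intr + self.w_extr


def compile_network(net):
    """Resolve log-scalings into the numeric arrays used by flow/transfer."""
    n_areas = len(net.areas)
    N = N_POP * n_areas
    idx = {(a, p): i * N_POP + j
           for i, a in enumerate(net.areas) for j, p in enumerate(POPULATIONS)}
    kappa = np.empty(N)
    rho = np.empty(N)
    w_self = np.zeros((N, N))
    w_intr = np.zeros((N, N))
    w_extr = np.zeros((N, N))
    d_in = np.zeros((N, n_areas))
    lead = np.zeros((n_areas, N))
    for ai, a in enumerate(net.areas):
        col = net.columns[a]
        for p in POPULATIONS:
            i = idx[(a, p)]
            kappa[i] = 1.0 / (K.T_PRIOR_MS[p] * np.exp(col.T[p]))
            rho[i] = K.SIGMOID_SLOPE * np.exp(col.S)
            lead[ai, i] = K.J_PRIOR[p] * np.exp(col.J[p])
        for name, (src, dst, sign, gbar) in K.INTRINSIC.items():
            g = sign * gbar * np.exp(col.G[name])
            if src == dst:
                w_self[idx[(a, dst)], idx[(a, src)]] += g
            else:
                w_intr[idx[(a, dst)], idx[(a, src)]] += g
        if a in net.C:
            d_in[idx[(a, "ss")], ai] = K.C_PRIOR * np.exp(net.C[a])
    for (src, dst), lam in net.a_fwd.items():
        g = K.EXTRINSIC_FORWARD_GAIN * np.exp(lam)
        for p, w in K.EXTRINSIC_FORWARD_TARGETS.items():
            w_extr[idx[(dst, p)], idx[(src, "sp")]] += g * w
    for (src, dst), lam in net.a_bwd.items():
        g = K.EXTRINSIC_BACKWARD_GAIN * np.exp(lam)
        for p, w in K.EXTRINSIC_BACKWARD_TARGETS.items():
            w_extr[idx[(dst, p)], idx[(src, "dp")]] += g * w
    tau_i = K.DELAY_INTRINSIC_MS * np.exp(net.D.get("intrinsic", 0.0))
    tau_e = K.DELAY_EXTRINSIC_MS * np.exp(net.D.get("extrinsic", 0.0))
    return CompiledNetwork(net.areas, kappa, rho, w_self, w_intr, w_extr,
                           tau_i, tau_e, d_in, lead)


def _rate(v, rho):
    return 1.0 / (1.0 + np.exp(-rho * v)) - 0.5


def flow(state, network, drive=None, compiled=None):
    """Time derivative of the state vector (delays collapsed to zero lag).

    ``state`` is ``[v, u]`` over all areas/populations; ``drive`` is a
    per-area input value (scalar or array).  Used for fixed points and
    linearization; the integrator and transfer function reinstate delays.
    """
    cn = compiled if compiled is not None else (
        compile_network(network) if isinstance(network, NetworkModel) else network)
    x = np.asarray(state, float)
    if x.size != 2 * cn.n:
        raise ModelError(f"state length {x.size} != {2 * cn.n}")
    v, u = x[:cn.n], x[cn.n:]
    drv = np.zeros(len(cn.areas)) if drive is None else \
        np.broadcast_to(np.asarray(drive, float), (len(cn.areas),))
    I = cn.w_total @ _rate(v, cn.rho) + cn.d_in @ drv
    k2 = cn.kappa ** 2
    return np.concatenate([u, k2 * (I - v) - 2.0 * cn.kappa * u])


def flow_jacobian(state, cn):
    """Analytic Jacobian of :func:`flow` at ``state`` (no delays)."""
    v = np.asarray(state, float)[:cn.n]
    s = 1.0 / (1.0 + np.exp(-cn.rho * v))
    rprime = cn.rho * s * (1.0 - s)
    k2 = cn.kappa ** 2
    N = cn.n
    Jm = np.zeros((2 * N, 2 * N))
    Jm[:N, N:] = np.eye(N)
    Jm[N:, :N] = (k2[:, None]) * (cn.w_total * rprime[None, :] - np.eye(N))
    Jm[N:, N:] = -2.0 * np.diag(cn.kappa)
    return Jm


class FixedPointError(RuntimeError):
    def __init__(self, residual):
        self.residual = residual
        super().__init__(f"fixed point not found; last residual {residual:.3e}")


def fixed_point(network, drive=0.0, tol=1e-10, max_iter=100):
    """Equilibrium state of the (delay-free) flow by damped Newton.

    Falls back to long-horizon integration if Newton stalls.  The returned
    state satisfies ``max|flow| < tol`` (default well below 1e-8).
    """
    cn = compile_network(network) if isinstance(network, NetworkModel) else network
    x = np.zeros(2 * cn.n)
    best = np.inf
    for attempt in range(2):
        for _ in range(max_iter):
            f = flow(x, cn, drive, compiled=cn)
            res = np.max(np.abs(f))
            if res < tol:
                return x
            Jm = flow_jacobian(x, cn)
            try:
                dx = np.linalg.solve(Jm, -f)
            except np.linalg.LinAlgError:
                dx = np.linalg.lstsq(Jm, -f, rcond=None)[0]
            step = 1.0
            for _ in range(30):
                xn = x + step * dx
                rn = np.max(np.abs(flow(xn, cn, drive, compiled=cn)))
                if rn < res:
                    x = xn
                    break
                step *= 0.5
            else:
                break
            best = min(best, res)
        if attempt == 0:
            # relaxation fallback: forward-Euler toward equilibrium
            dt = 0.05
            for _ in range(80000):
                x = x + dt * flow(x, cn, drive, compiled=cn)
                if not np.all(np.isfinite(x)):
                    raise FixedPointError(np.inf)
    res = np.max(np.abs(flow(x, cn, drive, compiled=cn)))
    if res < tol:
        return x
    raise FixedPointError(res)
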