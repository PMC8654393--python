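"""Synthetic cohorts with the statistical structure the analyses assume.

The study's clinical recordings are not available, so cohorts are generated
from the package's own forward models: per-subject parameters are drawn
around the prior means with group-level contrasts (a psychosis *diagnosis*
effect and a genetic *risk* effect on named parameters), symptom scores are
coupled linearly to named parameters, and observations carry realistic
noise.  Everything is reproducible from the cohort seed; each subject also
stores its own sub-seed so its data can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .cmc import (FixedPointError, ModelError, apply_priors, assr_network,
                  default_priors, mmn_network, rest_network)
from .forward import (CrossSpectrum, NoiseModel, Stimulus, UnstableModelError,
                      assr_grid, gaussian_bump_input, powerlaw_input,
                      predict_csd, rest_grid, simulate_erp)

#: Default group sizes from the study design.
GROUP_SIZES = {"Con": 107, "PScz": 108, "Rel": 57}

#: Default group effects (log-scale deltas).  The diagnosis effect adds to
#: PScz only; the risk effect to PScz and Rel.  Parameter paths refer to the
#: paradigm network named in the key.
DEFAULT_EFFECTS = {
    "assr": {
        "diagnosis": {"A1L.G.sp->sp": 0.25, "A1R.G.sp->sp": 0.25},
        "risk": {"A1L.G.sp->ii": -0.2, "A1R.G.sp->ii": -0.2},
    },
    "mmn": {
        "diagnosis": {"B.deviant.IFG.G.sp->sp": 0.3},
        "risk": {},
    },
    "rest": {
        "diagnosis": {"ctx.G.sp->sp": 0.25},
        "risk": {},
    },
}

#: Symptom model: positive-symptom score couples negatively to auditory
#: self-inhibition (disinhibition predicts abnormal percepts).
SYMPTOM_COUPLING = {"assr": {"A1L.G.sp->sp": -20.0},
                    "mmn": {"B.deviant.IFG.G.sp->sp": -20.0},
                    "rest": {"ctx.G.sp->sp": -20.0}}
SYMPTOM_SCALES = {"positive": (14.4, 5.0, 0.0, 49.0),
                  "negative": (7.3, 3.0, 0.0, 28.0)}


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort."""

    paradigms: tuple = ("assr",)
    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    effects: dict = None                 # paradigm -> contrast -> {path: d}
    symptom_coupling: dict = None
    between_sd: float = 0.1              # log-scale between-subject SD
    noise_rest: float = 0.1              # SD of log-power noise
    noise_mmn: float = 0.002             # additive ERP noise (about 10% of
                                         # the evoked peak: averaged trials)
    assr_dof: int = 150                  # Wishart dof: one per averaged
                                         # epoch (typical usable session)
    seed: int = 0
    age_mean: float = 39.4
    age_sd: float = 14.0
    sex_male_p: dict = field(default_factory=lambda: {
        "Con": 0.68, "PScz": 0.59, "Rel": 0.6})
    smoking_p: dict = field(default_factory=lambda: {
        "Con": 0.39, "PScz": 0.33, "Rel": 0.35})

    def __post_init__(self):
        if any(v < 1 for v in self.group_sizes.values()):
            raise ModelError("group sizes must be >= 1")
        if self.between_sd < 0:
            raise ModelError("between-subject SD must be >= 0")
        if self.effects is None:
            self.effects = {p: {c: dict(d) for c, d in
                                DEFAULT_EFFECTS[p].items()}
                            for p in self.paradigms}
        if self.symptom_coupling is None:
            self.symptom_coupling = {p: dict(SYMPTOM_COUPLING[p])
                                     for p in self.paradigms}


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    seed: int
    covariates: dict
    symptoms: dict
    true_params: dict            # paradigm -> {path: value}
    data: dict                   # paradigm -> paradigm-specific payload


def paradigm_network(paradigm):
    if paradigm == "rest":
        return rest_network()
    if paradigm == "mmn":
        return mmn_network()
    if paradigm == "assr":
        return assr_network()
    raise ModelError(f"unknown paradigm {paradigm!r}")


def paradigm_free_paths(paradigm):
    """The parameters that vary across subjects for a paradigm."""
    model = {"rest": "standard", "mmn": "6G", "assr": "full"}[paradigm]
    return default_priors(paradigm, model).free_names(), model


def assr_input(extras, grid=None):
    grid = assr_grid() if grid is None else grid
    width = K.ASSR_BUMP_WIDTH_HZ * np.exp(extras.get("input.width", 0.0))
    amp = K.ASSR_BUMP_AMPLITUDE * np.exp(extras.get("input.amplitude", 0.0))
    return gaussian_bump_input(40.0, width, amp, grid,
                               floor=K.ASSR_BUMP_FLOOR)


def rest_input(extras, grid=None):
    grid = rest_grid() if grid is None else grid
    amp = K.REST_INPUT_AMPLITUDE * np.exp(extras.get("input.amplitude", 0.0))
    expo = K.REST_INPUT_EXPONENT * np.exp(extras.get("input.exponent", 0.0))
    return powerlaw_input(amp, expo, grid, floor=K.REST_INPUT_FLOOR)


def predict_paradigm(paradigm, true_params, grid=None, erp_kwargs=None):
    """Noise-free forward prediction for a subject's true parameters."""
    net = paradigm_network(paradigm)
    priors = default_priors(paradigm,
                            {"rest": "standard", "mmn": "6G",
                             "assr": "full"}[paradigm])
    names = list(true_params)
    net, extras = apply_priors(net, priors, theta=list(true_params.values()),
                               names=names)
    if paradigm == "rest":
        inp = rest_input(extras, grid)
        return predict_csd(net, inp, grid=grid)
    if paradigm == "assr":
        inp = assr_input(extras, grid)
        # binaural click train: one common drive reaches both sources
        coh = np.ones((len(net.areas), len(net.areas)))
        return predict_csd(net, inp, grid=grid, input_coherence=coh)
    kwargs = dict(t_start_ms=-100.0, t_end_ms=400.0, dt=0.2)
    kwargs.update(erp_kwargs or {})
    return simulate_erp(net, Stimulus(), ("standard", "deviant"), **kwargs)


def add_observation_noise(paradigm, clean, spec: CohortSpec, rng):
    """Apply the paradigm's observation-noise model to a clean prediction."""
    if paradigm == "rest":
        d = clean.diagonal
        noisy = d * np.exp(spec.noise_rest * rng.standard_normal(d.shape))
        v = clean.values.copy()
        for c in range(v.shape[1]):
            v[:, c, c] = noisy[:, c]
        return CrossSpectrum(clean.grid, v, condition=clean.condition)
    if paradigm == "assr":
        # complex Wishart perturbation: Hermitian PSD by construction
        d = spec.assr_dof
        if not d:
            return clean                # dof 0/None: noiseless
        F, nc, _ = clean.values.shape
        out = np.empty_like(clean.values)
        for f in range(F):
            S = clean.values[f]
            w, V = np.linalg.eigh(S)
            w = np.clip(w, 0, None)
            Lc = V @ np.diag(np.sqrt(w))
            Z = (rng.standard_normal((nc, d))
                 + 1j * rng.standard_normal((nc, d))) / np.sqrt(2)
            X = Lc @ Z
            out[f] = (X @ X.conj().T) / d
        return CrossSpectrum(clean.grid, out, condition=clean.condition)
    if paradigm == "mmn":
        traces = {}
        sigma_samp = max(2.0 / clean.dt, 1.0)   # ~2 ms noise correlation
        half = int(np.ceil(4 * sigma_samp))
        for cond, tr in clean.traces.items():
            tr = np.asarray(tr)
            white = rng.standard_normal(tr.shape)
            kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_samp) ** 2)
            kern /= kern.sum()
            colored = np.apply_along_axis(
                lambda x: np.convolve(x, kern, mode="same"), -1, white)
            traces[cond] = tr + spec.noise_mmn * colored / colored.std()
        return type(clean)(clean.t_ms, traces, onset_ms=clean.onset_ms)
    raise ModelError(f"unknown paradigm {paradigm!r}")


def draw_true_parameters(spec: CohortSpec, paradigm, group, rng):
    names, _ = paradigm_free_paths(paradigm)
    priors = default_priors(paradigm,
                            {"rest": "standard", "mmn": "6G",
                             "assr": "full"}[paradigm])
    # subjects differ in their intrinsic gains and condition effects; the
    # biophysical constants (time constants, activation slope, lead field,
    # drive) are common to the cohort, mirroring the analyses' assumption
    # that connectivity -- not kinetics -- varies across people
    varies = lambda nm: (".G." in nm) or nm.startswith("B.")
    theta = {nm: priors[nm].mean
             + (spec.between_sd * rng.standard_normal() if varies(nm) else 0.0)
             for nm in names}
    # control-regime deviant disinhibition generating the mismatch response
    for nm in names:
        if nm.startswith("B.deviant.") and nm.endswith("G.sp->sp"):
            theta[nm] += K.MMN_DEVIANT_BASE
    eff = spec.effects.get(paradigm, {})
    applies = {"diagnosis": group == "PScz",
               "risk": group in ("PScz", "Rel")}
    for contrast, deltas in eff.items():
        if applies.get(contrast, False):
            for path, d in deltas.items():
                if path not in theta:
                    raise ModelError(
                        f"effect on {path!r} is not a free parameter")
                theta[path] += d
    return theta


def generate_subject_data(spec: CohortSpec, true_params, seed, grid=None,
                          erp_kwargs=None):
    """Per-paradigm data for stored true parameters; reproducible from seed."""
    rng = np.random.default_rng(seed)
    data = {}
    for paradigm, theta in true_params.items():
        clean = predict_paradigm(paradigm, theta, grid=grid,
                                 erp_kwargs=erp_kwargs)
        data[paradigm] = add_observation_noise(paradigm, clean, spec, rng)
    return data


def generate_cohort(spec: CohortSpec, grid=None, erp_kwargs=None,
                    max_retries=5):
    """Draw a full cohort of SubjectRecord (deterministic given the seed)."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    sid = 0
    for group, size in spec.group_sizes.items():
        for _ in range(size):
            sid += 1
            for attempt in range(max_retries):
                sub_seed = int(rng.integers(0, 2 ** 31 - 1))
                try:
                    true = {p: draw_true_parameters(spec, p, group, rng)
                            for p in spec.paradigms}
                    data = generate_subject_data(spec, true, sub_seed,
                                                 grid=grid,
                                                 erp_kwargs=erp_kwargs)
                    break
                except (UnstableModelError, FixedPointError):
                    continue
            else:
                raise ModelError(
                    f"subject {sid}: no stable parameter draw in "
                    f"{max_retries} attempts")
            age = spec.age_mean + spec.age_sd * rng.standard_normal()
            cov = dict(age=float(age),
                       male=bool(rng.random() < spec.sex_male_p[group]),
                       smoker=bool(rng.random() < spec.smoking_p[group]),
                       cpz=float(np.exp(rng.normal(5.5, 0.5)))
                       if group == "PScz" else 0.0)
            symptoms = {}
            for scale, (mean, sd, lo, hi) in SYMPTOM_SCALES.items():
                val = mean + sd * rng.standard_normal()
                if group == "PScz" and scale == "positive":
                    for paradigm, coup in spec.symptom_coupling.items():
                        if paradigm not in true:
                            continue
                        for path, w in coup.items():
                            base = default_priors(
                                paradigm, {"rest": "standard", "mmn": "6G",
                                           "assr": "full"}[paradigm]
                            )[path].mean
                            val += w * (true[paradigm][path] - base)
                if group != "PScz":
                    val = lo + 0.1 * (val - lo)
                symptoms[scale] = float(np.clip(val, lo, hi))
            subjects.append(SubjectRecord(
                subject_id=f"S{sid:04d}", group=group, seed=sub_seed,
                covariates=cov, symptoms=symptoms, true_params=true,
                data=data))
    return subjects
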