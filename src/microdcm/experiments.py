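"""In-silico studies and end-to-end pipelines.

Contains the five-model resting-spectrum perturbation study, sensitivity
analyses for the evoked (mismatch) and induced (40-Hz) paradigms, the
subject-level fitting helpers, and the cohort pipelines combining per-
subject inversion, random-effects model selection and PEB contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .cmc import (ModelError, NetworkModel, Prior, PriorSpec, apply_priors,
                  default_priors, mmn_network, rest_network,
                  MMN_MODEL_SPACE)
from .cohort import (CohortSpec, assr_input, generate_cohort,
                     paradigm_network, rest_input)
from .features import adjust_onef, band_power, mismatch_from_erp, peak_gamma
from .forward import (Stimulus, UnstableModelError, assr_grid,
                      gaussian_bump_input, predict_csd, rest_grid,
                      simulate_erp)
from .group import bms_random_effects, build_design, peb_fit
from .inversion import (FitSettings, Observation, csd_observation,
                        erp_observation, fit_variational_laplace)
from .cmc import FixedPointError

# -- five-model resting-EEG perturbation study -------------------------------

#: Parameter sets scaled by each microcircuit-pathology model: -1 = loss
#: (decrease per step), +1 = increase per step.
PATHOLOGY_MODELS = {
    1: {c: -1 for c in ("ss->sp", "ss->ii", "sp->ii", "ii->sp",
                        "dp->ii", "ii->dp")},          # all connectivity
    2: {c: -1 for c in ("sp->ii", "ii->sp", "dp->ii", "ii->dp")},
    3: {"ii->ii": -1},                                  # ii disinhibition
    4: {"ii->ii": +1},                                  # ii self-inhibition
    5: {"sp->sp": +1},                                  # sp self-inhibition
}


@dataclass
class PerturbationStudySpec:
    model_id: int
    step_percent: float = 3.0
    n_steps: int = 10

    def __post_init__(self):
        if self.model_id not in PATHOLOGY_MODELS:
            raise ModelError("model id must be in 1..5")
        if self.step_percent <= 0:
            raise ModelError("step size must be > 0")


@dataclass
class BandShiftReport:
    """Adjusted band-power deltas per perturbation step, plus the
    qualitative pattern classification."""

    model_id: int
    steps: np.ndarray            # log-scale deltas applied
    deltas: dict                 # band -> array of deltas vs step 0
    beta_peak_hz: np.ndarray
    unstable_steps: list
    pattern: dict                # band -> bool (reproduces the group change)

    @property
    def reproduces_all(self):
        return all(self.pattern[b] for b in ("theta", "beta", "gamma"))


def _classify(deltas, min_effect=0.02, prominence=0.5, slack=2e-3):
    """Scale-free pattern rule: a band reproduces the group change if its
    trajectory is monotone in the expected direction and its final change is
    a prominent feature (at least ``prominence`` of the largest band
    effect)."""
    signs = {"theta": +1, "beta": -1, "gamma": +1}
    finals = {b: v[-1] for b, v in deltas.items() if b in signs}
    mx = max(abs(v) for v in finals.values())
    out = {}
    for band, sign in signs.items():
        v = deltas[band]
        monot = bool(np.all(sign * np.diff(v) > -slack))
        out[band] = bool(monot and sign * finals[band] > 0
                         and abs(finals[band]) >= prominence * mx
                         and mx > min_effect)
    return out


def run_perturbation_model(spec: PerturbationStudySpec, grid=None):
    """Simulate one model's perturbation series and report band shifts."""
    grid = rest_grid() if grid is None else grid
    inp = rest_input({}, grid)
    step_log = np.log(1.0 + spec.step_percent / 100.0)
    steps = np.arange(spec.n_steps) * step_log
    bands = {b: [] for b in ("theta", "alpha", "beta", "gamma")}
    bpk = []
    unstable = []
    for k in range(spec.n_steps):
        net = rest_network()
        for conn, direction in PATHOLOGY_MODELS[spec.model_id].items():
            net.set_param(f"ctx.G.{conn}", direction * steps[k])
        try:
            csd = predict_csd(net, inp, grid=grid)
        except (UnstableModelError, FixedPointError):
            unstable.append(k)
            for b in bands:
                bands[b].append(np.nan)
            bpk.append(np.nan)
            continue
        adj = adjust_onef(csd.diagonal[:, 0], grid)
        bp = band_power(adj)
        for b in bands:
            bands[b].append(bp[b])
        sel = (grid >= 13.0) & (grid <= 30.0)
        bpk.append(float(grid[sel][np.argmax(adj.adjusted[sel])]))
    deltas = {b: np.asarray(v) - v[0] for b, v in bands.items()}
    return BandShiftReport(
        model_id=spec.model_id, steps=steps, deltas=deltas,
        beta_peak_hz=np.asarray(bpk), unstable_steps=unstable,
        pattern=_classify(deltas))


def rseeg_perturbation_study(step_percent=3.0, n_steps=10, grid=None):
    """The five-model study: which microcircuit pathology reproduces the
    resting-EEG band changes (theta up, beta down, gamma up)."""
    return {m: run_perturbation_model(
        PerturbationStudySpec(m, step_percent, n_steps), grid=grid)
        for m in PATHOLOGY_MODELS}


# -- sensitivity analyses ----------------------------------------------------


def mmn_sensitivity(parameter="G.sp->sp", deltas=(0.0, 0.2, 0.4),
                    areas=None, window=(150.0, 250.0), dt=0.2):
    """Effect of deviant-condition parameter changes on mismatch
    amplitude/latency.  Returns one (delta, amplitude, latency) row each."""
    net0 = mmn_network()
    areas = list(net0.areas) if areas is None else list(areas)
    rows = []
    for d in deltas:
        net = mmn_network()
        for a in areas:
            # control baseline: deviants disinhibit sp; the perturbation
            # (increased self-inhibition) erodes that condition effect
            net.B["deviant"][f"{a}.{parameter}"] = K.MMN_DEVIANT_BASE + d
        erp = simulate_erp(net, Stimulus(), ("standard", "deviant"), dt=dt)
        mm = mismatch_from_erp(erp, window=window)
        rows.append(dict(delta=float(d), amplitude=mm.amplitude,
                         latency_ms=mm.latency_ms))
    return rows


def assr_sensitivity(parameter="G.sp->sp", deltas=(0.0, 0.2, 0.4, 0.6),
                     band=(35.0, 45.0)):
    """Effect of parameter changes on driven 40-Hz power (both sources)."""
    grid = assr_grid()
    rows = []
    priors = default_priors("assr", "full")
    for d in deltas:
        net, extras = apply_priors(paradigm_network("assr"), priors)
        for a in net.areas:
            path = f"{a}.{parameter}"
            net.set_param(path, net.get_param(path) + d)
        inp = assr_input(extras, grid)
        coh = np.ones((len(net.areas), len(net.areas)))
        csd = predict_csd(net, inp, grid=grid, input_coherence=coh)
        sel = (grid >= band[0]) & (grid <= band[1])
        p = csd.diagonal[:, 0]
        rows.append(dict(delta=float(d),
                         gamma_power=float(p[sel].sum()),
                         peak_hz=float(grid[np.argmax(p)])))
    return rows


def sensitivity_analysis(paradigm, parameters=("G.sp->sp", "G.sp->ii"),
                         deltas=None):
    """Signed effect directions of microcircuit parameters per paradigm."""
    out = {}
    for par in parameters:
        if paradigm == "mmn":
            rows = mmn_sensitivity(par, deltas or (0.0, 0.2, 0.4))
            amp = [abs(r["amplitude"]) for r in rows]
            lat = [r["latency_ms"] for r in rows]
            out[par] = dict(rows=rows,
                            amplitude_direction=np.sign(amp[-1] - amp[0]),
                            latency_shift_ms=lat[-1] - lat[0])
        elif paradigm == "assr":
            rows = assr_sensitivity(par, deltas or (0.0, 0.2, 0.4, 0.6))
            pw = [r["gamma_power"] for r in rows]
            out[par] = dict(rows=rows,
                            power_direction=np.sign(pw[-1] - pw[0]))
        else:
            raise ModelError("sensitivity analysis covers 'mmn' and 'assr'")
    return out


# -- subject-level fitting ---------------------------------------------------


def assr_fit_priors(reduced=True, model_id="full"):
    """Priors for fitting ASSR cross-spectra.

    ``reduced`` fixes the empirical-prior parameters (J, S, T, delays, bump
    width) at their prior means and frees only the intrinsic gains and the
    drive amplitude -- the desk-scale configuration used by the cohort
    studies."""
    spec = default_priors("assr", model_id)
    if reduced:
        for name in list(spec):
            if (".T." in name or name.endswith(".S") or ".J." in name
                    or name.startswith("D.") or name.startswith("input.")
                    or name.endswith("G.ii->ii")):
                spec[name] = Prior(mean=spec[name].mean, var=0.0, fixed=True)
    return spec


def make_assr_predictor(priors, grid=None, log_diag=True):
    grid = assr_grid() if grid is None else grid
    names = priors.free_names()
    base_net = paradigm_network("assr")

    def predict(theta):
        net, extras = apply_priors(base_net, priors, theta=theta,
                                   names=names)
        inp = assr_input(extras, grid)
        coh = np.ones((len(base_net.areas), len(base_net.areas)))
        csd = predict_csd(net, inp, grid=grid, input_coherence=coh)
        return csd_observation(csd, log_diag=log_diag).y

    return predict, names


def fit_assr_subject(csd, priors=None, settings=None, log_diag=True):
    """Fit one subject's cross-spectra.  The diagonal is fitted on a log
    scale by default: sample cross-spectra have variance proportional to
    squared power, and the log transform stabilizes it."""
    priors = priors if priors is not None else assr_fit_priors()
    predict, names = make_assr_predictor(priors, grid=csd.grid,
                                         log_diag=log_diag)
    obs = csd_observation(csd, log_diag=log_diag)
    settings = settings or FitSettings(max_iter=32)
    return fit_variational_laplace(predict, obs, priors, settings)


def oddball_network():
    """Single-column oddball model (scaled-down mismatch generator)."""
    net = NetworkModel(areas=("ctx",))
    net.B["standard"] = {}
    net.B["deviant"] = {"ctx.G.sp->sp": 0.0}
    return net


def oddball_priors(model_id):
    """Single-column analogue of the mismatch model space."""
    if model_id not in MMN_MODEL_SPACE:
        raise ModelError(f"unknown model {model_id!r}; "
                         f"valid: {sorted(MMN_MODEL_SPACE)}")
    net = oddball_network()
    spec = PriorSpec()
    for path in net.parameter_paths():
        spec[path] = Prior()
    vG, vB, vT, vD = (K.PRIOR_VARIANCE[f] for f in ("G", "B", "T", "D"))
    for c in MMN_MODEL_SPACE[model_id]:
        spec.set_free(f"ctx.G.{c}", vG)
    spec.set_free("B.deviant.ctx.G.sp->sp", vB)
    if model_id == "6G,D,T":
        spec.set_free("D.intrinsic", vD)
        for p in ("ss", "sp", "ii", "dp"):
            spec.set_free(f"ctx.T.{p}", vT)
    return spec


def make_erp_predictor(priors, base_net, stimulus=None, dt=0.25,
                       t_start_ms=-50.0, t_end_ms=350.0, decimate=4):
    names = priors.free_names()
    stimulus = stimulus or Stimulus()

    def predict(theta):
        net, _ = apply_priors(base_net, priors, theta=theta, names=names)
        erp = simulate_erp(net, stimulus, ("standard", "deviant"), dt=dt,
                           t_start_ms=t_start_ms, t_end_ms=t_end_ms)
        return erp_observation(erp, decimate=decimate).y

    return predict, names


def fit_oddball_subject(erp, model_id, settings=None, dt=0.4, decimate=16):
    priors = oddball_priors(model_id)
    predict, names = make_erp_predictor(
        priors, oddball_network(), dt=dt,
        t_start_ms=float(erp.t_ms[0]), t_end_ms=float(erp.t_ms[-1]),
        decimate=decimate)
    obs = erp_observation(erp, decimate=decimate)
    settings = settings or FitSettings(max_iter=24)
    return fit_variational_laplace(predict, obs, priors, settings)


# -- cohort pipelines and recovery studies -----------------------------------


@dataclass
class PipelineResult:
    fits: list                    # per-subject FitResult (winning model)
    model_space: list
    log_evidence: np.ndarray      # (n_subjects, n_models) or None
    bms: object
    peb: object
    design: object
    report: dict


def run_assr_pipeline(cohort, scheme="risk-diagnosis", priors=None,
                      settings=None, selection=None,
                      exclude_nonconverged=False):
    """Fit every subject's cross-spectra and run PEB group contrasts.

    Non-converged fits are listed in the report; by default they are kept
    in the group analysis (set ``exclude_nonconverged`` to drop them).
    """
    priors = priors if priors is not None else assr_fit_priors()
    fits = []
    nonconverged = []
    for sub in cohort:
        fr = fit_assr_subject(sub.data["assr"], priors=priors,
                              settings=settings)
        fits.append(fr)
        if not fr.posterior.converged:
            nonconverged.append(sub.subject_id)
    keep = [i for i, fr in enumerate(fits)
            if fr.posterior.converged or not exclude_nonconverged]
    posts = [fits[i].posterior for i in keep]
    design = build_design([cohort[i].group for i in keep], scheme=scheme)
    selection = selection or [n for n in posts[0].names if ".G." in n]
    peb = peb_fit(posts, design, parameter_selection=selection)
    r2 = [fits[i].r2 for i in keep]
    report = dict(n_subjects=len(cohort), n_used=len(keep),
                  nonconverged=nonconverged, mean_r2=float(np.mean(r2)),
                  r2=r2)
    return PipelineResult(fits=fits, model_space=["full"], log_evidence=None,
                          bms=None, peb=peb, design=design, report=report)


def run_oddball_model_space(cohort_erps, models=None, settings=None,
                            seed=0):
    """Fit each subject under every mismatch model and select at random
    effects; returns (log-evidence table, BmsResult, fits of winning
    model)."""
    models = list(models or MMN_MODEL_SPACE)
    L = np.zeros((len(cohort_erps), len(models)))
    all_fits = {m: [] for m in models}
    for i, erp in enumerate(cohort_erps):
        for j, m in enumerate(models):
            fr = fit_oddball_subject(erp, m, settings=settings)
            L[i, j] = fr.posterior.free_energy
            all_fits[m].append(fr)
    bms = bms_random_effects(L, seed=seed)
    win = models[int(np.argmax(bms.protected_xp))]
    return L, bms, all_fits[win], models


def run_paradigm_pipeline(paradigm, cohort, scheme="risk-diagnosis",
                          models=None, settings=None, seed=0):
    """End-to-end pipeline for one paradigm.

    For "assr": fits every SubjectRecord's cross-spectra and runs PEB group
    contrasts.  For "mmn": expects single-column oddball subjects (pairs of
    (group, ErpTimeSeries) or SubjectRecords with one-channel traces), runs
    the six-model mismatch space with random-effects selection, then PEB on
    the winning model's parameters.  Deterministic given seeds.
    """
    if paradigm == "assr":
        return run_assr_pipeline(cohort, scheme=scheme, settings=settings)
    if paradigm != "mmn":
        raise ModelError("pipelines cover 'assr' and 'mmn'")
    groups, erps = [], []
    for item in cohort:
        if isinstance(item, tuple):
            g, erp = item
        else:
            g, erp = item.group, item.data["mmn"]
        groups.append(g)
        erps.append(erp)
    L, bms, fits, models_used = run_oddball_model_space(
        erps, models=models, settings=settings, seed=seed)
    design = build_design(groups, scheme=scheme)
    posts = [f.posterior for f in fits]
    peb = peb_fit(posts, design)
    report = dict(n_subjects=len(erps),
                  winning_model=models_used[int(np.argmax(bms.protected_xp))],
                  mean_r2=float(np.mean([f.r2 for f in fits])),
                  r2=[f.r2 for f in fits])
    return PipelineResult(fits=fits, model_space=models_used,
                          log_evidence=L, bms=bms, peb=peb, design=design,
                          report=report)


def peb_recovery_replication(seed, n_per_group=20, effect=0.25,
                             grid=None, settings=None, null=False):
    """One replication of the diagnosis-effect recovery experiment.

    Generates an ASSR cohort (Con/PScz/Rel) with a +``effect`` diagnosis
    delta on superficial pyramidal self-inhibition in both sources, fits all
    subjects, and runs PEB with genetic-risk and diagnosis contrasts.
    Returns the PEB result plus detection booleans.
    """
    # fit over a band wide enough to expose the background resonances,
    # which disambiguate the intrinsic gains from the drive response
    grid = np.arange(10.0, 50.0 + 1e-9, 1.0) if grid is None else grid
    effects = {"assr": {"diagnosis": {}, "risk": {}}} if null else {
        "assr": {"diagnosis": {"A1L.G.sp->sp": effect,
                               "A1R.G.sp->sp": effect},
                 "risk": {"A1L.G.sp->ii": -0.2, "A1R.G.sp->ii": -0.2}}}
    spec = CohortSpec(paradigms=("assr",),
                      group_sizes={"Con": n_per_group, "PScz": n_per_group,
                                   "Rel": n_per_group},
                      effects=effects, seed=seed)
    cohort = generate_cohort(spec, grid=grid)
    res = run_assr_pipeline(cohort, scheme="risk-diagnosis",
                            settings=settings or FitSettings(max_iter=24))
    peb = res.peb
    diag_row = peb.regressors.index("diagnosis:PScz>Rel")
    hits = {}
    for area in ("A1L", "A1R"):
        j = peb.parameters.index(f"{area}.G.sp->sp")
        hits[area] = dict(prob=float(peb.probability[diag_row, j]),
                          beta=float(peb.beta_mean[diag_row, j]))
    detected = all(h["prob"] > 0.95 and h["beta"] > 0
                   for h in hits.values())
    n_flagged = int(np.sum(peb.probability[1:] > 0.95))
    n_effects = int(peb.probability[1:].size)
    return dict(peb=peb, hits=hits, detected=detected,
                n_flagged=n_flagged, n_effects=n_effects,
                report=res.report)


def peb_recovery_study(n_replications=20, n_per_group=20, effect=0.25,
                       base_seed=100, null=False, **kw):
    """Replicated recovery (or null-calibration) experiment; returns the
    detection rate and the mean flagged fraction."""
    reps = []
    for r in range(n_replications):
        reps.append(peb_recovery_replication(base_seed + r,
                                             n_per_group=n_per_group,
                                             effect=effect, null=null, **kw))
    rate = float(np.mean([rep["detected"] for rep in reps]))
    flag_frac = float(np.mean([rep["n_flagged"] / rep["n_effects"]
                               for rep in reps]))
    return dict(replications=reps, detection_rate=rate,
                flagged_fraction=flag_frac)


def oddball_cohort_erps(n_subjects, seed, between_sd=0.1, noise=0.002,
                        deviant_effect=K.MMN_DEVIANT_BASE, dt=0.4):
    """Synthetic single-column oddball subjects generated under the full
    connectivity (6G) model."""
    from .cohort import add_observation_noise

    rng = np.random.default_rng(seed)
    priors = oddball_priors("6G")
    names = priors.free_names()
    erps = []
    spec = CohortSpec(paradigms=("mmn",), noise_mmn=noise,
                      group_sizes={"Con": 1}, seed=seed)
    for i in range(n_subjects):
        theta = {nm: priors[nm].mean + between_sd * rng.standard_normal()
                 for nm in names}
        theta["B.deviant.ctx.G.sp->sp"] = (
            deviant_effect + 0.5 * between_sd * rng.standard_normal())
        net, _ = apply_priors(oddball_network(), priors,
                              theta=list(theta.values()), names=names)
        erp = simulate_erp(net, Stimulus(), ("standard", "deviant"),
                           dt=dt, t_start_ms=-50.0, t_end_ms=350.0)
        erps.append(add_observation_noise(
            "mmn", erp, spec, np.random.default_rng(seed * 1000 + i)))
    return erps


def model_selection_study(n_replications=20, n_subjects=12, seed=500,
                          between_sd=0.25, settings=None):
    """Self-consistency of random-effects model selection: cohorts generated
    under 6G should prefer 6G.  The between-subject spread equals the prior
    SD so that the full connectivity set is expressed in the data."""
    wins = []
    results = []
    for r in range(n_replications):
        erps = oddball_cohort_erps(n_subjects, seed + r,
                                   between_sd=between_sd)
        L, bms, _, models = run_oddball_model_space(
            erps, settings=settings or FitSettings(max_iter=12),
            seed=seed + r)
        win = models[int(np.argmax(bms.protected_xp))]
        wins.append(win == "6G")
        results.append(dict(models=models, pxp=bms.protected_xp, win=win))
    return dict(win_rate=float(np.mean(wins)), replications=results)
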