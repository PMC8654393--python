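"""Versioned numeric constants: prior means and variances of the microcircuit.

All dynamic parameters are expressed as log-scalings of the prior means below
(effective value = prior mean * exp(log-scaling)), so a log-scaling of 0 is the
baseline ("standard") model everywhere in the package.

The baseline gains and time constants were calibrated once so that a single
column shows the canonical laminar resonance structure -- a gamma (~40 Hz)
resonance in the superficial pyramidal/interneuron loop and a beta (~15-20 Hz)
resonance in the deep pyramidal/interneuron loop -- on top of a low-pass
background.  They are package choices, not published estimates; see
docs/methods.md.
"""

CONSTANTS_VERSION = "1"

#: Population labels, in state order.
POPULATIONS = ("ss", "sp", "ii", "dp")

#: Intrinsic (within-column) connections: name -> (source, target, sign, prior-mean gain).
#: Gains are in units of millivolts of synaptic drive per unit firing-rate
#: deviation.  Sign +1 = excitatory (arrowhead), -1 = inhibitory (bead).
#: Ten connections: one inhibitory self-loop per population (synaptic gain)
#: plus six between-population connections.
INTRINSIC = {
    "ss->ss": ("ss", "ss", -1, 8.0),
    "sp->sp": ("sp", "sp", -1, 8.0),
    "ii->ii": ("ii", "ii", -1, 4.0),
    "dp->dp": ("dp", "dp", -1, 1.5),
    "ss->sp": ("ss", "sp", +1, 3.0),
    "ss->ii": ("ss", "ii", +1, 7.0),
    "sp->ii": ("sp", "ii", +1, 4.0),
    "ii->sp": ("ii", "sp", -1, 5.0),
    "dp->ii": ("dp", "ii", +1, 2.0),
    "ii->dp": ("ii", "dp", -1, 6.0),
}

#: Synaptic time constants, prior means in ms.  Lumped effective constants:
#: the superficial pyramidal value places that population's gain-dependent
#: corner frequency near the low gamma band, and the interneuron value puts
#: the pyramidal-interneuron loop resonance in the beta band.
T_PRIOR_MS = {"ss": 3.0, "sp": 10.0, "ii": 14.0, "dp": 40.0}

#: Baseline sigmoid slope parameter (1/mV); firing-rate slope at inflection is
#: SIGMOID_SLOPE/4 per mV.
SIGMOID_SLOPE = 2.0

#: Lead-field contribution of each population to the local source signal.
#: Superficial pyramidal cells dominate; interneurons contribute nothing.
J_PRIOR = {"ss": 0.2, "sp": 0.8, "ii": 0.0, "dp": 0.2}

#: Transmission delays, prior means in ms.
DELAY_INTRINSIC_MS = 1.0
DELAY_EXTRINSIC_MS = 12.0

#: Extrinsic coupling: prior-mean gain and laminar target weights.
#: Forward connections originate in sp and target ss (+ dp); backward
#: connections originate in dp and target sp (+ ii).
EXTRINSIC_FORWARD_GAIN = 1.5
EXTRINSIC_FORWARD_TARGETS = {"ss": 1.0, "dp": 0.5}
EXTRINSIC_BACKWARD_GAIN = 1.0
EXTRINSIC_BACKWARD_TARGETS = {"sp": 1.0, "ii": 0.5}

#: Exogenous input gain prior mean (input enters spiny stellate cells).
C_PRIOR = 1.0

#: Prior variances of the log-scaling parameters, by family.  A parameter that
#: a model "fixes" gets variance 0 instead.
PRIOR_VARIANCE = {
    "G": 1.0 / 16.0,
    "A": 1.0 / 16.0,
    "B": 1.0 / 16.0,
    "T": 1.0 / 32.0,
    "S": 1.0 / 32.0,
    "J": 1.0 / 32.0,
    "D": 1.0 / 32.0,
    "C": 1.0 / 16.0,
    "input": 1.0 / 16.0,
    "noise": 1.0 / 16.0,
}

#: ASSR empirical priors: non-zero prior means, on the log scale, for the
#: parameters the full ASSR model treats with informative ("empirical")
#: priors, and the thalamic-drive bump width priors in Hz.  The faster time
#: constants move the pyramidal-interneuron loop resonance into the gamma
#: band, where the driven 40-Hz response lives.
ASSR_EMPIRICAL_PRIOR_MEANS = {"J.ss": 0.5, "S": 0.2, "T": -0.5}
ASSR_BUMP_WIDTH_HZ = 4.0
ASSR_BUMP_WIDTH_NARROW_HZ = 1.0

#: Deviant-condition effect generating the mismatch response in the
#: reference (control) regime: deviant tones transiently disinhibit
#: superficial pyramidal cells.  Pathological increases in self-inhibition
#: push this toward zero, shrinking the mismatch amplitude.
MMN_DEVIANT_BASE = -0.3

#: Resting-state exogenous drive: power-law spectrum parameters.
REST_INPUT_AMPLITUDE = 1.0
REST_INPUT_EXPONENT = 1.0
REST_INPUT_FLOOR = 0.1

#: ASSR thalamic-drive bump amplitude and broadband floor (package choices).
ASSR_BUMP_AMPLITUDE = 1.0
ASSR_BUMP_FLOOR = 0.05

#: Observation-noise prior means (spectral floor amplitudes, a.u.).
CHANNEL_NOISE_WHITE = 1e-4
CHANNEL_NOISE_PINK = 1e-3
SOURCE_NOISE_WHITE = 1e-4
SOURCE_NOISE_PINK = 1e-3
NOISE_PINK_EXPONENT = 1.0
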