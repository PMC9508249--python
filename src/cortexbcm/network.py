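"""Crossbar pattern learning and the binocular orientation-selectivity network.

Two experiment pipelines are provided:

* :func:`run_crossbar_learning` — a 3x3 crossbar of memristive synapses
  converging on one output neuron learns an 'X' figure.  Per 200 ms epoch,
  Poisson optical pulses (30 Hz on the figure, 14 Hz on the background)
  drive the device model; the postsynaptic current is read as
  I = sum(w0 * G) with w0 = 0.5 V, converted to a feedback firing rate
  rho_y = g * I with g = 50 Hz/mA, and the BCM rule updates the persistent
  conductances.

* :func:`run_rearing` — two 9x9 input layers (left/right eye) project onto
  a single cortical cell, rho_y = Gl.rho_xl + Gr.rho_xr, trained under one
  of three rearing conditions: normal (the same oriented bar to both
  eyes each epoch), monocular deprivation (one eye sees bars, the other
  4-6 Hz noise) and binocular deprivation (both eyes noise).  This is the
  reduced rate-based path: weights are dimensionless conductances
  G / REFERENCE_CONDUCTANCE_US, and the per-epoch realized input rates
  carry Poisson sampling noise.

Units bridge: with the reference conductance of 5 mS the physical window
50-350 uS maps onto dimensionless weights 0.01-0.07; the crossbar path
keeps physical units and converts current to rate through (w0, g).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import device as dev
from .bcm import BCMParams, BCMState, bcm_dGdt, init_state, update_average
from .stimuli import (
    CROSS_PIXELS,
    RateMap,
    make_cross_pattern,
    make_noise_pattern,
    make_orientation_pattern,
    phototransduce,
    poisson_train,
    spawn_seeds,
)

__all__ = [
    "REFERENCE_CONDUCTANCE_US",
    "CrossbarConfig",
    "CrossbarResult",
    "RearingProtocol",
    "TuningResult",
    "readout_rate",
    "run_crossbar_learning",
    "run_rearing",
    "winner_orientation",
    "selectivity_metrics",
    "history_threshold",
]

#: Reference conductance (uS) absorbing the current-to-rate constants: the
#: device window 50-350 uS maps to dimensionless weights 0.01-0.07.
REFERENCE_CONDUCTANCE_US = 5000.0

ORIENTATIONS = (0, 45, 90, 135)
CONDITIONS = ("normal", "monocular_deprivation", "binocular_deprivation")


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------

def readout_rate(
    weights,
    ratemaps=None,
    w0: float = 0.5,
    g: float = 50.0,
) -> float:
    """Postsynaptic firing rate of the linear cortical cell (Hz).

    Two unit conventions, matching the two pipelines:

    * ``ratemaps`` given (one RateMap or a (left, right) pair):
      dimensionless weights, rho_y = sum over eyes of w . rho_x.
    * ``ratemaps`` is None: hardware read of physical conductances (uS),
      rho_y = g * I with I = w0 * sum(G) in mA — e.g. nine synapses at
      200 uS read at 0.5 V give I = 0.9 mA and rho_y = 45 Hz at
      g = 50 Hz/mA.
    """
    w = np.asarray(weights, dtype=float)
    if ratemaps is None:
        current_mA = w0 * w.sum() * 1e-3  # V * uS = uA
        return g * current_mA
    maps = ratemaps if isinstance(ratemaps, (tuple, list)) else (ratemaps,)
    rates = np.concatenate([m.rates for m in maps])
    if w.ravel().shape != rates.shape:
        raise ValueError(
            f"dimension mismatch: {w.size} weights vs {rates.size} input rates"
        )
    return float(w.ravel() @ rates)


# ---------------------------------------------------------------------------
# crossbar pattern learning (hardware loop)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossbarConfig:
    """Configuration of the 3x3 'X'-pattern learning loop."""

    w0: float = 0.5            # read amplitude (V)
    g: float = 50.0            # current-to-rate gain (Hz/mA)
    window: float = 200.0      # integration window = epoch duration (ms)
    epochs: int = 2000
    seed: int = 0
    high_rate: float = 30.0    # figure pixels (Hz)
    low_rate: float = 14.0     # background pixels (Hz)
    pulse_width: float = 5.0   # optical-evoked pulse width (ms)
    device: dev.DeviceParams = field(default_factory=dev.calibrate_defaults)
    bcm: BCMParams = field(default_factory=BCMParams)

    def __post_init__(self) -> None:
        if self.window <= 0 or self.g <= 0:
            raise ValueError("window and g must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class CrossbarResult:
    pattern: RateMap
    weight_trace: np.ndarray   # (epochs, 9) persistent conductance (uS)
    rate_trace: np.ndarray     # (epochs,) feedback rate rho_y (Hz)
    theta_trace: np.ndarray    # (epochs,)
    initial_G: np.ndarray      # (9,) uS
    final_G: np.ndarray        # (9,) uS

    @property
    def pattern_pixels(self) -> np.ndarray:
        """Boolean mask (row-major) of the X-figure pixels (1,3,5,7,9)."""
        mask = np.zeros(self.pattern.rates.size, dtype=bool)
        mask[[p - 1 for p in CROSS_PIXELS]] = True
        return mask


def run_crossbar_learning(config: CrossbarConfig) -> CrossbarResult:
    """Learn the 'X' figure on the 3x3 crossbar with the feedback loop."""
    pattern = make_cross_pattern(config.high_rate, config.low_rate)
    rates = pattern.rates
    n = rates.size
    p_dev, p_bcm = config.device, config.bcm
    # during the read window the optical pulses excite only the transient
    # state (u, G_short) probed by the current readout; the persistent
    # weight is set exclusively by the BCM feedback update, as in the
    # hardware loop where the feedback pulses realize the net rule
    p_read = replace(p_dev, retain_frac=0.0)
    rng = np.random.default_rng(config.seed)

    # all synapses start at low stochastic weights: bottom 10% of the window
    G0 = rng.uniform(p_dev.G_min, p_dev.G_min + 0.1 * p_dev.window_width, n)
    states = [dev.DeviceState.initial(p_dev, g0) for g0 in G0]

    bcm_state = init_state(G0 / REFERENCE_CONDUCTANCE_US, rates, p_bcm)
    epoch_seeds = spawn_seeds(rng.integers(2**31 - 1), config.epochs * n)

    wtrace = np.empty((config.epochs, n))
    ytrace = np.empty(config.epochs)
    ttrace = np.empty(config.epochs)
    for e in range(config.epochs):
        # optical drive through the solar cells
        for i in range(n):
            train = poisson_train(
                rates[i], config.window, int(epoch_seeds[e * n + i])
            )
            pulses = phototransduce(train, pulse_width=config.pulse_width)
            st = replace(states[i], t=0.0)
            trace = dev.run_train(st, pulses, p_read)
            st = trace.final_state
            states[i] = dev.relax(st, max(config.window - st.t, 0.0), p_read)

        # current readout and rate feedback
        rho_y = readout_rate(
            [s.G for s in states], None, w0=config.w0, g=config.g
        )

        # BCM weight modification applied to the persistent conductance
        w = np.array([s.G_long for s in states]) / REFERENCE_CONDUCTANCE_US
        dw = bcm_dGdt(rates, rho_y, bcm_state, p_bcm) * (config.window / 1000.0)
        w = np.clip(w + dw, p_bcm.w_min, p_bcm.w_max)
        states = [
            replace(s, G_long=wi * REFERENCE_CONDUCTANCE_US)
            for s, wi in zip(states, w)
        ]
        bcm_state = update_average(
            BCMState(w, bcm_state.theta, bcm_state.avg_rho_y_sq),
            rho_y,
            config.window,
            p_bcm,
        )
        wtrace[e] = w * REFERENCE_CONDUCTANCE_US
        ytrace[e] = rho_y
        ttrace[e] = bcm_state.theta

    return CrossbarResult(
        pattern=pattern,
        weight_trace=wtrace,
        rate_trace=ytrace,
        theta_trace=ttrace,
        initial_G=G0,
        final_G=wtrace[-1].copy(),
    )


# ---------------------------------------------------------------------------
# binocular rearing (reduced rate-based path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RearingProtocol:
    """One rearing condition of the orientation-selectivity experiment."""

    condition: str = "normal"
    orientations: tuple = ORIENTATIONS
    size: int = 9
    high_rate: float = 30.0
    low_rate: float = 14.0
    noise_lo: float = 4.0
    noise_hi: float = 6.0
    epochs: int = 6000
    epoch_duration: float = 200.0  # ms
    seed: int = 0
    frozen_noise: bool = False     # draw deprivation noise once per run
    deprived_eye: str = "right"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.deprived_eye not in ("left", "right"):
            raise ValueError("deprived_eye must be 'left' or 'right'")


@dataclass(frozen=True)
class TuningResult:
    """Outcome of one rearing run."""

    protocol: RearingProtocol
    orientations: tuple
    weight_left: np.ndarray    # (size, size) final dimensionless weights
    weight_right: np.ndarray
    weight_trace: np.ndarray   # (n_samples, 2*size*size)
    trace_epochs: np.ndarray   # epoch index of each weight sample
    rate_trace: np.ndarray     # (epochs, n_orientations) probe rho_y (Hz)
    theta_trace: np.ndarray    # (epochs,)
    w_min: float
    w_max: float

    def steady_slice(self, frac: float = 0.1) -> slice:
        """Index slice of the final ``frac`` of epochs (the steady state)."""
        n = self.rate_trace.shape[0]
        return slice(max(n - max(int(frac * n), 1), 0), n)

    def steady_rates(self) -> np.ndarray:
        return self.rate_trace[self.steady_slice()].mean(axis=0)

    def steady_theta(self) -> float:
        return float(self.theta_trace[self.steady_slice()].mean())


def _realized_rates(ideal: np.ndarray, duration_ms: float, rng) -> np.ndarray:
    """Poisson-realized per-pixel rates over one presentation window."""
    window_s = duration_ms / 1000.0
    return rng.poisson(ideal * window_s) / window_s


def run_rearing(protocol: RearingProtocol, params: BCMParams | None = None) -> TuningResult:
    """Train the two-eye network under one rearing condition."""
    params = params or BCMParams()
    rng = np.random.default_rng(protocol.seed)
    size = protocol.size
    npx = size * size

    bar_maps = {
        a: make_orientation_pattern(size, a, protocol.high_rate, protocol.low_rate)
        for a in protocol.orientations
    }
    orientations = tuple(protocol.orientations)
    mean_noise = 0.5 * (protocol.noise_lo + protocol.noise_hi)

    def noise_rates() -> np.ndarray:
        return rng.uniform(protocol.noise_lo, protocol.noise_hi, npx)

    frozen = noise_rates() if protocol.frozen_noise else None

    deprived_left = protocol.deprived_eye == "left"
    cond = protocol.condition

    # probe maps per orientation, used for the reported tuning curves: the
    # deprived eye contributes its mean noise rate
    probes = {}
    for a in orientations:
        bar = bar_maps[a].rates
        flat = np.full(npx, mean_noise)
        if cond == "normal":
            probes[a] = np.concatenate([bar, bar])
        elif cond == "monocular_deprivation":
            probes[a] = (
                np.concatenate([flat, bar]) if deprived_left
                else np.concatenate([bar, flat])
            )
        else:
            probes[a] = np.concatenate([flat, flat])

    # lower stochastic initial weights: bottom 10% of the weight range
    w0 = rng.uniform(
        params.w_min, params.w_min + 0.1 * (params.w_max - params.w_min), 2 * npx
    )
    state = init_state(w0, probes[orientations[0]], params)

    sample_every = max(1, protocol.epochs // 400)
    samples, sample_epochs = [], []
    rate_trace = np.empty((protocol.epochs, len(orientations)))
    theta_trace = np.empty(protocol.epochs)

    for e in range(protocol.epochs):
        angle = orientations[rng.integers(len(orientations))]
        bar = bar_maps[angle].rates

        def eye_input(is_deprived: bool) -> np.ndarray:
            if not is_deprived:
                return bar
            return frozen if frozen is not None else noise_rates()

        if cond == "normal":
            left, right = bar, bar
        elif cond == "monocular_deprivation":
            left = eye_input(deprived_left)
            right = eye_input(not deprived_left)
        else:
            left = eye_input(True)
            right = eye_input(True)

        ideal = np.concatenate([left, right])
        realized = _realized_rates(ideal, protocol.epoch_duration, rng)
        rho_y = float(state.G @ realized)
        dG = bcm_dGdt(realized, rho_y, state, params) * (
            protocol.epoch_duration / 1000.0
        )
        G_new = np.clip(state.G + dG, params.w_min, params.w_max)
        state = update_average(
            BCMState(G_new, state.theta, state.avg_rho_y_sq),
            rho_y,
            protocol.epoch_duration,
            params,
        )

        for k, a in enumerate(orientations):
            rate_trace[e, k] = float(state.G @ probes[a])
        theta_trace[e] = state.theta
        if e % sample_every == 0 or e == protocol.epochs - 1:
            samples.append(state.G.copy())
            sample_epochs.append(e)

    return TuningResult(
        protocol=protocol,
        orientations=orientations,
        weight_left=state.G[:npx].reshape(size, size),
        weight_right=state.G[npx:].reshape(size, size),
        weight_trace=np.asarray(samples),
        trace_epochs=np.asarray(sample_epochs),
        rate_trace=rate_trace,
        theta_trace=theta_trace,
        w_min=params.w_min,
        w_max=params.w_max,
    )


# ---------------------------------------------------------------------------
# outcome analysis
# ---------------------------------------------------------------------------

def winner_orientation(
    result: TuningResult, tie_tol: float = 1e-6
) -> int | None:
    """Winning orientation, or None if no orientation is superthreshold.

    Steady state is the mean over the final 10% of epochs.  The argmax
    orientation wins only if it is superthreshold; a tie within ``tie_tol``
    (Hz) between the top two is reported as unresolved (None).
    """
    rates = result.steady_rates()
    theta = result.steady_theta()
    order = np.argsort(rates)[::-1]
    top, second = rates[order[0]], rates[order[1]]
    if top - second <= tie_tol:
        return None
    if top <= theta:
        return None
    return int(result.orientations[order[0]])


def selectivity_metrics(result: TuningResult) -> dict:
    """Summary of a rearing outcome.

    Returns the steady-state winner rate (Hz), its margin over theta, and
    the cosine similarity of the two eyes' weight maps (1 for perfectly
    matched binocular receptive fields).
    """
    rates = result.steady_rates()
    theta = result.steady_theta()
    k = int(np.argmax(rates))
    wl = result.weight_left.ravel()
    wr = result.weight_right.ravel()
    cos = float(wl @ wr / (np.linalg.norm(wl) * np.linalg.norm(wr)))
    return {
        "winner": winner_orientation(result),
        "winner_rate": float(rates[k]),
        "margin_over_theta": float(rates[k] - theta),
        "theta": theta,
        "eye_matching": cos,
    }


def history_threshold(
    G0_uS: float,
    probe: RateMap | None = None,
    params: BCMParams | None = None,
    n_synapses: int = 9,
) -> float:
    """Sliding threshold induced by a device history state G0 (uS).

    Presents a fixed probe pattern to ``n_synapses`` synapses preset to
    G0; the resulting response seeds <rho_y^2> and hence theta.  Monotone
    increasing in G0: higher history states slide the threshold up.
    """
    params = params or BCMParams()
    probe = probe or make_cross_pattern(30.0, 14.0)
    w = np.full(probe.rates.size, G0_uS / REFERENCE_CONDUCTANCE_US)
    return init_state(w, probe.rates, params).theta
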