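"""Rate-based BCM learning engine with a sliding modification threshold.

The synaptic drift of the triplet-STDP rule on Poisson rate-coded trains
reduces, in the All-to-All limit, to a rate-based rule

    dG/dt = phi(rho_y, theta) * rho_x
          = (-A2- tau- rho_y - A3- tau- tau_x rho_x rho_y
             + A2+ tau+ rho_y + A3+ tau+ tau_y rho_y^2) * rho_x

which becomes the BCM form by (i) setting A3- = 0 (minimal triplet rule)
and (ii) scaling A2+- by <rho_y^2>/rho_0^2.  The modification function is
then

    phi(rho_y, theta) = A3+ tau+ tau_y * rho_y * (rho_y - theta),

negative below the threshold, zero at 0 and at theta, positive above, with
the threshold sliding as

    theta = <rho_y^2> (A2- tau- - A2+ tau+) / (rho_0^2 A3+ tau+ tau_y).

<rho_y^2> is estimated by an exponential moving average with time constant
``tau_avg``.  Weights are dimensionless (device conductance divided by a
reference conductance, see :mod:`cortexbcm.network`) and hard-clipped to
their bounds, mirroring the bounded conductance window of the physical
synapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .stdp import TripletParams

__all__ = [
    "BCMParams",
    "BCMState",
    "phi",
    "bcm_dGdt",
    "slide_theta",
    "update_average",
    "bcm_step",
    "init_state",
    "equilibrium_rate",
]


@dataclass(frozen=True)
class BCMParams:
    """Constants of the rate-based BCM engine.

    ``rho0`` (Hz) sets the scale of the sliding threshold (and thereby the
    steady-state firing rate); ``tau_avg`` (ms) is the averaging window of
    the postsynaptic-activity estimator, long relative to a 200 ms
    presentation epoch and short relative to a full rearing run.
    ``learning_rate`` is a global prescale of the drift: it sets how fast
    weights move but cancels out of the threshold formula, so it does not
    shift any fixed point.  Weight bounds are dimensionless.
    """

    triplet: TripletParams = field(default_factory=TripletParams)
    rho0: float = 32.0
    tau_avg: float = 5_000.0
    w_min: float = 0.01
    w_max: float = 0.07
    learning_rate: float = 0.005
    a3_minus_active: bool = False  # BCM reduction uses A3- = 0

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        if self.tau_avg <= 0:
            raise ValueError("tau_avg must be positive")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be < w_max")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    # products used throughout, with time constants converted to seconds
    @property
    def a2p_tp(self) -> float:
        return self.triplet.A2_plus * self.triplet.tau_plus / 1000.0

    @property
    def a2m_tm(self) -> float:
        return self.triplet.A2_minus * self.triplet.tau_minus / 1000.0

    @property
    def a3p_tp_ty(self) -> float:
        return (
            self.triplet.A3_plus
            * self.triplet.tau_plus
            * self.triplet.tau_y
            / 1e6
        )

    @property
    def a3m_tm_tx(self) -> float:
        return (
            self.triplet.A3_minus
            * self.triplet.tau_minus
            * self.triplet.tau_x
            / 1e6
        )


@dataclass(frozen=True)
class BCMState:
    """Weight vector, sliding threshold, and running <rho_y^2>."""

    G: np.ndarray
    theta: float
    avg_rho_y_sq: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "G", np.asarray(self.G, dtype=float))
        if self.theta < 0 or self.avg_rho_y_sq < 0:
            raise ValueError("theta and avg_rho_y_sq must be non-negative")


def phi(rho_y: float, theta: float, params: BCMParams) -> float:
    """BCM modification function: zero at 0 and theta, negative between.

    Reduced quadratic form phi = A3+ tau+ tau_y * rho_y * (rho_y - theta).
    """
    if rho_y < 0:
        raise ValueError("rho_y must be non-negative")
    return params.a3p_tp_ty * rho_y * (rho_y - theta) + 0.0


def slide_theta(avg_rho_y_sq: float, params: BCMParams) -> float:
    """Sliding threshold, proportional to the running mean of rho_y^2."""
    if avg_rho_y_sq < 0:
        raise ValueError("avg_rho_y_sq must be non-negative")
    num = params.a2m_tm - params.a2p_tp
    theta = avg_rho_y_sq * num / (params.rho0**2 * params.a3p_tp_ty)
    if theta < 0:
        raise ValueError(
            "negative threshold: parameter set violates "
            "A2_minus*tau_minus > A2_plus*tau_plus"
        )
    return theta


def bcm_dGdt(rho_x, rho_y: float, state: BCMState, params: BCMParams):
    """Weight drift dG/dt (per second) for input rate(s) ``rho_x``.

    Expanded triplet-drift polynomial with A2+- scaled by
    <rho_y^2>/rho0^2 (the sliding-threshold redefinition) and A3- = 0 in
    the BCM reduction (kept available behind ``a3_minus_active``).
    Accepts scalar or vector rho_x.
    """
    rho_x = np.asarray(rho_x, dtype=float)
    if np.any(rho_x < 0) or rho_y < 0:
        raise ValueError("rates must be non-negative")
    scale = state.avg_rho_y_sq / params.rho0**2
    drift = (
        -params.a2m_tm * scale * rho_y
        + params.a2p_tp * scale * rho_y
        + params.a3p_tp_ty * rho_y**2
    )
    if params.a3_minus_active:
        drift = drift - params.a3m_tm_tx * rho_x * rho_y
    return params.learning_rate * drift * rho_x


def update_average(state: BCMState, rho_y: float, dt: float, params: BCMParams) -> BCMState:
    """Exponential-moving-average update of <rho_y^2>; theta recomputed.

    ``dt`` in ms.  A constant rho_y held for much longer than tau_avg
    drives the average to rho_y^2 (EMA fixed point).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    alpha = 1.0 - float(np.exp(-dt / params.tau_avg))
    avg = state.avg_rho_y_sq + alpha * (rho_y**2 - state.avg_rho_y_sq)
    return BCMState(state.G, slide_theta(avg, params), avg)


def bcm_step(state: BCMState, rho_x_vector, dt: float, params: BCMParams) -> tuple[BCMState, float]:
    """One presentation epoch: respond, update weights, slide the threshold.

    rho_y = G . rho_x (linear neuron); every weight moves by
    bcm_dGdt * dt (dt in ms), hard-clipped to the bounds; then the running
    average and theta are updated.  Returns (new state, rho_y).
    """
    rho_x = np.asarray(rho_x_vector, dtype=float)
    if rho_x.shape != state.G.shape:
        raise ValueError(
            f"dimension mismatch: weights {state.G.shape}, rates {rho_x.shape}"
        )
    rho_y = float(state.G @ rho_x)
    dG = bcm_dGdt(rho_x, rho_y, state, params) * (dt / 1000.0)
    G_new = np.clip(state.G + dG, params.w_min, params.w_max)
    new = update_average(
        BCMState(G_new, state.theta, state.avg_rho_y_sq), rho_y, dt, params
    )
    return new, rho_y


def init_state(weights, probe_rho_x, params: BCMParams) -> BCMState:
    """Initial state with theta seeded by one probe presentation.

    Avoids the theta = 0 pathology at start: the running average is
    initialized to the squared response to the probe stimulus.
    """
    G = np.asarray(weights, dtype=float)
    rho_y = float(G @ np.asarray(probe_rho_x, dtype=float))
    avg = rho_y**2
    return BCMState(G, slide_theta(avg, params), avg)


def equilibrium_rate(params: BCMParams) -> float:
    """Rate at which theta equals rho_y when <rho_y^2> = rho_y^2.

    Solving theta(rho_y^2) = rho_y gives
    rho_eq = rho0^2 A3+ tau+ tau_y / (A2- tau- - A2+ tau+): the attractor
    of the postsynaptic rate under a single sustained stimulus.
    """
    return params.rho0**2 * params.a3p_tp_ty / (params.a2m_tm - params.a2p_tp)
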