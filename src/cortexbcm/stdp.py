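"""Pair- and triplet-STDP kernels with All-to-All accumulation.

Spike-timing-dependent plasticity is modelled in the detector (trace)
formulation: each presynaptic spike increments two presynaptic traces
r1, r2 (decaying with tau_plus, tau_x) and each postsynaptic spike two
postsynaptic traces o1, o2 (tau_minus, tau_y).  Weight updates are

    on a pre spike:   w <- w - eff * o1 * (A2_minus + A3_minus * r2-)
    on a post spike:  w <- w + eff * r1 * (A2_plus  + A3_plus  * o2-)

where the minus superscript denotes the trace value just before that
spike's own increment.  Because the traces persist across all previous
spikes, this realizes the All-to-All accumulation scheme: every spike
interacts with the full spike history, which is what lets the triplet rule
reproduce the rate (BCM) limit.

``eff`` implements first-spike-dominating suppression: each spike's
efficacy is reduced by the proximity of the preceding spike on the same
side, eff = 1 - exp(-dt_prev / tau_supp), with the first spike of a train
at full efficacy.  With tau_supp = 0 suppression is inert and, with
A3 = 0, the model reduces exactly to pair-STDP exponential kernels.

For independent Poisson pre/post trains the expected drift is the
closed-form quadratic in the firing rates (see :func:`expected_drift`),
which is the bridge to the rate-based BCM engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .device import relaxation_offset
from .stimuli import SpikeTrain

__all__ = [
    "TripletParams",
    "SpikeTriplet",
    "WeightTrace",
    "pair_stdp_dw",
    "triplet_apply",
    "triplet_sequence",
    "quadrant_map",
    "expected_drift",
    "fit_triplet_params",
    "ORDERINGS",
]

ORDERINGS = (
    "post-pre-post",
    "pre-post-pre",
    "pre-pre-post",
    "pre-post-post",
    "post-post-pre",
    "post-pre-pre",
)


@dataclass(frozen=True)
class TripletParams:
    """Amplitudes and time constants of the pair/triplet kernels.

    Times in ms; amplitudes in dimensionless weight units per event.  The
    time-constant defaults are the canonical triplet-model values for
    visual-cortex data (tau_plus 16.8 ms, tau_minus 33.7 ms, tau_x 101 ms,
    tau_y 125 ms); the amplitudes are this package's documented defaults,
    chosen to satisfy the threshold-positivity constraint
    A2_minus*tau_minus > A2_plus*tau_plus required for a positive sliding
    threshold, and to reproduce the qualitative triplet quadrant structure.
    """

    A2_plus: float = 3.0e-3
    A2_minus: float = 1.05e-2
    A3_plus: float = 6.2e-3
    A3_minus: float = 1.0e-4
    tau_plus: float = 16.8
    tau_minus: float = 33.7
    tau_x: float = 101.0
    tau_y: float = 125.0
    tau_supp: float = 30.0

    def __post_init__(self) -> None:
        for name in ("tau_plus", "tau_minus", "tau_x", "tau_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_supp < 0:
            raise ValueError("tau_supp must be non-negative (0 disables suppression)")
        for name in ("A2_plus", "A2_minus", "A3_plus", "A3_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.A2_minus * self.tau_minus <= self.A2_plus * self.tau_plus:
            raise ValueError(
                "need A2_minus*tau_minus > A2_plus*tau_plus "
                "(positivity of the sliding threshold)"
            )


@dataclass(frozen=True)
class SpikeTriplet:
    """A three-spike sequence defined by its ordering and two lags (ms).

    Sign conventions per ordering follow the pairwise decomposition: for
    'post-pre-post', dt1 = t_post1 - t_pre < 0 and dt2 = t_post2 - t_pre
    > 0; for 'pre-post-pre', dt1 = t_post - t_pre1 > 0 and
    dt2 = t_post - t_pre2 < 0; the four one-sided orderings carry two lags
    of equal sign.
    """

    ordering: str
    dt1: float
    dt2: float

    def __post_init__(self) -> None:
        if self.ordering not in ORDERINGS:
            raise ValueError(f"unknown ordering {self.ordering!r}")
        s1, s2 = np.sign(self.dt1), np.sign(self.dt2)
        expected = {
            "post-pre-post": (-1, 1),
            "pre-post-pre": (1, -1),
            "pre-pre-post": (1, 1),
            "pre-post-post": (1, 1),
            "post-post-pre": (-1, -1),
            "post-pre-pre": (-1, -1),
        }[self.ordering]
        if (s1, s2) != expected:
            raise ValueError(
                f"lag signs ({s1:+.0f}, {s2:+.0f}) inconsistent with "
                f"ordering {self.ordering!r} (expected {expected})"
            )


# ---------------------------------------------------------------------------
# pair STDP with device-state-dependent decay offset
# ---------------------------------------------------------------------------

def pair_stdp_dw(
    dt: float,
    G0: float,
    params: TripletParams | None = None,
    device_decay=relaxation_offset,
) -> float:
    """History-dependent pair-STDP weight change for a single pre/post pair.

    The pure exponential kernel is offset by the device's state-dependent
    relaxation D(G0, |dt|) (monotone in both arguments), which is what
    flips potentiation into depression at long lags in high history states.
    """
    if dt == 0:
        raise ValueError("dt = 0 (simultaneous spikes) is undefined")
    params = params or TripletParams()
    if dt > 0:
        kernel = params.A2_plus * float(np.exp(-dt / params.tau_plus))
    else:
        kernel = -params.A2_minus * float(np.exp(dt / params.tau_minus))
    return kernel - device_decay(G0, abs(dt))


# ---------------------------------------------------------------------------
# triplet model, All-to-All, with suppression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightTrace:
    """Cumulative weight change evaluated at every spike event."""

    times: np.ndarray
    dw: np.ndarray

    @property
    def total(self) -> float:
        return float(self.dw[-1]) if self.dw.size else 0.0


def triplet_apply(
    pre_train: SpikeTrain | np.ndarray,
    post_train: SpikeTrain | np.ndarray,
    params: TripletParams | None = None,
) -> WeightTrace:
    """Run the triplet detector model over a pre/post spike-train pair.

    Simultaneous pre and post spikes are rejected (the update order would
    be arbitrary).  Returns the cumulative weight-change trace.
    """
    params = params or TripletParams()
    pre = np.asarray(getattr(pre_train, "times", pre_train), dtype=float)
    post = np.asarray(getattr(post_train, "times", post_train), dtype=float)
    if np.intersect1d(pre, post).size:
        raise ValueError("simultaneous pre and post spikes are not supported")

    events = np.concatenate([pre, post])
    sides = np.concatenate([np.zeros(pre.size, int), np.ones(post.size, int)])
    order = np.argsort(events, kind="stable")
    events, sides = events[order], sides[order]

    r1 = r2 = o1 = o2 = 0.0
    t_last = None
    t_prev_side = [None, None]  # previous spike time per side (0 pre, 1 post)
    dw_cum = np.empty(events.size)
    w = 0.0
    for i, (t, side) in enumerate(zip(events, sides)):
        if t_last is not None:
            gap = t - t_last
            r1 *= np.exp(-gap / params.tau_plus)
            r2 *= np.exp(-gap / params.tau_x)
            o1 *= np.exp(-gap / params.tau_minus)
            o2 *= np.exp(-gap / params.tau_y)
        t_last = t

        prev = t_prev_side[side]
        if prev is None or params.tau_supp == 0:
            eff = 1.0
        else:
            eff = 1.0 - np.exp(-(t - prev) / params.tau_supp)
        t_prev_side[side] = t

        if side == 0:  # presynaptic spike: depression, then bump pre traces
            w -= eff * o1 * (params.A2_minus + params.A3_minus * r2)
            r1 += 1.0
            r2 += 1.0
        else:  # postsynaptic spike: potentiation, then bump post traces
            w += eff * r1 * (params.A2_plus + params.A3_plus * o2)
            o1 += 1.0
            o2 += 1.0
        dw_cum[i] = w
    return WeightTrace(events, dw_cum)


def triplet_sequence(
    ordering: str, dt1: float, dt2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spike times (pre, post) realizing a named three-spike sequence."""
    trip = SpikeTriplet(ordering, dt1, dt2)  # validates signs
    o, d1, d2 = trip.ordering, trip.dt1, trip.dt2
    if o == "post-pre-post":
        pre, post = [0.0], [d1, d2]
    elif o == "pre-post-pre":
        pre, post = [-d1, -d2], [0.0]
    elif o in ("pre-pre-post", "pre-post-post"):
        # lags measured from each pre spike to the (first) post spike
        if o == "pre-pre-post":
            pre, post = [-d1, -d2], [0.0]
        else:
            pre, post = [0.0], [d1, d2]
    else:  # 'post-post-pre', 'post-pre-pre'
        if o == "post-post-pre":
            pre, post = [0.0], [d1, d2]
        else:
            pre, post = [-d1, -d2], [0.0]
    pre_t = np.sort(np.asarray(pre, float))
    post_t = np.sort(np.asarray(post, float))
    if np.unique(pre_t).size != pre_t.size or np.unique(post_t).size != post_t.size:
        raise ValueError("degenerate sequence: coincident same-side spikes")
    return pre_t, post_t


def _quadrant_ordering(dt1: float, dt2: float) -> str:
    if dt1 < 0 and dt2 > 0:
        return "post-pre-post"
    if dt1 > 0 and dt2 < 0:
        return "pre-post-pre"
    if dt1 > 0 and dt2 > 0:
        return "pre-pre-post"
    return "post-post-pre"


def quadrant_map(dt1_grid, dt2_grid, params: TripletParams | None = None):
    """Triplet weight change over the (dt1, dt2) plane.

    Quadrant conventions: II (dt1<0, dt2>0) is 'post-pre-post', IV
    (dt1>0, dt2<0) is 'pre-post-pre'; I and III hold the one-sided
    sequences ('pre-pre-post', 'post-post-pre').  Returns (dG, orderings)
    arrays of shape (len(dt1_grid), len(dt2_grid)); entries whose two lags
    would place same-side spikes at the same instant are NaN.
    """
    params = params or TripletParams()
    d1s = np.asarray(dt1_grid, dtype=float)
    d2s = np.asarray(dt2_grid, dtype=float)
    if np.any(d1s == 0) or np.any(d2s == 0):
        raise ValueError("grids must exclude 0")
    dG = np.full((d1s.size, d2s.size), np.nan)
    orderings = np.empty((d1s.size, d2s.size), dtype=object)
    for i, d1 in enumerate(d1s):
        for j, d2 in enumerate(d2s):
            ordering = _quadrant_ordering(d1, d2)
            orderings[i, j] = ordering
            try:
                pre_t, post_t = triplet_sequence(ordering, d1, d2)
            except ValueError:
                continue
            dG[i, j] = triplet_apply(pre_t, post_t, params).total
    return dG, orderings


# ---------------------------------------------------------------------------
# rate-based expectation (All-to-All closed form)
# ---------------------------------------------------------------------------

def expected_drift(
    rho_x: float, rho_y: float, params: TripletParams | None = None
) -> float:
    """Expected dw/dt (per second) for independent Poisson trains.

    All-to-All expectation of the triplet rule (suppression inert):

        dw/dt = (-A2- tau- rho_y - A3- tau- tau_x rho_x rho_y
                 + A2+ tau+ rho_y + A3+ tau+ tau_y rho_y^2) * rho_x

    with rates in Hz and time constants in ms (converted internally).
    """
    params = params or TripletParams()
    rx, ry = rho_x / 1000.0, rho_y / 1000.0  # spikes per ms
    drift_per_ms = (
        -params.A2_minus * params.tau_minus * ry
        - params.A3_minus * params.tau_minus * params.tau_x * rx * ry
        + params.A2_plus * params.tau_plus * ry
        + params.A3_plus * params.tau_plus * params.tau_y * ry**2
    ) * rx
    return drift_per_ms * 1000.0


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

_FIT_FIELDS = (
    "A2_plus", "A2_minus", "A3_plus", "A3_minus",
    "tau_plus", "tau_minus", "tau_x", "tau_y",
)


def fit_triplet_params(
    observations,
    start: TripletParams | None = None,
    tau_supp: float | None = None,
) -> TripletParams:
    """Least-squares fit of the 8 kernel parameters to triplet data.

    ``observations`` is a sequence of ((ordering, dt1, dt2), dG) pairs and
    must contain at least 8 entries covering both typical-triplet quadrants
    (II: 'post-pre-post' and IV: 'pre-post-pre'); otherwise the problem is
    rejected as underdetermined.  Parameters are fitted in log space
    (positivity built in) within a broad box around the starting values,
    minimizing relative residuals (the natural choice for weight changes
    measured with multiplicative error).  A fitted set violating the
    threshold-positivity constraint is returned as-is with a warning.
    """
    obs = list(observations)
    orderings = {o for (o, _, _), _ in obs}
    missing = {"post-pre-post", "pre-post-pre"} - orderings
    if len(obs) < 8 or missing:
        raise ValueError(
            "underdetermined fit: need >= 8 observations covering quadrants II "
            f"and IV; got {len(obs)} observations, missing orderings: "
            f"{sorted(missing) if missing else 'none'}"
        )
    start = start or TripletParams()
    supp = start.tau_supp if tau_supp is None else tau_supp
    x0 = np.log([getattr(start, f) for f in _FIT_FIELDS])

    sequences = [triplet_sequence(o, d1, d2) for (o, d1, d2), _ in obs]
    targets = np.array([dg for _, dg in obs], dtype=float)
    scale = np.maximum(np.abs(targets), 1e-5)

    def residuals(logx):
        vals = dict(zip(_FIT_FIELDS, np.exp(logx)))
        p = _unchecked_params(tau_supp=supp, **vals)
        pred = np.array(
            [triplet_apply(pre, post, p).total for pre, post in sequences]
        )
        return (pred - targets) / scale

    sol = optimize.least_squares(
        residuals, x0, bounds=(x0 - np.log(50.0), x0 + np.log(50.0)),
        max_nfev=5000,
    )
    vals = dict(zip(_FIT_FIELDS, np.exp(sol.x)))
    if vals["A2_minus"] * vals["tau_minus"] <= vals["A2_plus"] * vals["tau_plus"]:
        warnings.warn(
            "fitted parameters violate A2_minus*tau_minus > A2_plus*tau_plus "
            "(the sliding threshold would not be positive)",
            UserWarning,
        )
        return _unchecked_params(tau_supp=supp, **vals)
    return TripletParams(tau_supp=supp, **vals)


def _unchecked_params(**vals) -> TripletParams:
    """TripletParams bypassing the threshold-positivity invariant check."""
    p = TripletParams.__new__(TripletParams)
    defaults = dict(
        A2_plus=3.0e-3, A2_minus=1.05e-2, A3_plus=6.2e-3, A3_minus=1.0e-4,
        tau_plus=16.8, tau_minus=33.7, tau_x=101.0, tau_y=125.0, tau_supp=30.0,
    )
    defaults.update(vals)
    for k, v in defaults.items():
        object.__setattr__(p, k, float(v))
    return p
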