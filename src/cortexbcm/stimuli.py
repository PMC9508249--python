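"""Synthetic optical front end: rate-coded pattern maps and Poisson spike trains.

The hardware this package models drives each synapse with optical pulse
trains: a pattern is a grid of Poisson rates (high-rate pixels on the
figure, low-rate pixels on the background), each pixel emits a homogeneous
Poisson train, and a miniature solar cell converts every optical pulse into
a voltage pulse of fixed amplitude (open-circuit voltage ~1 V at
100 mW/cm^2).  This module generates all three stages synthetically.

Conventions
-----------
* Grids are square (3x3 or 9x9), stored row-major; pixel ids in reports are
  1-based row-major so that the centre pixel of a 3x3 grid is "5".
* Bars are one pixel wide through the centre: 0 deg = centre row,
  90 deg = centre column, 45 deg = main diagonal, 135 deg = anti-diagonal.
* All randomness flows from an integer seed through
  :func:`numpy.random.default_rng`; a root seed fans out per-pixel child
  seeds deterministically via ``spawn_seeds``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateMap",
    "SpikeTrain",
    "VoltagePulseTrain",
    "make_orientation_pattern",
    "make_cross_pattern",
    "make_noise_pattern",
    "poisson_train",
    "phototransduce",
    "rate_map_trains",
    "spawn_seeds",
    "voc_log",
]

SUPPORTED_ANGLES = (0, 45, 90, 135)

#: Irradiance (mW/cm^2) at which the solar cell delivers its nominal 1 V pulse.
NOMINAL_IRRADIANCE = 100.0
NOMINAL_VOC = 1.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateMap:
    """A 2-D grid of Poisson rates (Hz) with a pattern label."""

    grid: np.ndarray
    label: str

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
            raise ValueError(f"rate map must be a square 2-D grid, got shape {grid.shape}")
        if np.any(grid < 0):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "grid", grid)

    @property
    def size(self) -> int:
        return self.grid.shape[0]

    @property
    def rates(self) -> np.ndarray:
        """Flattened (row-major) copy of the rate grid."""
        return self.grid.ravel().copy()

    def pixel_rate(self, pixel_id: int) -> float:
        """Rate of a 1-based row-major pixel id."""
        n = self.grid.size
        if not 1 <= pixel_id <= n:
            raise ValueError(f"pixel_id must be in 1..{n}, got {pixel_id}")
        return float(self.grid.ravel()[pixel_id - 1])


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered event times (ms) within a window [0, duration]."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValueError("spike times must lie in [0, duration]")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return int(self.times.size)

    def rate(self) -> float:
        """Empirical rate in Hz."""
        return 1000.0 * len(self) / self.duration


@dataclass(frozen=True)
class VoltagePulseTrain:
    """Rectangular voltage pulses: onset times (ms), common amplitude and width."""

    times: np.ndarray
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if self.width <= 0:
            raise ValueError("pulse width must be positive")
        if times.size and self.amplitude <= 0:
            raise ValueError("optical-evoked pulses must have positive amplitude")
        if times.size > 1 and np.any(np.diff(times) < self.width):
            raise ValueError("pulses must not overlap (gap >= width)")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# pattern constructors
# ---------------------------------------------------------------------------

def _bar_indices(size: int, angle: int) -> tuple[np.ndarray, np.ndarray]:
    c = size // 2
    idx = np.arange(size)
    if angle == 0:  # horizontal: centre row
        return np.full(size, c), idx
    if angle == 90:  # vertical: centre column
        return idx, np.full(size, c)
    if angle == 45:  # main diagonal
        return idx, idx
    if angle == 135:  # anti-diagonal
        return idx, size - 1 - idx
    raise ValueError(
        f"unsupported orientation {angle!r}: must be one of {SUPPORTED_ANGLES}"
    )


def make_orientation_pattern(
    size: int, angle: int, high_rate: float, low_rate: float
) -> RateMap:
    """Width-1 oriented bar through the grid centre.

    ``size`` pixels on the bar fire at ``high_rate`` (30 Hz in the reference
    protocol), the remaining pixels at ``low_rate`` (14 Hz).
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("grid size must be odd and >= 3")
    if low_rate < 0 or high_rate < low_rate:
        raise ValueError("need high_rate >= low_rate >= 0")
    rows, cols = _bar_indices(size, angle)
    grid = np.full((size, size), float(low_rate))
    grid[rows, cols] = float(high_rate)
    return RateMap(grid, label=f"{angle}deg")


#: 1-based row-major pixel ids forming the 'X' figure on a 3x3 grid.
CROSS_PIXELS = (1, 3, 5, 7, 9)


def make_cross_pattern(high_rate: float, low_rate: float) -> RateMap:
    """3x3 'X' figure: corners and centre at ``high_rate``, edges at ``low_rate``."""
    if high_rate < 0 or low_rate < 0:
        raise ValueError("rates must be non-negative")
    grid = np.full(9, float(low_rate))
    grid[[p - 1 for p in CROSS_PIXELS]] = float(high_rate)
    return RateMap(grid.reshape(3, 3), label="X")


def make_noise_pattern(size: int, lo: float, hi: float, seed: int) -> RateMap:
    """Structureless deprivation input: i.i.d. uniform rates on [lo, hi]."""
    if lo < 0 or hi < lo:
        raise ValueError("need 0 <= lo <= hi")
    rng = np.random.default_rng(seed)
    grid = rng.uniform(lo, hi, size=(size, size))
    return RateMap(grid, label="noise")


# ---------------------------------------------------------------------------
# spike generation and transduction
# ---------------------------------------------------------------------------

def poisson_train(rate: float, duration: float, seed: int) -> SpikeTrain:
    """Homogeneous Poisson train by exponential inter-arrival sampling."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate == 0:
        return SpikeTrain(np.empty(0), duration)
    rng = np.random.default_rng(seed)
    mean_gap = 1000.0 / rate  # ms
    # draw in blocks until the window is covered
    times: list[np.ndarray] = []
    t = 0.0
    block = max(16, int(1.5 * rate * duration / 1000.0) + 16)
    while t <= duration:
        gaps = rng.exponential(mean_gap, size=block)
        cum = t + np.cumsum(gaps)
        times.append(cum)
        t = cum[-1]
    all_times = np.concatenate(times)
    return SpikeTrain(all_times[all_times <= duration], duration)


def voc_log(irradiance: float) -> float:
    """Monotone open-circuit-voltage map, pinned to 1 V at 100 mW/cm^2.

    Uses the logarithmic Voc-irradiance dependence of a photovoltaic cell,
    Voc(E) = a * ln(1 + E), with a chosen so Voc(100) = 1.0 V.
    """
    if irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    a = NOMINAL_VOC / math.log1p(NOMINAL_IRRADIANCE)
    return a * math.log1p(irradiance)


def phototransduce(
    train: SpikeTrain,
    irradiance: float = NOMINAL_IRRADIANCE,
    pulse_width: float = 5.0,
    voc_map=voc_log,
) -> VoltagePulseTrain:
    """Convert an optical spike train into solar-cell voltage pulses.

    One rectangular pulse per optical spike, all at amplitude
    ``voc_map(irradiance)``.  Pulses closer than ``pulse_width`` are merged
    into the earlier pulse (the cell cannot re-fire while still held high);
    at zero irradiance the output is empty.
    """
    if irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    amplitude = float(voc_map(irradiance))
    if amplitude <= 0 or len(train) == 0:
        return VoltagePulseTrain(np.empty(0), amplitude=amplitude, width=pulse_width)
    kept = [float(train.times[0])]
    for t in train.times[1:]:
        if t - kept[-1] >= pulse_width:
            kept.append(float(t))
    return VoltagePulseTrain(np.asarray(kept), amplitude=amplitude, width=pulse_width)


# ---------------------------------------------------------------------------
# seeding helpers
# ---------------------------------------------------------------------------

def spawn_seeds(root_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent child seeds from one root seed.

    Deterministic: the same root always yields the same children.  Children
    are drawn below 2**31 so they remain valid seeds everywhere.
    """
    rng = np.random.default_rng(root_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def rate_map_trains(
    ratemap: RateMap, duration: float, seed: int
) -> list[SpikeTrain]:
    """One Poisson train per pixel (row-major order), seeded from one root."""
    rates = ratemap.rates
    seeds = spawn_seeds(seed, rates.size)
    return [poisson_train(r, duration, int(s)) for r, s in zip(rates, seeds)]
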