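"""Synthetic saccade-register generator.

Emulates the class-conditional structure of EOG saccade registers in SCA2
screening without any recorded data:

* **control (C)** registers hold clean, fast step-like transitions;
* **sick (S)** registers hold slowed, deformed transitions with tremor;
* **presymptomatic (P)** registers are *mixtures*: mostly control-like
  saccades with a minority of sick-like ones, which is exactly the ambiguity
  the uncertainty pipeline is designed to resolve.

A saccade is modelled as an endpoint-normalized sigmoid transition between
gaze levels -0.45·d and +0.45·d (d = ±1), plus a damped post-transition
oscillation (overshoot ringing), a low-amplitude sinusoidal tremor, and
Gaussian sensor noise, clipped to the admissible range [-0.5, 0.5].

Register sizes are drawn from per-class truncated normals whose default
mean / sd / min / max match the summary statistics of the 85-register SCA2
screening cohort: C (78.3, 21.6, 38, 169), P (76.7, 25, 28, 172),
S (54, 49, 6, 172).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import (
    AMPLITUDE_BOUND,
    SACCADE_LENGTH,
    ClassLabel,
    DataSet,
    Register,
    write_register_file,
)

__all__ = [
    "SaccadeShapeParams",
    "ShapeRanges",
    "ClassGeneratorConfig",
    "generate_saccade",
    "generate_register",
    "generate_dataset",
    "write_dataset",
    "save_config",
]

_PLATEAU = 0.45  # clean-signal gaze level; leaves headroom for noise within +-0.5


@dataclass(frozen=True)
class SaccadeShapeParams:
    """Waveform parameters of a single synthetic saccade.

    transition_width is the sigmoid time constant in samples: small values
    give the crisp transition of a healthy saccade, large values the slowed
    ramp of an ataxic one.
    """

    transition_center: float = 96.0
    transition_width: float = 3.0
    overshoot_amplitude: float = 0.0
    tremor_amplitude: float = 0.0
    noise_sd: float = 0.0
    direction: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.transition_center < SACCADE_LENGTH):
            raise ValueError("transition_center must lie inside (0, 192)")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if self.noise_sd < 0 or self.tremor_amplitude < 0 or self.overshoot_amplitude < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class ShapeRanges:
    """Uniform sampling ranges for SaccadeShapeParams, one set per class."""

    transition_center: tuple[float, float] = (70.0, 120.0)
    transition_width: tuple[float, float] = (1.5, 4.0)
    overshoot_amplitude: tuple[float, float] = (0.0, 0.05)
    tremor_amplitude: tuple[float, float] = (0.0, 0.01)
    noise_sd: tuple[float, float] = (0.005, 0.015)

    def sample(self, rng: np.random.Generator) -> SaccadeShapeParams:
        def u(lo_hi):
            return float(rng.uniform(*lo_hi))

        return SaccadeShapeParams(
            transition_center=u(self.transition_center),
            transition_width=u(self.transition_width),
            overshoot_amplitude=u(self.overshoot_amplitude),
            tremor_amplitude=u(self.tremor_amplitude),
            noise_sd=u(self.noise_sd),
            direction=1 if rng.random() < 0.5 else -1,
        )


_CONTROL_SHAPE = ShapeRanges()
_SICK_SHAPE = ShapeRanges(
    transition_width=(18.0, 45.0),
    overshoot_amplitude=(0.0, 0.02),
    tremor_amplitude=(0.01, 0.04),
    noise_sd=(0.01, 0.03),
)


@dataclass(frozen=True)
class ClassGeneratorConfig:
    """Per-class waveform and register-size law.

    ``register_size_mean_sd`` and ``register_size_bounds`` default to the
    cohort summary statistics (see module docstring).  In a presymptomatic
    register each saccade is sick-like with probability f, where f is drawn
    once per register from ``presym_sick_fraction_range``; the default
    (0.2, 0.5) reflects observed presymptomatic registers in which roughly a
    fifth to a half of the saccades behave pathologically.
    """

    control_shape: ShapeRanges = _CONTROL_SHAPE
    sick_shape: ShapeRanges = _SICK_SHAPE
    presym_sick_fraction_range: tuple[float, float] = (0.2, 0.5)
    register_size_mean_sd: dict = field(
        default_factory=lambda: {"C": (78.3, 21.6), "P": (76.7, 25.0), "S": (54.0, 49.0)}
    )
    register_size_bounds: dict = field(
        default_factory=lambda: {"C": (38, 169), "P": (28, 172), "S": (6, 172)}
    )

    def __post_init__(self) -> None:
        lo, hi = self.presym_sick_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("presym_sick_fraction_range must be within [0, 1]")
        for name in ClassLabel:
            mn, mx = self.register_size_bounds[name.name]
            if mn > mx:
                raise ValueError(f"register_size_bounds for {name.name}: min > max")
            if mn < 1:
                raise ValueError("register sizes must be at least 1")


def generate_saccade(shape: SaccadeShapeParams, rng: np.random.Generator) -> np.ndarray:
    """Render one 192-sample saccade from its waveform parameters."""
    t = np.arange(SACCADE_LENGTH, dtype=np.float64)
    c, w, d = shape.transition_center, shape.transition_width, shape.direction

    # endpoint-normalized logistic transition: exactly +-plateau at t=0, 191
    s = 1.0 / (1.0 + np.exp(-(t - c) / w))
    s0 = 1.0 / (1.0 + np.exp(c / w))
    s1 = 1.0 / (1.0 + np.exp(-(SACCADE_LENGTH - 1 - c) / w))
    x = d * (-_PLATEAU + 2 * _PLATEAU * (s - s0) / (s1 - s0))

    if shape.overshoot_amplitude > 0:
        dt = np.maximum(t - c, 0.0)
        ringing = np.exp(-dt / 12.0) * np.sin(2 * np.pi * dt / 16.0)
        ringing[t <= c] = 0.0
        x = x + d * shape.overshoot_amplitude * ringing
    if shape.tremor_amplitude > 0:
        period = rng.uniform(6.0, 15.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        x = x + shape.tremor_amplitude * np.sin(2 * np.pi * t / period + phase)
    if shape.noise_sd > 0:
        x = x + rng.normal(0.0, shape.noise_sd, SACCADE_LENGTH)
    return np.clip(x, -AMPLITUDE_BOUND, AMPLITUDE_BOUND)


def _truncated_normal_int(rng: np.random.Generator, mean: float, sd: float,
                          bounds: tuple[int, int], max_tries: int = 10_000) -> int:
    """Integer register size: resample a normal until it lands in bounds."""
    lo, hi = bounds
    for _ in range(max_tries):
        n = int(round(rng.normal(mean, sd)))
        if lo <= n <= hi:
            return n
    raise RuntimeError(
        f"could not draw a size in [{lo}, {hi}] from N({mean}, {sd}^2); "
        "check the configuration"
    )


def generate_register(label: ClassLabel, cfg: ClassGeneratorConfig,
                      rng: np.random.Generator, register_id: str | None = None
                      ) -> Register:
    """Generate one labeled register.

    C registers draw only control-shaped saccades, S registers only
    sick-shaped ones.  A P register draws a sick fraction f once, then each
    saccade independently is sick-like with probability f — so order carries
    no information and both kinds appear with probability -> 1 as the
    register grows.
    """
    label = ClassLabel(label)
    mean, sd = cfg.register_size_mean_sd[label.name]
    n = _truncated_normal_int(rng, mean, sd, cfg.register_size_bounds[label.name])
    if label == ClassLabel.C:
        sick_mask = np.zeros(n, dtype=bool)
    elif label == ClassLabel.S:
        sick_mask = np.ones(n, dtype=bool)
    else:
        f = rng.uniform(*cfg.presym_sick_fraction_range)
        sick_mask = rng.random(n) < f
    saccades = np.empty((n, SACCADE_LENGTH))
    for i in range(n):
        ranges = cfg.sick_shape if sick_mask[i] else cfg.control_shape
        saccades[i] = generate_saccade(ranges.sample(rng), rng)
    if register_id is None:
        register_id = f"{label.name}{rng.integers(0, 10**9):09d}"
    return Register(register_id, label, saccades)


def generate_dataset(n_per_class: tuple[int, int, int],
                     cfg: ClassGeneratorConfig | None = None,
                     seed: int = 0) -> DataSet:
    """Generate ``n_C + n_P + n_S`` registers, reproducible from the seed.

    Register ids encode class and index (``C000``, ``P007``, ...).
    """
    cfg = cfg or ClassGeneratorConfig()
    if any(n < 0 for n in n_per_class):
        raise ValueError("register counts must be non-negative")
    rng = np.random.default_rng(seed)
    registers = []
    for label, count in zip(ClassLabel, n_per_class):
        for i in range(count):
            registers.append(
                generate_register(label, cfg, rng, register_id=f"{label.name}{i:03d}")
            )
    return DataSet(registers)


def write_dataset(dataset: DataSet, directory) -> list[Path]:
    """Write every register as a canonical ``.reg.csv`` file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [
        write_register_file(r, directory / f"{r.register_id}.reg.csv")
        for r in dataset
    ]


def save_config(cfg: ClassGeneratorConfig, path) -> Path:
    """Serialize the generator config as a flat key=value text file."""
    path = Path(path)
    lines = []
    flat = asdict(cfg)
    for key, value in sorted(flat.items()):
        lines.append(f"{key}={value!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
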