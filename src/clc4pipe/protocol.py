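"""Voltage-step protocol description.

The standard protocol holds the cell at 0 mV and applies 10 ms test pulses
from -115 mV to +175 mV in 10 mV increments every 500 ms, sampled at 100 kHz.
Linear leak and capacitance are estimated with a P/8 scheme: eight subpulses
of one-eighth the test amplitude delivered from a -30 mV baseline.

Each recorded sweep has three segments on a common time base:

* ``pre``   -- ``pre_ms`` at the sweep's holding level (baseline),
* ``pulse`` -- ``pulse_ms`` at the test (or subpulse) potential,
* ``tail``  -- ``tail_ms`` back at the holding level, where the off-gating
  capacitive current is recorded.

All voltages are in mV, times in ms, sampling rate in kHz, so ``1/sample_khz``
is the sample interval in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["ProtocolSpec"]


def _is_integer(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) < tol


@dataclass(frozen=True)
class ProtocolSpec:
    """Voltage-step protocol with P/8 leak-subtraction settings."""

    holding: float = 0.0
    v_start: float = -115.0
    v_end: float = 175.0
    v_step: float = 10.0
    pulse_ms: float = 10.0
    interval_ms: float = 500.0
    sample_khz: float = 100.0
    tail_ms: float = 20.0
    pre_ms: float = 2.0
    p8_baseline: float = -30.0
    p8_count: int = 8

    def __post_init__(self) -> None:
        if self.v_step <= 0:
            raise ValueError("v_step must be positive")
        if self.v_end < self.v_start:
            raise ValueError("v_end must be >= v_start")
        if not _is_integer((self.v_end - self.v_start) / self.v_step):
            raise ValueError(
                "(v_end - v_start) must be divisible by v_step; got "
                f"{self.v_start}..{self.v_end} by {self.v_step}"
            )
        if self.pulse_ms <= 0 or self.sample_khz <= 0:
            raise ValueError("pulse_ms and sample_khz must be positive")
        if self.tail_ms < 0 or self.pre_ms < 0:
            raise ValueError("tail_ms and pre_ms must be non-negative")
        for name in ("pulse_ms", "tail_ms", "pre_ms"):
            if not _is_integer(getattr(self, name) * self.sample_khz):
                raise ValueError(
                    f"sample_khz * {name} must give an integer sample count"
                )
        if self.p8_count < 1:
            raise ValueError("p8_count must be >= 1")

    # ------------------------------------------------------------------ grid
    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sample_khz

    @property
    def voltages(self) -> np.ndarray:
        """Test-pulse potentials in ascending order (mV)."""
        n = int(round((self.v_end - self.v_start) / self.v_step)) + 1
        return self.v_start + self.v_step * np.arange(n)

    @property
    def n_voltages(self) -> int:
        return len(self.voltages)

    @property
    def n_pre(self) -> int:
        return int(round(self.pre_ms * self.sample_khz))

    @property
    def n_pulse(self) -> int:
        return int(round(self.pulse_ms * self.sample_khz))

    @property
    def n_tail(self) -> int:
        return int(round(self.tail_ms * self.sample_khz))

    @property
    def n_samples(self) -> int:
        return self.n_pre + self.n_pulse + self.n_tail

    @property
    def pre_slice(self) -> slice:
        return slice(0, self.n_pre)

    @property
    def pulse_slice(self) -> slice:
        return slice(self.n_pre, self.n_pre + self.n_pulse)

    @property
    def tail_slice(self) -> slice:
        return slice(self.n_pre + self.n_pulse, self.n_samples)

    @property
    def time_ms(self) -> np.ndarray:
        """Sample times from sweep start (ms)."""
        return np.arange(self.n_samples) * self.dt_ms

    def p8_amplitude(self, v_test: float) -> float:
        """Subpulse amplitude for a test potential: (v_test - holding)/p8_count."""
        return (v_test - self.holding) / self.p8_count

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)
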