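"""In-memory containers for whole-cell sweep sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .protocol import ProtocolSpec

__all__ = ["GroundTruth", "Recording", "SubtractedRecording", "CohortDataset"]


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form description of a simulated cell.

    Stored alongside simulated sweeps so that every analysis stage can be
    checked against the defining formulas. All methods mirror the simulator
    exactly: a Boltzmann activation gate ``p_inf(V)``, an outward rectifier
    ``r(V)``, the steady transport current ``i_ss(V) = i_max * p_inf(V) * r(V)``
    and a gating charge ``q_off(V) = q_max * (p_inf(V) - p_inf(holding))``
    released on return to the holding potential.
    """

    v_half: float            # mV
    k_slope: float           # mV
    rect_v: float            # mV
    i_max: float             # nA, includes expression and surface factors
    q_max: float             # pC
    rho_ref: float           # pC/nA
    ref_prepulse: float      # mV
    holding: float           # mV
    cell_factor: float       # lognormal expression draw
    fluorescence: float      # a.u.
    g_leak: float            # nS
    c_m: float               # pF
    r_s: float               # MOhm
    tau_act_ms: float = 1.0
    tau_off_ms: float = 0.5

    def p_inf(self, v):
        """Steady-state activation (Boltzmann)."""
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - self.v_half)
                                   / self.k_slope))

    def rectifier(self, v):
        return 1.0 / (1.0 + np.exp(-np.asarray(v, float) / self.rect_v))

    def i_ss(self, v):
        """Steady transport current at potential v (nA)."""
        return self.i_max * self.p_inf(v) * self.rectifier(v)

    def q_off(self, v):
        """Signed off-gating charge after a prepulse to v (pC).

        Positive for depolarizing prepulses (charge returning inward at the
        holding potential), negative below the holding potential.
        """
        return self.q_max * (self.p_inf(v) - self.p_inf(self.holding))

    def nonlinear_sweep(self, protocol: ProtocolSpec, v_test: float) -> np.ndarray:
        """Noise-free nonlinear (transport + gating) current trace in pA.

        This is exactly the component that P/8 subtraction is expected to
        preserve: the linear leak and membrane-capacitance transients are
        excluded.
        """
        dt = protocol.dt_ms
        out = np.empty(protocol.n_samples)
        i_hold_pa = 1e3 * self.i_ss(protocol.holding)
        out[protocol.pre_slice] = i_hold_pa

        p0 = self.p_inf(protocol.holding)
        p_target = self.p_inf(v_test)
        t_pulse = np.arange(protocol.n_pulse) * dt
        gate = p_target + (p0 - p_target) * np.exp(-t_pulse / self.tau_act_ms)
        q_on = self.q_max * (p_target - p0)  # pC, signed
        on_gating = 1e3 * (q_on / self.tau_off_ms) * np.exp(-t_pulse / self.tau_off_ms)
        out[protocol.pulse_slice] = (
            1e3 * self.i_max * self.rectifier(v_test) * gate + on_gating
        )

        t_tail = np.arange(protocol.n_tail) * dt
        off_gating = -1e3 * (q_on / self.tau_off_ms) * np.exp(-t_tail / self.tau_off_ms)
        out[protocol.tail_slice] = i_hold_pa + off_gating
        return out


@dataclass
class Recording:
    """One cell's raw sweep set.

    ``sweeps`` holds one current trace per protocol voltage (pA, rows ordered
    as ``protocol.voltages``); ``p8_sweeps`` holds the P/8 subpulse responses,
    shaped ``(n_voltages, p8_count, n_samples)``.
    """

    protocol: ProtocolSpec
    sweeps: np.ndarray
    p8_sweeps: Optional[np.ndarray]
    fluorescence: float
    meta: dict = field(default_factory=dict)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, float)
        if self.sweeps.shape != (self.protocol.n_voltages, self.protocol.n_samples):
            raise ValueError(
                f"sweeps shape {self.sweeps.shape} does not match protocol "
                f"({self.protocol.n_voltages} voltages x "
                f"{self.protocol.n_samples} samples)"
            )
        if self.p8_sweeps is not None:
            self.p8_sweeps = np.asarray(self.p8_sweeps, float)
            expected = (self.protocol.n_voltages, self.protocol.p8_count,
                        self.protocol.n_samples)
            if self.p8_sweeps.shape != expected:
                raise ValueError(
                    f"p8_sweeps shape {self.p8_sweeps.shape} != {expected}"
                )

    @property
    def voltages(self) -> np.ndarray:
        return self.protocol.voltages


@dataclass
class SubtractedRecording(Recording):
    """A sweep set after leak/capacitance subtraction.

    Same layout as :class:`Recording`; ``subtraction`` records the method used
    (provenance). The retained ``p8_sweeps`` are the per-subpulse residuals
    about their mean, so a second subtraction pass is a no-op up to noise.
    """

    subtraction: str = "none"


@dataclass
class CohortDataset:
    """A set of simulated or imported recordings with a manifest."""

    recordings: list
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.recordings)

    def by_variant(self, name: str) -> list:
        return [r for r in self.recordings if r.meta.get("variant") == name]
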