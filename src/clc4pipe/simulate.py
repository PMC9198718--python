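"""Whole-cell recording simulator.

Generates sweep sets that emulate ClC-4 whole-cell recordings under the
standard step protocol: an outwardly rectifying, Boltzmann-activated transport
current; voltage-dependent on/off capacitive gating currents; linear leak and
membrane-capacitance transients; and Gaussian sampling noise. Per-cell
expression is a lognormal draw linked to a fluorescence readout, mimicking the
current-fluorescence scatter of eGFP-tagged transporters.

Model contract
--------------
With gate ``p_inf(V) = 1/(1 + exp(-(V - v_half)/k))`` and rectifier
``r(V) = 1/(1 + exp(-V/rect_v))``:

* steady transport current ``I_ss(V) = I_max * p_inf(V) * r(V)`` with
  ``I_max = i_max_density * expr_scale * surface_fraction * cell_factor``;
* the gate relaxes mono-exponentially (tau = 1 ms) toward ``p_inf(V)`` during
  the test pulse, so the 10 ms pulse reaches steady state;
* on return to holding, the off-gating charge
  ``Q_off(V) = Q_max * (p_inf(V) - p_inf(holding))`` flows as a single
  exponential (tau = 0.5 ms); ``Q_max`` is calibrated so that
  ``Q_off/I_ss`` at the variant's reference prepulse equals ``rho_ref``;
* pulse onset carries the charge-conservative mirror (on-gating) transient;
* during the tail the transport current sits at its holding-level steady value
  (a constant); the nonlinear tail relaxation is, by definition, the off-gating
  exponential above;
* linear leak ``g_leak * V`` and an RC transient (tau = r_s * c_m) are
  superimposed on every voltage step, and Gaussian noise of ``noise_sd`` pA is
  added to every sample.

P/8 subpulses are simulated as sampled sweeps of the *linear* subsystem (leak,
capacitance transient, noise): at the -30 mV baseline the transporter is
treated as quiescent, the same assumption the experimental P/8 procedure
makes. Subtraction therefore operates on honest sampled data but is not
contaminated by the (artificially shallow) model gate at subpulse potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .protocol import ProtocolSpec
from .recording import CohortDataset, GroundTruth, Recording
from .variants import VariantConfig

__all__ = [
    "CellPassiveSpec",
    "simulate_cell",
    "simulate_cohort",
    "TAU_ACT_MS",
    "TAU_OFF_MS",
    "EXPRESSION_SIGMA_LN",
]

TAU_ACT_MS = 1.0   # activation-gate relaxation time constant
TAU_OFF_MS = 0.5   # off-gating charge relaxation time constant
EXPRESSION_SIGMA_LN = 0.5  # lognormal sigma of per-cell expression


@dataclass(frozen=True)
class CellPassiveSpec:
    """Passive (linear) cell properties and measurement plumbing.

    These are the components the P/8 procedure is designed to cancel, kept
    small because the recordings emulate capacitance-cancelled,
    series-resistance-compensated data.
    """

    g_leak: float = 1.0       # nS
    c_m: float = 10.0         # pF
    r_s: float = 5.0          # MOhm; r_s*c_m is the RC transient tau (ms*1e-3)
    noise_sd: float = 10.0    # pA per sample
    fluor_gain: float = 100.0  # a.u. per expression unit
    fluor_bg: float = 20.0    # a.u.

    def __post_init__(self) -> None:
        for name in ("g_leak", "c_m", "r_s", "noise_sd", "fluor_gain",
                     "fluor_bg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def tau_c_ms(self) -> float:
        """Membrane-capacitance transient time constant (ms)."""
        return self.r_s * self.c_m * 1e-3  # MOhm * pF = us

    def to_dict(self) -> dict:
        return asdict(self)


def _linear_sweep(protocol: ProtocolSpec, passive: CellPassiveSpec,
                  v_base: float, v_pulse: float) -> np.ndarray:
    """Leak + RC-transient response to base -> pulse -> base steps (pA)."""
    dt = protocol.dt_ms
    out = np.empty(protocol.n_samples)
    out[protocol.pre_slice] = passive.g_leak * v_base
    out[protocol.pulse_slice] = passive.g_leak * v_pulse
    out[protocol.tail_slice] = passive.g_leak * v_base

    tau = passive.tau_c_ms
    dv = v_pulse - v_base
    if tau > 0.0 and passive.c_m > 0.0 and dv != 0.0:
        amp = passive.c_m * dv / tau  # pF*mV/ms = pA
        t_pulse = np.arange(protocol.n_pulse) * dt
        out[protocol.pulse_slice] += amp * np.exp(-t_pulse / tau)
        t_tail = np.arange(protocol.n_tail) * dt
        out[protocol.tail_slice] += -amp * np.exp(-t_tail / tau)
    return out


def simulate_cell(
    variant: VariantConfig,
    protocol: ProtocolSpec | None = None,
    passive: CellPassiveSpec | None = None,
    seed: Union[int, np.random.Generator, np.random.SeedSequence] = 0,
) -> Recording:
    """Simulate one cell's full sweep set (test sweeps + P/8 subpulses).

    The seed fixes all randomness: the lognormal expression draw and the
    per-sample Gaussian noise. Ground truth (closed-form currents, charges and
    fluorescence) is stored on the returned :class:`Recording`.
    """
    protocol = protocol or ProtocolSpec()
    passive = passive or CellPassiveSpec()
    if not isinstance(variant, VariantConfig):
        raise TypeError("variant must be a VariantConfig")
    rng = np.random.default_rng(seed)

    cell_factor = float(np.exp(rng.normal(0.0, EXPRESSION_SIGMA_LN)))
    i_max = (variant.i_max_density * variant.expr_scale
             * variant.surface_fraction * cell_factor)  # nA
    fluorescence = (passive.fluor_gain * variant.expr_scale * cell_factor
                    + passive.fluor_bg)

    gt = GroundTruth(
        v_half=variant.v_half,
        k_slope=variant.k_slope,
        rect_v=variant.rect_v,
        i_max=i_max,
        q_max=0.0,  # placeholder, replaced below
        rho_ref=variant.rho_ref,
        ref_prepulse=variant.ref_prepulse,
        holding=protocol.holding,
        cell_factor=cell_factor,
        fluorescence=fluorescence,
        g_leak=passive.g_leak,
        c_m=passive.c_m,
        r_s=passive.r_s,
        tau_act_ms=TAU_ACT_MS,
        tau_off_ms=TAU_OFF_MS,
    )
    # Calibrate Q_max so that Q_off/I_ss at the reference prepulse == rho_ref.
    dp_ref = gt.p_inf(variant.ref_prepulse) - gt.p_inf(protocol.holding)
    if abs(dp_ref) < 1e-12:
        q_max = 0.0
    else:
        q_max = (variant.rho_ref * i_max * gt.p_inf(variant.ref_prepulse)
                 * gt.rectifier(variant.ref_prepulse) / dp_ref)
    gt = GroundTruth(**{**asdict(gt), "q_max": q_max})

    voltages = protocol.voltages
    n_s = protocol.n_samples
    sweeps = np.empty((len(voltages), n_s))
    p8 = np.empty((len(voltages), protocol.p8_count, n_s))
    for i, v in enumerate(voltages):
        clean = (gt.nonlinear_sweep(protocol, v)
                 + _linear_sweep(protocol, passive, protocol.holding, v))
        sweeps[i] = clean
        sub_amp = protocol.p8_amplitude(v)
        sub = _linear_sweep(protocol, passive, protocol.p8_baseline,
                            protocol.p8_baseline + sub_amp)
        p8[i] = sub[None, :]
    if passive.noise_sd > 0:
        sweeps += rng.normal(0.0, passive.noise_sd, sweeps.shape)
        p8 += rng.normal(0.0, passive.noise_sd, p8.shape)

    meta = {
        "variant": variant.name,
        "ref_prepulse": variant.ref_prepulse,
        "v_half_true": variant.v_half,
        "k_slope_true": variant.k_slope,
        "rho_ref_true": variant.rho_ref,
    }
    return Recording(
        protocol=protocol,
        sweeps=sweeps,
        p8_sweeps=p8,
        fluorescence=fluorescence,
        meta=meta,
        ground_truth=gt,
    )


def simulate_cohort(
    variants: Sequence[VariantConfig],
    n_cells_per_variant: int,
    protocol: ProtocolSpec | None = None,
    passive: CellPassiveSpec | None = None,
    seed: int = 0,
) -> CohortDataset:
    """Simulate ``n_cells_per_variant`` cells for each variant.

    Deterministic given ``seed``: per-cell seeds are spawned from a single
    :class:`numpy.random.SeedSequence`, so the same seed reproduces the cohort
    byte-for-byte and different seeds share ground-truth parameters but have
    independent expression/noise realizations.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("variants list must not be empty")
    if n_cells_per_variant < 1:
        raise ValueError("n_cells_per_variant must be >= 1")
    protocol = protocol or ProtocolSpec()
    passive = passive or CellPassiveSpec()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(variants) * n_cells_per_variant)
    recordings = []
    rows = []
    idx = 0
    for variant in variants:
        for j in range(n_cells_per_variant):
            cell_id = f"{variant.name}_{j:03d}"
            rec = simulate_cell(variant, protocol, passive, seed=children[idx])
            rec.meta["cell_id"] = cell_id
            recordings.append(rec)
            gt = rec.ground_truth
            rows.append({
                "cell_id": cell_id,
                "variant": variant.name,
                "fluorescence": rec.fluorescence,
                "v_half_true": gt.v_half,
                "k_slope_true": gt.k_slope,
                "rho_ref_true": gt.rho_ref,
                "ref_prepulse": gt.ref_prepulse,
                "i_max_true": gt.i_max,
                "q_max_true": gt.q_max,
                "cell_factor": gt.cell_factor,
            })
            idx += 1
    manifest = pd.DataFrame(rows)
    return CohortDataset(recordings=recordings, manifest=manifest)
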