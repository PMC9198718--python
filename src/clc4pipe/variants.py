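"""Ground-truth transporter configurations for the simulator.

Each :class:`VariantConfig` describes one ClC-4 variant as seen by the
phenomenological whole-cell model: a Boltzmann-activated, outwardly rectifying
transport current coupled to an off-gating charge.

The activation midpoints (``v_half``) of the measurable variants are the
published values for disease-associated ClC-4 variants; the Boltzmann slope is
not published, so a typical CLC gating-charge slope of 25 mV is used for every
variant. The Q_off/current ratios (``rho_ref``) are *designed* values that
respect the published rank ordering (V275M, G544R and R718W raise the ratio;
the chimeric V212G and L221V raise it relative to the chimeric WT) -- no
numeric ratios are published.

Two families are provided: full-length transporters, whose reference prepulse
for the Q_off/current ratio is +135 mV, and chimeras carrying the ClC-3
inter-CBS linker, which traffic to the surface membrane about twice as
efficiently and whose reference prepulse is +95 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

__all__ = [
    "VariantConfig",
    "full_length_variants",
    "chimera_variants",
    "get_variant",
]


@dataclass(frozen=True)
class VariantConfig:
    """Ground-truth parameters of one transporter variant.

    Parameters
    ----------
    name
        Variant label (e.g. ``"WT"`` or ``"V275M"``).
    v_half
        Boltzmann midpoint of the gating-charge activation curve (mV).
    k_slope
        Boltzmann slope factor (mV), > 0.
    rho_ref
        Designed Q_off / steady-current ratio at the reference prepulse
        (pC/nA).
    i_max_density
        Maximal steady transport current per unit expression at full surface
        insertion (nA per expression unit).
    expr_scale
        Relative expression level (dimensionless, > 0).
    surface_fraction
        Fraction of expressed transporters residing in the plasma membrane
        (0..1).
    rect_v
        Softness of the outward rectification of the unitary current (mV).
    ref_prepulse
        Prepulse potential at which rho_ref is defined (mV): +135 for
        full-length constructs, +95 for linker chimeras.
    """

    name: str
    v_half: float
    k_slope: float = 25.0
    rho_ref: float = 0.30
    i_max_density: float = 35.0
    expr_scale: float = 1.0
    surface_fraction: float = 0.10
    rect_v: float = 35.0
    ref_prepulse: float = 135.0

    def __post_init__(self) -> None:
        if self.k_slope <= 0:
            raise ValueError("k_slope must be positive")
        if self.rho_ref <= 0:
            raise ValueError("rho_ref must be positive")
        if not 0.0 <= self.surface_fraction <= 1.0:
            raise ValueError("surface_fraction must lie in [0, 1]")
        if self.expr_scale <= 0:
            raise ValueError("expr_scale must be positive")
        if self.rect_v <= 0:
            raise ValueError("rect_v must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VariantConfig":
        return cls(**d)


def full_length_variants() -> dict[str, VariantConfig]:
    """Built-in table of full-length ClC-4 variants (WT + 12 mutants).

    Midpoints follow the published per-variant values; variants whose
    activation was not measurable (loss-of-function: currents at background)
    keep the WT midpoint but have their surface density set so low that the
    analysis flags them as undefined, as in the experiments.
    """
    wt = VariantConfig("WT", v_half=75.0, rho_ref=0.30)
    table = {
        "WT": wt,
        "D15N": replace(wt, name="D15N", v_half=77.0, rho_ref=0.32,
                        surface_fraction=0.09),
        "G78S": replace(wt, name="G78S", v_half=75.0, surface_fraction=0.015),
        "V212G": replace(wt, name="V212G", v_half=75.0, surface_fraction=0.015),
        "L221P": replace(wt, name="L221P", v_half=75.0, surface_fraction=0.0005),
        "L221V": replace(wt, name="L221V", v_half=75.0, surface_fraction=0.0005),
        "V275M": replace(wt, name="V275M", v_half=64.0, rho_ref=0.55),
        "S534L": replace(wt, name="S534L", v_half=75.0, surface_fraction=0.0005),
        "V536M": replace(wt, name="V536M", v_half=112.0, rho_ref=0.35,
                         surface_fraction=0.08),
        "G544R": replace(wt, name="G544R", v_half=89.2, rho_ref=0.60,
                         surface_fraction=0.06),
        "A555V": replace(wt, name="A555V", v_half=75.0, surface_fraction=0.02),
        "R718W": replace(wt, name="R718W", v_half=80.0, rho_ref=0.55,
                         surface_fraction=0.07),
        "G731R": replace(wt, name="G731R", v_half=70.0, surface_fraction=0.02),
    }
    return table


def chimera_variants() -> dict[str, VariantConfig]:
    """Built-in table of ClC-4 linker-chimera constructs.

    The ClC-3 inter-CBS linker removes an ER-retention signal, doubling
    surface insertion relative to full-length WT; the reference prepulse for
    the Q_off/current ratio is +95 mV.
    """
    wt = VariantConfig("WT_chimera", v_half=72.0, rho_ref=0.30,
                       surface_fraction=0.20, ref_prepulse=95.0)
    table = {
        "WT_chimera": wt,
        "G78S_chimera": replace(wt, name="G78S_chimera",
                                surface_fraction=0.0005),
        "V212G_chimera": replace(wt, name="V212G_chimera", v_half=51.2,
                                 rho_ref=0.50),
        "L221P_chimera": replace(wt, name="L221P_chimera",
                                 surface_fraction=0.0005),
        "L221V_chimera": replace(wt, name="L221V_chimera", v_half=27.8,
                                 rho_ref=0.50),
        "S534L_chimera": replace(wt, name="S534L_chimera",
                                 surface_fraction=0.0005),
        "G731R_chimera": replace(wt, name="G731R_chimera", v_half=70.0),
    }
    return table


def get_variant(name: str) -> VariantConfig:
    """Look up a built-in variant by name (full-length or chimera)."""
    tables = {**full_length_variants(), **chimera_variants()}
    try:
        return tables[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; known: {sorted(tables)}"
        ) from None
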