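"""Electrostatic sequestration arithmetic for a polybasic lipid-binding domain.

Three small calculations: the depth of the binding energy well implied by a
dissociation constant (dG = RT ln(C0/Kd) against the 1 mol/L standard state),
the Boltzmann local-concentration enhancement exp(dG/RT) = C0/Kd that the
well produces, and a diffusion-limited encounter-time estimate for a lipid
performing a two-dimensional random walk toward sparse membrane channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GAS_CONSTANT_KCAL

__all__ = [
    "EnergyWell",
    "EncounterParams",
    "EncounterResult",
    "energy_from_kd",
    "enhancement_factor",
    "encounter_time",
]

STANDARD_STATE_UM = 1e6  # 1 mol/L in uM


@dataclass(frozen=True)
class EnergyWell:
    """Binding energy well: Kd (uM), temperature (K), depth delta_G (kcal/mol)."""

    Kd: float
    temperature: float
    delta_G: float


@dataclass(frozen=True)
class EncounterParams:
    """Inputs for the 2-D diffusive capture estimate.

    channel_density : channels per um^2 (sparse traps).
    diffusion_constant : lipid diffusion constant, um^2/s.
    pip2_mole_fraction : ligand lipids per membrane lipid.
    lipid_density : lipids per um^2 of leaflet.
    capture_radius : trap radius, nm.
    """

    channel_density: float = 7.0
    diffusion_constant: float = 4.0
    pip2_mole_fraction: float = 1e-3
    lipid_density: float = 2e6
    capture_radius: float = 1.0

    def __post_init__(self) -> None:
        for name in ("channel_density", "diffusion_constant", "pip2_mole_fraction",
                     "lipid_density", "capture_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pip2_mole_fraction > 1:
            raise ValueError("pip2_mole_fraction must be <= 1")


@dataclass(frozen=True)
class EncounterResult:
    """Encounter-time estimate with all intermediate terms (lengths in um)."""

    domain_radius: float  # b: radius of the disc each channel drains
    tau_single: float  # mean capture time of one diffuser, s
    n_diffusers: float  # ligand lipids per channel domain
    tau: float  # mean first arrival of any diffuser, s


def energy_from_kd(Kd: float, T: float = 293.15) -> EnergyWell:
    """Energy-well depth dG = R T ln(1 M / Kd), kcal/mol, Kd in uM."""
    if Kd <= 0 or T <= 0:
        raise ValueError("Kd and T must be > 0")
    dg = GAS_CONSTANT_KCAL * T * np.log(STANDARD_STATE_UM / Kd)
    return EnergyWell(Kd=Kd, temperature=T, delta_G=float(dg))


def enhancement_factor(well: EnergyWell) -> float:
    """Boltzmann local-concentration enhancement exp(dG/RT) = C0/Kd."""
    return float(np.exp(well.delta_G / (GAS_CONSTANT_KCAL * well.temperature)))


def encounter_time(params: EncounterParams = EncounterParams()) -> EncounterResult:
    """Mean waiting time for any ligand lipid to reach a channel by diffusion.

    Each channel is treated as an absorbing disc of radius a (the capture
    radius) at the centre of a reflecting disc of radius b = (pi*rho_ch)^-1/2
    that tiles the membrane.  A single diffuser started uniformly in the
    domain is captured in mean time tau_1 = (b^2 / 2D) (ln(b/a) - 3/4); with
    N_p = mole_fraction * lipid_density / channel_density independent
    diffusers per domain the mean first arrival is approximately tau_1 / N_p.
    """
    a = params.capture_radius * 1e-3  # nm -> um
    b = 1.0 / np.sqrt(np.pi * params.channel_density)
    if b <= a:
        raise ValueError("capture radius must be smaller than the channel domain radius")
    tau_single = b**2 / (2.0 * params.diffusion_constant) * (np.log(b / a) - 0.75)
    n_diffusers = params.pip2_mole_fraction * params.lipid_density / params.channel_density
    return EncounterResult(
        domain_radius=float(b),
        tau_single=float(tau_single),
        n_diffusers=float(n_diffusers),
        tau=float(tau_single / n_diffusers),
    )
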