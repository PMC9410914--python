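"""Kinetically derived free-energy diagram of translation initiation.

State free energies at a reference ribosome concentration follow from the
rate constants: a binding step with equilibrium constant K_eq = k_on*C/k_off
contributes dG = -RT ln K_eq.  The fast pathway defines the transient
standby-site level; the additional drop from standby to the
cleft-accommodated state is set by the ratio of slow- to fast-pathway
equilibrium constants (concentration cancels there, so the accommodation
step — and hence the ligand-induced net unfolding penalty — is independent
of the reference concentration).
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import GAS_CONSTANT_KCAL, FreeEnergyDiagram, KineticScheme


def binding_free_energy(
    k_on: float, k_off: float, conc: float, temperature: float = 298.15
) -> float:
    """dG (kcal/mol) of a bimolecular binding step at concentration ``conc``.

    dG = -R T ln(k_on * conc / k_off); negative when the bound state is
    favored at the stated concentration.
    """
    if k_on <= 0 or k_off <= 0 or conc <= 0 or temperature <= 0:
        raise ValueError("rates, concentration and temperature must be > 0")
    return float(-GAS_CONSTANT_KCAL * temperature * np.log(k_on * conc / k_off))


def accommodation_penalty(dG_acc_minus: float, dG_acc_plus: float) -> float:
    """Net ligand-induced penalty for cleft accommodation (kcal/mol)."""
    if not (np.isfinite(dG_acc_minus) and np.isfinite(dG_acc_plus)):
        raise ValueError("inputs must be finite")
    return float(dG_acc_plus - dG_acc_minus)


def accommodation_step(scheme: KineticScheme, temperature: float = 298.15) -> float:
    """dG of the standby -> cleft-accommodated step from one scheme.

    -RT ln[(k_on,slow/k_off,slow) / (k_on,fast/k_off,fast)]; concentration
    cancels between the two pathways.
    """
    ratio = (scheme.k_on_slow / scheme.k_off_slow) / (
        scheme.k_on_fast / scheme.k_off_fast
    )
    return float(-GAS_CONSTANT_KCAL * temperature * np.log(ratio))


def build_diagram(
    rates_minus: KineticScheme,
    rates_plus: KineticScheme,
    conc: float | None = None,
    temperature: float = 298.15,
) -> FreeEnergyDiagram:
    """Free-energy diagram from fitted schemes without/with saturating ligand.

    Levels (kcal/mol, unbound = 0): standby from the fast components via
    :func:`binding_free_energy`; accommodated = standby + accommodation step
    per condition.  The net penalty is the difference of the accommodation
    steps (plus minus minus).  The standby level is reported for the
    ligand-free condition; a warning is issued if the two conditions
    disagree by more than 0.5 kcal/mol on it.
    """
    conc = conc if conc is not None else rates_minus.ribosome_conc
    standby_minus = binding_free_energy(
        rates_minus.k_on_fast, rates_minus.k_off_fast, conc, temperature
    )
    standby_plus = binding_free_energy(
        rates_plus.k_on_fast, rates_plus.k_off_fast, conc, temperature
    )
    if abs(standby_plus - standby_minus) > 0.5:
        warnings.warn(
            "standby levels differ between conditions by "
            f"{abs(standby_plus - standby_minus):.2f} kcal/mol"
        )
    acc_minus = accommodation_step(rates_minus, temperature)
    acc_plus = accommodation_step(rates_plus, temperature)
    return FreeEnergyDiagram(
        dG_standby=standby_minus,
        dG_accommodation_minus_ligand=acc_minus,
        dG_accommodation_plus_ligand=acc_plus,
        net_penalty=accommodation_penalty(acc_minus, acc_plus),
        temperature=temperature,
        reference_conc=conc,
    )


def diagram_levels(diagram: FreeEnergyDiagram) -> dict[str, dict[str, float]]:
    """Absolute state levels per condition (unbound = 0), for serialization."""
    return {
        "minus_ligand": {
            "unbound": 0.0,
            "standby": diagram.dG_standby,
            "accommodated": diagram.dG_standby
            + diagram.dG_accommodation_minus_ligand,
        },
        "plus_ligand": {
            "unbound": 0.0,
            "standby": diagram.dG_standby,
            "accommodated": diagram.dG_standby
            + diagram.dG_accommodation_plus_ligand,
        },
        "net_penalty": diagram.net_penalty,
    }
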