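"""Advective transport through the sinusoidal chain, hepatic clearance,
portal-hypertension flow scaling, and stimulus assembly.

Blood enters the lobule at the periportal compartment (index 0), flows
compartment-to-compartment at rate ``bf`` and exits the pericentral
compartment into the body compartment, which is ``s = 5·N`` times larger.
Pure advection conserves Σᵢ Mᵢ + s·M₀ exactly (telescoping mass balance);
first-order hepatic clearance applies only inside the lobule, producing the
porto-central hormone gradient.
"""

from __future__ import annotations

import numpy as np

from .params import InnervationPattern

__all__ = [
    "advection_rhs",
    "hypertensive_flow",
    "assemble_stimulus",
    "hepatic_clearance_rhs",
]


def advection_rhs(M, M0, bf, s):
    """Advection derivatives for one blood species.

    Returns ``(dM/dt vector, dM0/dt)`` with dMᵢ/dt = bf·(Mᵢ₋₁ − Mᵢ), the
    body value feeding compartment 1, and dM₀/dt = bf·(M_N − M₀)/s.
    """
    M = np.asarray(M, dtype=float)
    if M.size < 2:
        raise ValueError("need at least two compartments")
    if bf <= 0 or s <= 0:
        raise ValueError("bf and s must be > 0")
    upstream = np.concatenate(([M0], M[:-1]))
    dM = bf * (upstream - M)
    dM0 = bf * (M[-1] - M0) / s
    return dM, dM0


def hypertensive_flow(bf_normal, pressure_fold):
    """Blood flow under a portal pressure increase.

    Poiseuille's law with fixed viscosity, vessel length and radius makes
    flow proportional to the pressure differential, so a ``pressure_fold``
    rise scales ``bf`` by the same factor.
    """
    if pressure_fold < 1:
        raise ValueError("pressure_fold must be >= 1")
    return bf_normal * pressure_fold


def assemble_stimulus(Epn, NEpn, innervation: InnervationPattern, CNSAct,
                      stim_gain_cat: float = 1.0):
    """Per-cell Ca²⁺-mobilizing stimulus H (nM-equivalent).

    Every hepatocyte sees the catecholamines of its own sinusoidal
    compartment, scaled by the circulating-stimulus gain; innervated cells
    additionally receive the synaptic norepinephrine term
    K_NEpn_stim · CNSAct.
    """
    Epn = np.asarray(Epn, dtype=float)
    NEpn = np.asarray(NEpn, dtype=float)
    mask = innervation.innervated_mask
    if Epn.shape != NEpn.shape or Epn.shape[0] != mask.shape[0]:
        raise ValueError("catecholamine vectors and innervation mask lengths differ")
    H = stim_gain_cat * (Epn + NEpn)
    H = H + np.where(mask, innervation.K_NEpn_stim * CNSAct, 0.0)
    return H


def hepatic_clearance_rhs(M, k_clear):
    """First-order clearance sink, applied in hepatic compartments only."""
    M = np.asarray(M, dtype=float)
    if np.any(M < -1e-12):
        raise ValueError("concentrations must be >= 0")
    return -k_clear * M
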