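"""Ca²⁺-potentiated glycogenolysis and the zonated glycogen→glucose backbone.

Glycogen breakdown is driven by the glucagon/insulin balance through the
``K_Phos_max`` ratio, saturates in the glycogen store and intracellular
phosphate, and is potentiated up to (1 + v_CaI_max)-fold by cytosolic Ca²⁺
through glycogen phosphorylase kinase (GPK).  The G6P intermediate is
collapsed: broken-down glucosyl units feed intracellular free glucose
directly, which exchanges with the local sinusoid compartment by first-order
transport.  A per-cell zonation weight (decreasing PP→PC) imposes the
periportal bias of glycogenolytic capacity.
"""

from __future__ import annotations

import numpy as np

from .params import MetabolismParams

__all__ = [
    "gpk_activity",
    "k_phos_max",
    "glycogenolysis_rate",
    "glucose_export_flux",
]


def gpk_activity(CaI, CaI_GPK=0.44, K_CaI_GPK=3.0, v0=0.05):
    """Dimensionless glycogen-phosphorylase-kinase activity.

    Below the Ca²⁺ amplitude threshold ``CaI_GPK`` the kinase sits at its
    basal activity ``v0``; above it, activity follows first-order saturation
    CaI/(K + CaI).
    """
    CaI = np.asarray(CaI, dtype=float)
    sat = CaI / (K_CaI_GPK + CaI)
    return np.where(CaI > CaI_GPK, sat, v0)


def k_phos_max(Glu, Ins, k_LP=45.0, k_IP=26.66):
    """Glucagon/insulin control ratio (Glu + k_LP)/(Ins + k_IP).

    All four quantities must share one concentration unit (pM in the default
    parameterization); the engine converts blood hormones from nM at this
    interface.
    """
    Glu = np.asarray(Glu, dtype=float)
    Ins = np.asarray(Ins, dtype=float)
    return (Glu + k_LP) / (Ins + k_IP)


def glycogenolysis_rate(Glyc, Phos, Glu_pM, Ins_pM, CaI, zonation_weight=1.0,
                        params: MetabolismParams | None = None):
    """Glycogen breakdown flux in µM glucosyl units per second (positive =
    breakdown; dGlyc/dt is the negative of this flux in mM/s).

    Parameters
    ----------
    Glyc : glycogen store (mM glucosyl units)
    Phos : intracellular phosphate (µM)
    Glu_pM, Ins_pM : local sinusoidal glucagon and insulin (pM)
    CaI : cytosolic Ca²⁺ (µM)
    zonation_weight : per-cell multiplicative capacity weight
    """
    p = params or MetabolismParams()
    Glyc = np.asarray(Glyc, dtype=float)
    kphos = k_phos_max(Glu_pM, Ins_pM, p.k_LP, p.k_IP)
    glyc_term = Glyc**p.n_brk / (Glyc**p.n_brk + p.Km_Glyc**p.n_brk)
    phos_term = Phos / (p.Km_Phos + Phos)
    gpk = gpk_activity(CaI, p.CaI_GPK, p.gpk_hill_constant, p.v0)
    return zonation_weight * p.v_brk * kphos * glyc_term * phos_term * (1.0 + p.v_CaI_max * gpk)


def glucose_export_flux(Glucose_cell, Glucose_blood, k_export=0.1):
    """First-order hepatocyte→sinusoid glucose exchange (µM/s).

    Positive flux moves glucose from the cell into its local blood
    compartment; the exchange is symmetric, so a closed cell/compartment pair
    conserves total glucose.
    """
    return k_export * (np.asarray(Glucose_cell, dtype=float) - np.asarray(Glucose_blood, dtype=float))
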