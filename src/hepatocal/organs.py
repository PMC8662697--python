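"""Body-compartment physiology: CNS glucose sensing, pancreatic secretion,
adrenal catecholamine release, and muscle glucose uptake during exercise.

Two model variants are supported.  In the main variant the CNS drives
adrenal catecholamine synthesis multiplicatively; in the alternative variant
the adrenal medulla is denervated (constant synthesis) and the CNS instead
adds a saturating term to pancreatic glucagon secretion.
"""

from __future__ import annotations

import numpy as np

from .params import SystemicParams

__all__ = [
    "cns_activation",
    "pancreas_secretion",
    "adrenal_secretion",
    "body_glucose_consumption",
]


def cns_activation(GB, G_symp=4500.0, Km_symp=500.0):
    """Dimensionless hypothalamic activation in [0, 1).

    Saturating in the hypoglycemic deviation (G_symp − GB); identically zero
    at or above the activation threshold G_symp.
    """
    GB = np.asarray(GB, dtype=float)
    if np.any(GB < 0):
        raise ValueError("GB must be >= 0")
    dev = G_symp - GB
    act = np.where(dev > 0, dev / (Km_symp + np.abs(dev)), 0.0)
    return act if act.ndim else float(act)


def _log_deviation_hill(x, km, n):
    return x**n / (km**n + x**n)


def pancreas_secretion(GB_au, params: SystemicParams | None = None,
                       variant: str = "main", CNSAct: float = 0.0):
    """Rates of systemic glucagon and insulin secretion (nM/s).

    The pancreas senses systemic glucose in reference units (GB_au); the
    glucagon branch is active only below the reference G_ref and the insulin
    branch only above it, each a Hill function of |ln(G_ref/GB_au)|.  The
    alternative variant adds a CNS-driven saturating term to glucagon.
    """
    p = params or SystemicParams()
    if GB_au <= 0:
        raise ValueError("GB_au must be > 0")
    x = np.log(p.G_ref / GB_au)
    d_glu = 0.0
    d_ins = 0.0
    if GB_au < p.G_ref:
        d_glu = _log_deviation_hill(x, p.km_glu, p.n_glu) / p.tau_glu
        if variant == "alternative":
            d_glu += p.v_glu_alt * CNSAct / (p.km_glu_alt + CNSAct)
    elif GB_au > p.G_ref:
        d_ins = _log_deviation_hill(-x, p.km_ins, p.n_ins) / p.tau_ins
    return float(d_glu), float(d_ins)


def adrenal_secretion(CNSAct, params: SystemicParams | None = None,
                      variant: str = "main"):
    """Rates of systemic epinephrine and norepinephrine release (nM/s).

    Main variant: basal synthesis amplified (1 + X·CNSAct)-fold by CNS
    activation.  Alternative variant (adrenal denervation): constant basal
    synthesis regardless of CNS state.  Both scale with the scenario's
    adrenal amplification factor.
    """
    p = params or SystemicParams()
    if not (0 <= CNSAct < 1 + 1e-12):
        raise ValueError("CNSAct must lie in [0, 1)")
    amp = p.adrenal_amplification
    if variant == "alternative":
        return amp * p.v_Epn, amp * p.v_NEpn
    return (amp * p.v_Epn * (1.0 + p.X_Epn * CNSAct),
            amp * p.v_NEpn * (1.0 + p.X_NEpn * CNSAct))


def body_glucose_consumption(t, u_G_basal, exercise_start=500.0,
                             exercise_duration=3600.0, multiplier=3.5):
    """Body (muscle) glucose uptake rate at time ``t`` (µM/s).

    Basal outside the exercise window, ``multiplier``-fold elevated inside
    [exercise_start, exercise_start + exercise_duration).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    in_window = exercise_start <= t < exercise_start + exercise_duration
    return u_G_basal * (multiplier if in_window else 1.0)
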