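"""Per-hepatocyte Ca²⁺ spiking dynamics and gap-junction IP₃ coupling.

The oscillator couples four states per cell: the free surface-receptor
fraction ``r``, cytosolic IP₃, cytosolic Ca²⁺ ``CaI`` and the free IP₃
receptor fraction ``g``.  Catecholamine stimulus ``H`` drives receptor
occupancy, occupied receptors synthesize IP₃ with Ca²⁺-dependent positive
feedback, IP₃ gates Ca²⁺ release from the ER store, and high Ca²⁺
inactivates the IP₃ receptor, terminating each spike.  Adjacent cells
exchange only IP₃, by linear mass transfer with coefficient ``G_ij`` and
no-flux chain ends.

All functions are pure and accept scalars or (broadcastable) arrays; the
simulation engine calls them with length-N vectors.
"""

from __future__ import annotations

import numpy as np

from .params import CalciumParams, InitialConditions

# Reference constant catecholamine stimulus (nM) for an isolated mid-lobular
# hepatocyte, calibrated so sustained spiking shows inter-spike intervals of
# roughly 100 s; circulating stimuli in the full lobule model move around
# this value during simulated exercise.
CALIBRATED_STIMULUS = 4.0

__all__ = [
    "CALIBRATED_STIMULUS",
    "receptor_rhs",
    "ip3_rhs",
    "gap_junction_flux",
    "calcium_rhs",
    "ip3r_rhs",
    "single_cell_trajectory",
]


def receptor_rhs(r, H, k_r, k_d, k_Hr):
    """dr/dt for the free α₁-adrenergic receptor fraction.

    Recycling of bound receptors at rate ``k_r`` replenishes the free pool;
    hormone-independent binding (``k_d``) and mass-action hormone binding
    (``k_Hr·H``) deplete it.
    """
    r = np.asarray(r, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(r < 0) or np.any(r > 1) or np.any(H < 0):
        raise ValueError("receptor_rhs requires r in [0,1] and H >= 0")
    return k_r * (1.0 - r) - k_d * r - k_Hr * H * r


def gap_junction_flux(IP3, G_ij):
    """Net gap-junction IP₃ loss per cell: G_ij · Σ_j (IP3_i − IP3_j).

    Neighbors are the adjacent cells of the 1-D chain; cells at the chain
    ends have a single neighbor (no-flux boundaries).  Pairwise exchange
    terms are equal and opposite, so the coupling conserves total IP₃.
    """
    IP3 = np.atleast_1d(np.asarray(IP3, dtype=float))
    out = np.zeros_like(IP3)
    if IP3.size >= 2 and G_ij != 0.0:
        d = IP3[:-1] - IP3[1:]
        out[:-1] += G_ij * d
        out[1:] -= G_ij * d
    return out


def ip3_rhs(IP3, r, CaI, H, k_IP3, k_cat, k3, D, G_ij=0.0, coupling=None):
    """dIP3/dt: receptor-saturated synthesis with Ca²⁺ feedback, first-order
    degradation, and gap-junction exchange.

    The synthesis term is k_IP3·H·r/(k_cat+r) · CaI/(CaI+k3); it vanishes
    when either the Ca²⁺ feedback gate is closed (CaI = 0) or the stimulus is
    absent (H = 0).  ``coupling`` may carry a precomputed
    :func:`gap_junction_flux`; otherwise it is derived from the IP3 vector.
    """
    IP3 = np.asarray(IP3, dtype=float)
    CaI = np.asarray(CaI, dtype=float)
    if np.any(IP3 < 0) or np.any(CaI < 0) or np.any(np.asarray(H) < 0):
        raise ValueError("ip3_rhs requires non-negative concentrations")
    synth = k_IP3 * H * r / (k_cat + r) * CaI / (CaI + k3)
    if coupling is None:
        coupling = gap_junction_flux(IP3, G_ij)
    return synth - D * IP3 - coupling


def calcium_rhs(CaI, CaT, g, IP3, A, k1, L, B, k2):
    """dCaI/dt: IP₃-gated store release plus constitutive leak, against the
    SERCA pump.

    Release and leak scale with the free store content (CaT − CaI) and with
    the bound IP₃R fraction (1 − g); the pump is a second-order Hill term in
    cytosolic Ca²⁺.
    """
    CaI = np.asarray(CaI, dtype=float)
    if np.any(CaI > np.asarray(CaT) + 1e-12):
        raise ValueError("state violation: CaI exceeds total cell calcium CaT")
    release = (1.0 - g) * (A * IP3**4 / (k1 + IP3) ** 4 + L) * (CaT - CaI)
    pump = B * CaI**2 / (k2**2 + CaI**2)
    return release - pump


def ip3r_rhs(g, CaI, E, F):
    """dg/dt for the free IP₃-receptor fraction.

    Cytosolic Ca²⁺ inactivates the IP₃R at rate E·CaI⁴ acting on the bound
    fraction, against constant reactivation F.  The raw rate can drive g
    below 0 at low Ca²⁺; the integrator clamps the state at the bound (see
    the engine), so this function returns the unclamped rate.
    """
    return E * np.asarray(CaI, dtype=float) ** 4 * (1.0 - np.asarray(g, dtype=float)) - F


def _clamped_rate(value, rate, lo=0.0, hi=1.0):
    """Zero the rate where it would push ``value`` past [lo, hi]."""
    rate = np.asarray(rate, dtype=float).copy()
    value = np.asarray(value, dtype=float)
    rate[(value <= lo) & (rate < 0)] = 0.0
    rate[(value >= hi) & (rate > 0)] = 0.0
    return rate


def single_cell_trajectory(params: CalciumParams | None = None,
                           H: float = 1.0,
                           t_end: float = 2000.0,
                           cell_index: int = 7,
                           initial: InitialConditions | None = None,
                           dt_output: float = 0.5,
                           rtol: float = 1e-8,
                           atol: float = 1e-10):
    """Integrate one isolated hepatocyte under a constant stimulus.

    Uses the graded rates of ``cell_index`` (default: mid-lobular cell 8,
    zero-based index 7).  Returns ``(t, states)`` where ``states`` maps the
    names ``r``, ``IP3``, ``CaI``, ``g`` to trajectories.  With H = 0 the
    cell relaxes to a non-spiking fixed point; sufficiently strong stimuli
    produce sustained spiking.
    """
    from scipy.integrate import solve_ivp

    p = params or CalciumParams()
    ic = initial or InitialConditions()
    if H < 0:
        raise ValueError("stimulus H must be >= 0")
    k_r = float(p.k_r_i[cell_index])
    k_IP3 = float(p.k_IP3_i[cell_index])

    def rhs(t, y):
        r, IP3, CaI, g = np.clip(y[0], 0, 1), max(y[1], 0.0), max(y[2], 0.0), np.clip(y[3], 0, 1)
        dr = receptor_rhs(r, H, k_r, p.k_d, p.k_Hr)
        dIP3 = ip3_rhs(IP3, r, CaI, H, k_IP3, p.k_cat, p.k3, p.D, 0.0, coupling=0.0)
        dCaI = calcium_rhs(CaI, ic.CaT0, g, IP3, p.A, p.k1, p.L, p.B, p.k2)
        dg = ip3r_rhs(g, CaI, p.E, p.F)
        dg = float(_clamped_rate(g, dg))
        dr = float(_clamped_rate(r, dr))
        return [float(dr), float(dIP3), float(dCaI), float(dg)]

    y0 = [ic.r0, ic.IP30, ic.CaI0, ic.g0]
    t_eval = np.arange(0.0, t_end + dt_output / 2, dt_output)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"single-cell integration failed: {sol.message}")
    names = ("r", "IP3", "CaI", "g")
    return sol.t, {n: sol.y[i] for i, n in enumerate(names)}
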