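"""Assembly and integration of the coupled lobule/body ODE system.

State vector layout for a lobule of N hepatocytes (170 states at N = 15), in
integration order:

====================  ==========  =========================================
block                 slice        meaning (units)
====================  ==========  =========================================
``r``                 0:N          free surface-receptor fraction
``IP3``               N:2N         cytosolic IP3 (µM)
``CaI``               2N:3N        cytosolic Ca2+ (µM)
``g``                 3N:4N        free IP3R fraction
``Glyc``              4N:5N        glycogen store (mM glucosyl units)
``Gc``                5N:6N        intracellular free glucose (µM)
``glucose``           6N:7N        sinusoidal glucose (µM), species-major
``insulin``           7N:8N        sinusoidal insulin (nM)
``glucagon``          8N:9N        sinusoidal glucagon (nM)
``epinephrine``       9N:10N       sinusoidal epinephrine (nM)
``norepinephrine``    10N:11N      sinusoidal norepinephrine (nM)
body                  11N:11N+5    GB (µM), Ins_B, Glu_B, Epn_B, NEpn_B (nM)
====================  ==========  =========================================

The exercise step is handled exactly: integration restarts at the window
boundaries, so the uptake rate is constant within every solver segment.
Bounded states (r, g in [0,1]; concentrations ≥ 0) are kept in range by
zeroing outward rates at the bounds inside the RHS; residual excursions on
the output grid are counted and clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from . import calcium, metabolism, organs, transport
from .params import ScenarioConfig, config_hash

__all__ = ["SimulationResult", "run_scenario", "run_comparison",
           "basal_catecholamine_profile", "basal_hormone_profile"]

BLOOD_SPECIES = ("glucose", "insulin", "glucagon", "epinephrine", "norepinephrine")
CELL_STATES = ("r", "IP3", "CaI", "g", "Glyc", "Gc")
BODY_STATES = ("GB", "Ins_B", "Glu_B", "Epn_B", "NEpn_B")


class IntegrationError(RuntimeError):
    pass


class InvariantViolationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Basal steady-state profiles (used for initial conditions and calibration)
# ---------------------------------------------------------------------------

def basal_catecholamine_profile(config: ScenarioConfig):
    """Closed-form basal (CNSAct = 0) catecholamine steady state.

    With constant adrenal secretion v and first-order hepatic clearance, each
    compartment is a geometric step M_i = M0 · phi^i with
    phi = bf/(bf + k_clear), and the body level balances secretion against
    the lobular clearance throughput: M0 = v·s / (bf·(1 − phi^N)).
    Returns ``(Epn0, NEpn0, Epn_i, NEpn_i)``.
    """
    p, tr = config.systemic, config.transport
    bf, s, N = tr.bf_effective, tr.s, tr.N
    phi = bf / (bf + p.k_clear_cat)
    denom = bf * (1.0 - phi**N)
    steps = phi ** np.arange(1, N + 1)
    amp = p.adrenal_amplification
    # secretion v is lobule-referred and divided by s in the body balance,
    # so the volume ratio cancels: M0 = v / (bf (1 - phi^N))
    Epn0 = amp * p.v_Epn / denom
    NEpn0 = amp * p.v_NEpn / denom
    return Epn0, NEpn0, Epn0 * steps, NEpn0 * steps


def basal_hormone_profile(M0, k_clear, config: ScenarioConfig):
    """Steady sinusoidal gradient of a hormone held at body level ``M0``."""
    tr = config.transport
    phi = tr.bf_effective / (tr.bf_effective + k_clear)
    return M0 * phi ** np.arange(1, tr.N + 1)


# ---------------------------------------------------------------------------
# State packing
# ---------------------------------------------------------------------------

def _build_initial_state(config: ScenarioConfig) -> np.ndarray:
    N = config.transport.N
    ic = config.initial
    y0 = np.empty(11 * N + 5)
    y0[0:N] = ic.r0
    y0[N:2 * N] = ic.IP30
    y0[2 * N:3 * N] = ic.CaI0
    y0[3 * N:4 * N] = ic.g0
    y0[4 * N:5 * N] = ic.Glyc0
    y0[5 * N:6 * N] = ic.GB0          # intracellular glucose equilibrated with blood
    y0[6 * N:7 * N] = ic.GB0
    sp = config.systemic
    y0[7 * N:8 * N] = basal_hormone_profile(ic.Ins_B0, sp.k_clear_insulin, config)
    y0[8 * N:9 * N] = basal_hormone_profile(ic.Glu_B0, sp.k_clear_glucagon, config)
    Epn0, NEpn0, Epn_i, NEpn_i = basal_catecholamine_profile(config)
    if ic.Epn_B0 is not None:
        Epn0, Epn_i = ic.Epn_B0, basal_hormone_profile(ic.Epn_B0, sp.k_clear_cat, config)
    if ic.NEpn_B0 is not None:
        NEpn0, NEpn_i = ic.NEpn_B0, basal_hormone_profile(ic.NEpn_B0, sp.k_clear_cat, config)
    y0[9 * N:10 * N] = Epn_i
    y0[10 * N:11 * N] = NEpn_i
    y0[11 * N:] = [ic.GB0, ic.Ins_B0, ic.Glu_B0, Epn0, NEpn0]
    return y0


def _resolve_u_G_basal(config: ScenarioConfig, y0: np.ndarray) -> float:
    """Basal body glucose consumption balancing hepatic export at start.

    Muscle demand is a property of the body, so it is always derived from
    the normotensive resting state: a portal-hypertensive scenario keeps the
    same uptake as its normotensive counterpart rather than inheriting the
    flow-dependent shift of the basal hormone gradient.
    """
    if config.systemic.u_G_basal is not None:
        return config.systemic.u_G_basal
    if config.transport.pressure_fold != 1.0:
        import copy
        ref = copy.deepcopy(config)
        ref.transport.pressure_fold = 1.0
        return _resolve_u_G_basal(ref, _build_initial_state(ref))
    N = config.transport.N
    m = config.metabolism
    flux = metabolism.glycogenolysis_rate(
        y0[4 * N:5 * N], m.Phos,
        y0[8 * N:9 * N] * 1e3, y0[7 * N:8 * N] * 1e3,
        y0[2 * N:3 * N], m.zonation_weight_i, m)
    return float(np.sum(flux) / config.transport.s)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _make_rhs(config: ScenarioConfig, u_G: float):
    """RHS closure for one solver segment with constant uptake rate ``u_G``."""
    N = config.transport.N
    cp, mp, sp, tr = config.calcium, config.metabolism, config.systemic, config.transport
    bf, s = tr.bf_effective, tr.s
    innerv = config.innervation
    variant = config.variant
    stim_on = config.ca_stimulus_enabled
    CaT = config.initial.CaT0

    def rhs(t, y):
        r = np.clip(y[0:N], 0.0, 1.0)
        IP3 = np.maximum(y[N:2 * N], 0.0)
        CaI = np.maximum(y[2 * N:3 * N], 0.0)
        g = np.clip(y[3 * N:4 * N], 0.0, 1.0)
        Glyc = np.maximum(y[4 * N:5 * N], 0.0)
        Gc = np.maximum(y[5 * N:6 * N], 0.0)
        blood = [np.maximum(y[(6 + k) * N:(7 + k) * N], 0.0) for k in range(5)]
        Gb, Insb, Glub, Epnb, NEpnb = blood
        GB, InsB, GluB, EpnB, NEpnB = np.maximum(y[11 * N:], 0.0)

        cns = organs.cns_activation(GB, sp.G_symp, sp.Km_symp)
        if stim_on:
            H = transport.assemble_stimulus(Epnb, NEpnb, innerv, cns, sp.stim_gain_cat)
        else:
            H = np.zeros(N)

        # hepatocyte signaling
        dr = cp.k_r_i * (1.0 - r) - cp.k_d * r - cp.k_Hr * H * r
        coupling = calcium.gap_junction_flux(IP3, config.G_ij)
        synth = cp.k_IP3_i * H * r / (cp.k_cat + r) * CaI / (CaI + cp.k3)
        dIP3 = synth - cp.D * IP3 - coupling
        release = (1.0 - g) * (cp.A * IP3**4 / (cp.k1 + IP3)**4 + cp.L) * (CaT - CaI)
        dCaI = release - cp.B * CaI**2 / (cp.k2**2 + CaI**2)
        dg = cp.E * CaI**4 * (1.0 - g) - cp.F
        dr = calcium._clamped_rate(r, dr)
        dg = calcium._clamped_rate(g, dg)

        # metabolism
        flux = metabolism.glycogenolysis_rate(
            Glyc, mp.Phos, Glub * 1e3, Insb * 1e3, CaI, mp.zonation_weight_i, mp)
        export = metabolism.glucose_export_flux(Gc, Gb, mp.k_export)
        dGlyc = -flux * 1e-3
        dGc = flux - export

        # blood transport + local sources/sinks
        body_vals = (GB, InsB, GluB, EpnB, NEpnB)
        dblood = []
        dbody = []
        for k, (M, M0) in enumerate(zip(blood, body_vals)):
            dM, dM0 = transport.advection_rhs(M, M0, bf, s)
            if k == 0:
                dM = dM + export
            elif k == 1:
                dM = dM + transport.hepatic_clearance_rhs(M, sp.k_clear_insulin)
            elif k == 2:
                dM = dM + transport.hepatic_clearance_rhs(M, sp.k_clear_glucagon)
            else:
                dM = dM + transport.hepatic_clearance_rhs(M, sp.k_clear_cat)
            dblood.append(dM)
            dbody.append(dM0)

        # body-side physiology
        glu_rate, ins_rate = organs.pancreas_secretion(
            GB / sp.G_au_scale, sp, variant, cns)
        epn_rate, nepn_rate = organs.adrenal_secretion(cns, sp, variant)
        dbody[0] -= u_G
        dbody[1] += ins_rate
        dbody[2] += glu_rate
        # adrenal output is a lobule-referred flux; the body pool is s-fold larger
        dbody[3] += epn_rate / s
        dbody[4] += nepn_rate / s

        out = np.concatenate([dr, dIP3, dCaI, dg, dGlyc, dGc] + dblood + [np.asarray(dbody)])
        # keep non-negative states from integrating below zero
        neg = (y <= 0.0) & (out < 0.0)
        # r and g are handled above; concentrations clamp at zero here
        neg[0:N] = False
        neg[3 * N:4 * N] = False
        out[neg] = 0.0
        return out

    return rhs


def _jac_sparsity(config: ScenarioConfig):
    N = config.transport.N
    n = 11 * N + 5
    S = lil_matrix((n, n), dtype=np.int8)
    iGB = 11 * N

    def blk(name):
        return {"r": 0, "IP3": N, "CaI": 2 * N, "g": 3 * N, "Glyc": 4 * N,
                "Gc": 5 * N, "glucose": 6 * N, "insulin": 7 * N,
                "glucagon": 8 * N, "epinephrine": 9 * N,
                "norepinephrine": 10 * N}[name]

    for i in range(N):
        r, ip3, ca, g = blk("r") + i, blk("IP3") + i, blk("CaI") + i, blk("g") + i
        gly, gc = blk("Glyc") + i, blk("Gc") + i
        gb, ins, glu = blk("glucose") + i, blk("insulin") + i, blk("glucagon") + i
        epn, nepn = blk("epinephrine") + i, blk("norepinephrine") + i
        S[r, [r, epn, nepn, iGB]] = 1
        dep = [r, ip3, ca, epn, nepn, iGB]
        if i > 0:
            dep.append(blk("IP3") + i - 1)
        if i < N - 1:
            dep.append(blk("IP3") + i + 1)
        S[ip3, dep] = 1
        S[ca, [ca, g, ip3]] = 1
        S[g, [g, ca]] = 1
        S[gly, [gly, glu, ins, ca]] = 1
        S[gc, [gc, gly, glu, ins, ca, gb]] = 1
        for k, b in enumerate((gb, ins, glu, epn, nepn)):
            col0 = blk(BLOOD_SPECIES[k])
            dep = [b, col0 + i - 1 if i > 0 else iGB + k]
            S[b, dep] = 1
        S[gb, gc] = 1
    # body compartment rows: advective return + self + GB sensing
    for k in range(5):
        S[iGB + k, blk(BLOOD_SPECIES[k]) + N - 1] = 1
        S[iGB + k, iGB + k] = 1
        S[iGB + k, iGB] = 1  # CNSAct / pancreas sensing of GB
    return S.tocsr()


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time-indexed trajectories plus derived fluxes for one scenario."""

    t: np.ndarray                       # (T,) strictly increasing, s
    y: np.ndarray                       # (n_states, T)
    config: ScenarioConfig
    u_G_basal: float
    provenance: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.config.transport.N

    def cell(self, name: str) -> np.ndarray:
        """Per-cell trajectory block, shape (N, T)."""
        k = CELL_STATES.index(name)
        return self.y[k * self.N:(k + 1) * self.N]

    def blood(self, species: str) -> np.ndarray:
        """Sinusoidal trajectory block for one blood species, shape (N, T)."""
        k = BLOOD_SPECIES.index(species)
        return self.y[(6 + k) * self.N:(7 + k) * self.N]

    def body(self, name: str) -> np.ndarray:
        """Body-compartment trajectory, shape (T,)."""
        return self.y[11 * self.N + BODY_STATES.index(name)]

    @property
    def cns_activation(self) -> np.ndarray:
        sp = self.config.systemic
        return organs.cns_activation(self.body("GB"), sp.G_symp, sp.Km_symp)

    @property
    def glycogenolysis_flux(self) -> np.ndarray:
        """Per-layer glycogen breakdown flux (µM/s), shape (N, T)."""
        m = self.config.metabolism
        return metabolism.glycogenolysis_rate(
            self.cell("Glyc"), m.Phos,
            self.blood("glucagon") * 1e3, self.blood("insulin") * 1e3,
            self.cell("CaI"), m.zonation_weight_i[:, None], m)

    @property
    def glucose_export(self) -> np.ndarray:
        """Per-layer hepatocyte→sinusoid glucose flux (µM/s), shape (N, T)."""
        return metabolism.glucose_export_flux(
            self.cell("Gc"), self.blood("glucose"), self.config.metabolism.k_export)

    def to_long_dataframe(self):
        """Tidy long-format trajectory table (time, entity, variable, value)."""
        import pandas as pd
        frames = []
        for name in CELL_STATES:
            arr = self.cell(name)
            for i in range(self.N):
                frames.append(pd.DataFrame(
                    {"time": self.t, "entity": f"hepatocyte_{i + 1}",
                     "variable": name, "value": arr[i]}))
        for sp in BLOOD_SPECIES:
            arr = self.blood(sp)
            for i in range(self.N):
                frames.append(pd.DataFrame(
                    {"time": self.t, "entity": f"sinusoid_{i + 1}",
                     "variable": sp, "value": arr[i]}))
        for name in BODY_STATES:
            frames.append(pd.DataFrame(
                {"time": self.t, "entity": "body", "variable": name,
                 "value": self.body(name)}))
        return pd.concat(frames, ignore_index=True)

    def to_wide_dataframe(self):
        import pandas as pd
        cols = {}
        for name in CELL_STATES:
            arr = self.cell(name)
            for i in range(self.N):
                cols[f"{name}_{i + 1}"] = arr[i]
        for sp in BLOOD_SPECIES:
            arr = self.blood(sp)
            for i in range(self.N):
                cols[f"{sp}_{i + 1}"] = arr[i]
        for name in BODY_STATES:
            cols[name] = self.body(name)
        return pd.DataFrame(cols, index=pd.Index(self.t, name="time"))

    def summary(self) -> dict:
        from .analysis import glucose_outputs
        total, per_layer = glucose_outputs(self)
        return {
            "config_hash": self.provenance.get("config_hash"),
            "total_glucose_output": float(total),
            "per_layer_glucose_output": [float(v) for v in per_layer],
            "u_G_basal": self.u_G_basal,
            "final_GB": float(self.body("GB")[-1]),
            "integrator": self.provenance.get("integrator", {}),
        }

    def save(self, directory, wide: bool = False):
        """Write trajectory CSV and summary JSON into ``directory``."""
        import os
        os.makedirs(directory, exist_ok=True)
        df = self.to_wide_dataframe() if wide else self.to_long_dataframe()
        df.to_csv(os.path.join(directory, "trajectory.csv"),
                  index=wide, float_format="%.6g")
        with open(os.path.join(directory, "summary.json"), "w") as fh:
            json.dump(self.summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def run_scenario(config: ScenarioConfig) -> SimulationResult:
    """Integrate a scenario over [0, t_end] and return its trajectories.

    Deterministic: identical configs yield identical results at fixed
    integrator settings.  The exercise step is applied by restarting the
    integrator at the window boundaries.
    """
    N = config.transport.N
    y0 = _build_initial_state(config)
    u_basal = _resolve_u_G_basal(config, y0)
    sp = config.systemic

    t_grid = np.arange(0.0, config.t_end + config.dt_output / 2, config.dt_output)
    breaks = [0.0]
    if config.exercise_duration > 0 and sp.exercise_multiplier != 1.0:
        ex0 = config.exercise_start
        ex1 = min(config.exercise_start + config.exercise_duration, config.t_end)
        for b in (ex0, ex1):
            if 0.0 < b < config.t_end:
                breaks.append(b)
    breaks.append(config.t_end)
    breaks = sorted(set(breaks))

    sparsity = _jac_sparsity(config)
    ys = [y0[:, None]]
    ts = [np.array([0.0])]
    nfev = 0
    y_cur = y0
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        in_window = (config.exercise_start <= mid
                     < config.exercise_start + config.exercise_duration)
        u_G = u_basal * (sp.exercise_multiplier if in_window else 1.0)
        rhs = _make_rhs(config, u_G)
        seg_eval = t_grid[(t_grid > a + 1e-9) & (t_grid <= b + 1e-9)]
        sol = solve_ivp(rhs, (a, b), y_cur, method="BDF",
                        t_eval=seg_eval if len(seg_eval) else None,
                        rtol=config.rtol, atol=config.atol,
                        jac_sparsity=sparsity)
        if not sol.success:
            raise IntegrationError(
                f"integration failed on [{a}, {b}] at t={sol.t[-1] if len(sol.t) else a}: "
                f"{sol.message}")
        nfev += sol.nfev
        if len(seg_eval):
            ts.append(sol.t)
            ys.append(sol.y)
        # restart from the segment endpoint (re-integrate end if not on grid)
        if len(sol.t) and abs(sol.t[-1] - b) < 1e-9:
            y_cur = sol.y[:, -1]
        else:
            sol_end = solve_ivp(rhs, (sol.t[-1] if len(sol.t) else a, b),
                                sol.y[:, -1] if len(sol.t) else y_cur,
                                method="BDF", rtol=config.rtol, atol=config.atol,
                                jac_sparsity=sparsity)
            if not sol_end.success:
                raise IntegrationError(f"integration failed reaching t={b}")
            y_cur = sol_end.y[:, -1]

    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)

    # clamp residual excursions on the output grid and count them
    tol = 1e-6
    viol = 0
    for sl, lo, hi in ((slice(0, N), 0.0, 1.0), (slice(3 * N, 4 * N), 0.0, 1.0),
                       (slice(N, 3 * N), 0.0, None), (slice(4 * N, 11 * N + 5), 0.0, None)):
        block = y[sl]
        bad = (block < -tol) | ((block > 1.0 + tol) if hi is not None else False)
        viol += int(np.count_nonzero(bad))
        np.clip(block, lo, hi, out=block)
    frac = viol / y.size
    if frac > 1e-3:
        raise InvariantViolationError(
            f"{100 * frac:.2f}% of output samples violated state bounds")

    prov = {
        "config_hash": config_hash(config),
        "integrator": {"method": "BDF", "rtol": config.rtol, "atol": config.atol,
                       "nfev": int(nfev), "clamped_samples": int(viol)},
    }
    return SimulationResult(t=t, y=y, config=config, u_G_basal=u_basal,
                            provenance=prov)


def run_comparison(configs) -> list:
    """Run several scenarios on a shared time grid for paired analysis."""
    configs = list(configs)
    if not configs:
        return []
    ref = configs[0]
    for c in configs[1:]:
        if c.transport.N != ref.transport.N or c.t_end != ref.t_end \
                or c.dt_output != ref.dt_output:
            raise ValueError("comparison configs must share N, t_end and dt_output")
    return [run_scenario(c) for c in configs]
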