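"""Model parameters, zonation gradients, initial conditions and scenario presets.

Every rate constant of the coupled lobule model lives here, grouped by the
physiological subsystem it belongs to.  The dataclasses are plain containers;
validation happens in ``__post_init__`` so that a fully constructed
:class:`ScenarioConfig` is always internally consistent.  Configs round-trip
through YAML via :func:`to_yaml` / :func:`from_yaml`.

Units follow the conventions used throughout the package: concentrations in
µM for Ca²⁺, IP₃ and glucose, nM for hormones and catecholamines, mM for the
glycogen store; all rates per second.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "CalciumParams",
    "MetabolismParams",
    "SystemicParams",
    "TransportParams",
    "InnervationPattern",
    "InitialConditions",
    "ScenarioConfig",
    "build_zonation_gradients",
    "preset",
    "PRESET_NAMES",
    "to_yaml",
    "from_yaml",
    "config_hash",
]


class InvalidLobuleError(ValueError):
    """Raised when a lobule geometry is degenerate (fewer than two layers)."""


def build_zonation_gradients(N: int, lo: float, hi: float) -> np.ndarray:
    """Linearly graded per-cell rate vector along the porto-central axis.

    Cell 1 (periportal) takes the value ``lo``, cell ``N`` (pericentral)
    ``hi``; interior cells are linearly interpolated.  The graded Ca²⁺
    signaling rates (receptor recycling ``k_r`` and IP₃ synthesis ``k_IP3``)
    increase from PP to PC, reflecting the higher α₁-adrenergic receptor and
    IP₃-pathway expression of pericentral hepatocytes.

    Parameters
    ----------
    N : number of hepatic layers (≥ 2)
    lo : rate at the periportal end (s⁻¹)
    hi : rate at the pericentral end (s⁻¹)
    """
    if N < 2:
        raise InvalidLobuleError(f"a lobule needs at least 2 layers, got N={N}")
    if lo > hi:
        raise ValueError(f"gradient must be non-decreasing PP->PC (lo={lo} > hi={hi})")
    return np.linspace(float(lo), float(hi), int(N))


@dataclass
class CalciumParams:
    """Constants of the per-hepatocyte IP₃–Ca²⁺ cross-coupling oscillator.

    The oscillator follows the closed-cell Meyer–Stryer formulation: IP₃
    gates Ca²⁺ release from the ER store, cytosolic Ca²⁺ feeds back on IP₃
    synthesis, and high Ca²⁺ inactivates the IP₃ receptor.
    """

    A: float = 0.20          # max ER release rate (µM/s)
    B: float = 0.082         # max SERCA pump rate (µM/s)
    D: float = 0.8           # IP3 degradation rate (1/s)
    E: float = 1.0           # IP3R inactivation rate (1/µM^4/s)
    F: float = 0.01          # IP3R reactivation rate (1/s)
    k1: float = 1.0          # IP3 half-sat of store release (µM)
    k2: float = 0.15         # CaI half-sat of the pump (µM)
    k3: float = 1.0          # CaI half-sat of IP3 production (µM)
    k_cat: float = 0.45      # bound-receptor ratio for half-max IP3 production
    k_d: float = 0.34        # hormone-independent receptor binding rate (1/s)
    k_Hr: float = 1.0        # hormone-receptor binding rate (1/nM/s)
    L: float = 0.00015       # store leak flux (µM/s)
    # per-cell graded rates, periportal (index 0) -> pericentral (index N-1)
    k_r_i: np.ndarray = field(default_factory=lambda: build_zonation_gradients(15, 0.5, 1.0))
    k_IP3_i: np.ndarray = field(default_factory=lambda: build_zonation_gradients(15, 0.5, 0.6))

    def __post_init__(self):
        self.k_r_i = np.asarray(self.k_r_i, dtype=float)
        self.k_IP3_i = np.asarray(self.k_IP3_i, dtype=float)
        for name in ("A", "B", "D", "E", "F", "k1", "k2", "k3", "k_cat", "k_d", "k_Hr", "L"):
            if getattr(self, name) < 0:
                raise ValueError(f"CalciumParams.{name} must be >= 0")
        for name in ("k_r_i", "k_IP3_i"):
            v = getattr(self, name)
            if np.any(np.diff(v) < -1e-12):
                raise ValueError(f"CalciumParams.{name} must be non-decreasing PP->PC")


@dataclass
class MetabolismParams:
    """Ca²⁺-potentiated glycogenolysis and the glycogen→glucose backbone."""

    CaI_GPK: float = 0.44        # Ca activation threshold of GPK (µM)
    K_CaI_GPK: float = 3.0       # Hill constant of the GPK activity term (µM)
    v0: float = 0.05             # basal GPK activity below threshold
    v_brk: float = 5.0           # max glycogen breakdown rate (µM/s)
    Km_Glyc: float = 100.0       # glycogen half-sat (mM)
    Km_Phos: float = 4000.0      # phosphate half-sat (µM)
    n_brk: float = 4.0           # Hill exponent of the glycogen term
    v_CaI_max: float = 3.0       # max Ca-driven potentiation of glycogenolysis
    Km_CaI: float = 0.6          # Michaelis constant of the Ca potentiation (µM)
    use_Km_CaI: bool = True      # False switches the GPK Hill constant to K_CaI_GPK
    k_LP: float = 45.0           # glucagon offset in K_Phos_max (pM)
    k_IP: float = 26.66          # insulin offset in K_Phos_max (pM)
    Phos: float = 4000.0         # intracellular phosphate, held constant (µM)
    k_export: float = 0.1        # hepatocyte<->sinusoid glucose exchange rate (1/s)
    # multiplicative per-cell weight on glycogenolysis, non-increasing PP->PC
    zonation_weight_i: np.ndarray = field(
        default_factory=lambda: np.linspace(1.0, 0.5, 15))

    def __post_init__(self):
        self.zonation_weight_i = np.asarray(self.zonation_weight_i, dtype=float)
        if self.CaI_GPK <= 0:
            raise ValueError("CaI_GPK must be > 0")
        if not (0 < self.v0 <= 1):
            raise ValueError("v0 must lie in (0, 1]")
        if self.n_brk < 1:
            raise ValueError("n_brk must be >= 1")
        w = self.zonation_weight_i
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("zonation weights must lie in (0, 1]")
        if np.any(np.diff(w) > 1e-12):
            raise ValueError("zonation weights must be non-increasing PP->PC")

    @property
    def gpk_hill_constant(self) -> float:
        return self.Km_CaI if self.use_Km_CaI else self.K_CaI_GPK


@dataclass
class SystemicParams:
    """Body-compartment constants: pancreas, CNS, adrenal glands, muscle uptake."""

    G_ref: float = 2.0            # glucose reference for the pancreas (a.u.)
    tau_glu: float = 1.3          # glucagon secretion time constant (s)
    tau_ins: float = 0.9          # insulin secretion time constant (s)
    km_glu: float = 1.3           # half-max constant of the log-deviation Hill term
    km_ins: float = 0.9
    n_glu: float = 2.0
    n_ins: float = 2.0
    Km_symp: float = 500.0        # CNS half-sat (µM)
    G_symp: float = 4500.0        # CNS activation threshold (µM)
    v_Epn: float = 0.5            # basal epinephrine synthesis rate (nM/s)
    v_NEpn: float = 1.5           # basal norepinephrine synthesis rate (nM/s)
    X_Epn: float = 6.0            # CNS stimulatory factor on epinephrine
    X_NEpn: float = 14.0          # CNS stimulatory factor on norepinephrine
    adrenal_amplification: float = 1.0
    v_glu_alt: float = 0.1        # CNS-driven glucagon rate, alternative variant (nM/s)
    km_glu_alt: float = 0.1       # half-max CNS activation, alternative variant
    G_au_scale: float = 2500.0    # µM per a.u. bridge for the pancreas equations
    k_clear_glucagon: float = 0.012  # hepatic glucagon clearance (1/s, calibrated)
    k_clear_insulin: float = 2e-4    # hepatic insulin clearance (1/s, calibrated)
    k_clear_cat: float = 0.03        # hepatic catecholamine clearance (1/s, calibrated)
    stim_gain_cat: float = 1.0       # circulating catecholamine -> stimulus gain (dimensionless dial)
    u_G_basal: float | None = None   # basal body glucose consumption (µM/s); None = balance at start
    exercise_multiplier: float = 3.5

    def __post_init__(self):
        for name in ("G_ref", "tau_glu", "tau_ins", "km_glu", "km_ins", "Km_symp",
                     "G_symp", "G_au_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SystemicParams.{name} must be > 0")
        if self.adrenal_amplification < 0:
            raise ValueError("adrenal_amplification must be >= 0")


@dataclass
class TransportParams:
    """Sinusoidal blood-flow geometry of the lobule."""

    N: int = 15                   # number of hepatic layers
    bf: float | None = None       # per-compartment blood flow (1/s); None = 0.15 * N
    pressure_fold: float = 1.0    # portal pressure multiplier (Poiseuille scaling)

    def __post_init__(self):
        if self.N < 2:
            raise InvalidLobuleError(f"a lobule needs at least 2 layers, got N={self.N}")
        if self.bf is None:
            self.bf = 0.15 * self.N
        self.bf = float(self.bf) * 1.0
        if self.bf <= 0:
            raise ValueError("bf must be > 0")
        if self.pressure_fold < 1:
            raise ValueError("pressure_fold must be >= 1")

    @property
    def s(self) -> float:
        """Body-to-hepatic compartment volume ratio, s = 5·N."""
        return 5.0 * self.N

    @property
    def bf_effective(self) -> float:
        """Flow rate after Poiseuille pressure scaling."""
        return self.bf * self.pressure_fold


@dataclass
class InnervationPattern:
    """Which hepatic layers receive direct sympathetic norepinephrine input."""

    innervated_mask: np.ndarray = field(default_factory=lambda: np.ones(15, dtype=bool))
    K_NEpn_stim: float = 2.0      # synaptic norepinephrine stimulus (nM)

    def __post_init__(self):
        self.innervated_mask = np.asarray(self.innervated_mask, dtype=bool)
        if self.K_NEpn_stim < 0:
            raise ValueError("K_NEpn_stim must be >= 0")

    @classmethod
    def human(cls, N: int = 15) -> "InnervationPattern":
        """All layers innervated (human-like extensive innervation)."""
        return cls(np.ones(N, dtype=bool), 2.0)

    @classmethod
    def rodent(cls, N: int = 15) -> "InnervationPattern":
        """Only the first four periportal layers innervated (rodent-like)."""
        mask = np.zeros(N, dtype=bool)
        mask[: min(4, N)] = True
        return cls(mask, 2.0)

    @classmethod
    def denervated(cls, N: int = 15) -> "InnervationPattern":
        """No synaptic input anywhere (K_NEpn_stim = 0)."""
        return cls(np.zeros(N, dtype=bool), 0.0)


@dataclass
class InitialConditions:
    """Initial state shared by all hepatocytes, plus blood/body species."""

    CaI0: float = 0.2        # cytosolic Ca (µM)
    CaT0: float = 500.2      # total cell Ca (µM), constant per cell
    g0: float = 0.25         # free/total IP3R fraction
    IP30: float = 1e-4       # IP3 (µM); 0.1 nM
    r0: float = 0.5          # free/total surface receptor fraction
    Glyc0: float = 300.0     # glycogen store (mM glucosyl units)
    # Blood-side initial values sit at the resting (no-exercise) fixed point
    # so the control scenario is stationary from t = 0: normoglycemic GB with
    # basal glucagon exactly balancing its hepatic clearance.
    GB0: float = 4600.0      # systemic and sinusoidal glucose (µM)
    Ins_B0: float = 15.0     # systemic insulin (nM)
    Glu_B0: float = 1.37     # systemic glucagon (nM)
    # Catecholamine initial values default to the basal secretion/clearance
    # steady state and are filled in by the engine when left as None.
    Epn_B0: float | None = None
    NEpn_B0: float | None = None


@dataclass
class ScenarioConfig:
    """Fully specified simulation scenario."""

    variant: str = "main"                     # "main" | "alternative"
    innervation: InnervationPattern = field(default_factory=InnervationPattern.human)
    G_ij: float = 5.0                         # gap-junction IP3 transfer coefficient (1/s)
    transport: TransportParams = field(default_factory=TransportParams)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    metabolism: MetabolismParams = field(default_factory=MetabolismParams)
    systemic: SystemicParams = field(default_factory=SystemicParams)
    initial: InitialConditions = field(default_factory=InitialConditions)
    exercise_start: float = 500.0             # s
    exercise_duration: float = 3600.0         # s
    t_end: float = 4100.0                     # s
    dt_output: float = 1.0                    # dense output resolution (s)
    ca_stimulus_enabled: bool = True          # False disables the hepatocyte Ca stimulus
    rtol: float = 1e-6
    atol: float = 1e-9
    seed: int | None = None                   # inert; reserved for jitter studies

    def __post_init__(self):
        if self.variant not in ("main", "alternative"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.G_ij < 0:
            raise ValueError("G_ij must be >= 0")
        N = self.transport.N
        if len(self.innervation.innervated_mask) != N:
            raise ValueError("innervation mask length must equal N")
        if len(self.calcium.k_r_i) != N or len(self.calcium.k_IP3_i) != N:
            raise ValueError("zonation gradient length must equal N")
        if len(self.metabolism.zonation_weight_i) != N:
            raise ValueError("zonation weight length must equal N")
        if self.exercise_duration < 0:
            raise ValueError("exercise_duration must be >= 0")
        if not 0 <= self.exercise_start <= self.t_end + 1e-9:
            raise ValueError("exercise must start within [0, t_end]")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "human",
    "rodent",
    "denervated",
    "rodent_1.2x",
    "denervated_1.4x",
    "human_hypertensive",
    "rodent_hypertensive",
    "no_exercise",
)


def preset(name: str, gij: float = 5.0, variant: str = "main") -> ScenarioConfig:
    """Build a named scenario at a given gap-junction coupling level.

    ``human`` innervates all 15 layers, ``rodent`` the first four periportal
    layers, ``denervated`` none.  ``*_1.2x`` / ``*_1.4x`` amplify adrenal
    catecholamine synthesis, ``*_hypertensive`` applies the 3-fold Poiseuille
    flow scaling of severe portal hypertension, and ``no_exercise`` is the
    flat control (unit exercise multiplier).
    """
    N = 15
    transport = TransportParams(N=N)
    systemic = SystemicParams()
    innervation = InnervationPattern.human(N)
    exercise_multiplier = 3.5

    base = name
    if name == "rodent_1.2x":
        base, systemic.adrenal_amplification = "rodent", 1.2
    elif name == "denervated_1.4x":
        base, systemic.adrenal_amplification = "denervated", 1.4
    elif name == "human_hypertensive":
        base, transport.pressure_fold = "human", 3.0
    elif name == "rodent_hypertensive":
        base, transport.pressure_fold = "rodent", 3.0
    elif name == "no_exercise":
        base, exercise_multiplier = "human", 1.0

    if base == "human":
        innervation = InnervationPattern.human(N)
    elif base == "rodent":
        innervation = InnervationPattern.rodent(N)
    elif base == "denervated":
        innervation = InnervationPattern.denervated(N)
    else:
        raise KeyError(f"unknown preset {name!r}")

    calcium = CalciumParams()
    if variant == "alternative":
        calcium.k_r_i = build_zonation_gradients(N, 1.0, 2.0)
        calcium.k_IP3_i = build_zonation_gradients(N, 1.0, 2.0)

    systemic.exercise_multiplier = exercise_multiplier
    return ScenarioConfig(
        variant=variant,
        innervation=innervation,
        G_ij=float(gij),
        transport=transport,
        calcium=calcium,
        systemic=systemic,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, np.integer, np.floating)):
        return obj.item()
    return obj


def to_dict(config: ScenarioConfig) -> dict:
    return _to_plain(config)


def to_yaml(config: ScenarioConfig, path=None) -> str:
    """Serialize a scenario config to YAML (returned; also written if a path is given)."""
    text = yaml.safe_dump(to_dict(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    sub = {
        "innervation": InnervationPattern,
        "transport": TransportParams,
        "calcium": CalciumParams,
        "metabolism": MetabolismParams,
        "systemic": SystemicParams,
        "initial": InitialConditions,
    }
    kwargs = {}
    for key, val in d.items():
        if key in sub and isinstance(val, dict):
            kwargs[key] = sub[key](**val)
        else:
            kwargs[key] = val
    return ScenarioConfig(**kwargs)


def from_yaml(source) -> ScenarioConfig:
    """Load a scenario config from a YAML string or file path."""
    import os
    if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith(("{", "variant")) \
            and os.path.exists(str(source)):
        with open(source) as fh:
            d = yaml.safe_load(fh)
    else:
        d = yaml.safe_load(source)
    return from_dict(d)


def config_hash(config: ScenarioConfig) -> str:
    """Stable short hash of a config, for provenance records."""
    payload = json.dumps(to_dict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
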