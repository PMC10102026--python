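"""Three-compartment mass-action model of karyopherin-mediated transport.

The network couples three modules:

* **Import** — importin-α (lumped KPNA1–7) dimerizes with importin-β; the
  heterodimer loads classical-NLS cargo in the cytoplasm, translocates through
  the nuclear pore, and is disassembled in the nucleus by RanGTP binding to
  importin-β.  IBB-type cargo binds importin-β directly.  CAS (CSE1L) recycles
  importin-α back to the cytoplasm as a CAS:RanGTP:ImpA complex and also
  competes for free importin-α in a RanGTP-independent manner.
* **Export** — NES cargo is loaded in the nucleus onto CRM1 (XPO1) that has
  been primed by RanBP3 and RanGTP; the export complex translocates and is
  disassembled in the cytoplasm by RanBP1/RanGAP.
* **Ran cycle** — RCC1 exchanges RanGDP→RanGTP in the nucleus; RanBP1 strips
  RanGTP from carrier complexes in the cytoplasm and RanGAP hydrolyzes it;
  NTF2 returns RanGDP to the nucleus.

Directionality is emergent: every binding reaction is reversible and every
translocation step is symmetric, so the steady-state nuclear accumulation of
cargo is driven entirely by the RanGTP gradient that the RCC1/RanGAP
asymmetry maintains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .config import ModelConfig
from .network import CYTOPLASM, NUCLEUS, PORE, Compartment, Reaction, ReactionNetwork

__all__ = [
    "CargoSpec",
    "SteadyStateResult",
    "TransportModel",
    "build_network",
    "add_cargo",
    "integrate",
    "steady_state",
    "scale_initial_conditions",
    "sensitivity_scan",
    "stratified_prediction_test",
    "TRANSCRIPT_MAP",
]

BASE_SPECIES = (
    "Ran", "NTF2", "RCC1", "RanGAP", "RanBP1", "RanBP3",
    "ImpA", "ImpB", "CAS", "CRM1",
)

#: microarray gene symbols → model species (KPNA1–7 aggregate to ImpA)
TRANSCRIPT_MAP = {
    "KPNA1": "ImpA", "KPNA2": "ImpA", "KPNA3": "ImpA", "KPNA4": "ImpA",
    "KPNA5": "ImpA", "KPNA6": "ImpA", "KPNA7": "ImpA",
    "KPNB1": "ImpB", "CSE1L": "CAS", "XPO1": "CRM1", "RAN": "Ran",
    "RANBP1": "RanBP1", "RANBP3": "RanBP3", "RANGAP1": "RanGAP",
    "RCC1": "RCC1", "NUTF2": "NTF2",
}


@dataclass(frozen=True)
class CargoSpec:
    """A transport cargo reporter.

    import_mode "classical" binds the Imp-α:Imp-β heterodimer, "ibb" binds
    Imp-β alone, "inert" has no import route (control).  Dissociation
    constants in nM; k_off is derived as K_D · k_on with the configured k_on.
    """

    name: str
    import_mode: str = "classical"  # classical | ibb | inert
    kd_import: float = 32.0         # nM
    has_nes: bool = False
    kd_export: float | None = None  # nM, required if has_nes
    total_concentration: float = 1.0  # µM
    kon: float | None = None        # µM⁻¹s⁻¹; None → configured kon_cargo

    def __post_init__(self):
        if self.import_mode not in ("classical", "ibb", "inert"):
            raise ValueError(f"unknown import_mode {self.import_mode!r}")
        if not self.kd_import > 0:
            raise ValueError("kd_import must be > 0")
        if not self.total_concentration > 0:
            raise ValueError("total_concentration must be > 0")
        if self.has_nes and not (self.kd_export and self.kd_export > 0):
            raise ValueError("has_nes requires a positive kd_export")


# canonical reporters from the validation experiments
NLS_SV40 = CargoSpec("NLS", "classical", kd_import=32.0)
NLS2_CBP80 = CargoSpec("2xNLS", "classical", kd_import=2.5)
IBB_KPNA2 = CargoSpec("IBB", "ibb", kd_import=6.5)


@dataclass
class SteadyStateResult:
    x: np.ndarray
    nc_ratio: float
    residual_norm: float
    converged: bool
    method: str
    species_totals: dict[str, dict[str, float]] = field(default_factory=dict)


class TransportModel:
    """A compiled transport network plus its cargo bookkeeping."""

    def __init__(self, network: ReactionNetwork, config: ModelConfig):
        self.network = network
        self.config = config
        self.cargoes: dict[str, CargoSpec] = {}

    def copy(self) -> "TransportModel":
        m = TransportModel(self.network.copy(), self.config)
        m.cargoes = dict(self.cargoes)
        return m

    def cargo_states(self, cargo: str, compartment: str) -> list[int]:
        return [
            self.network.state_index(sp, comp)
            for sp, comp in self.network.states
            if comp == compartment and cargo in sp.split(":")
        ]

    def cargo_concentration(self, x: np.ndarray, cargo: str, compartment: str) -> float:
        """Total cargo concentration (free + complexed) in a compartment."""
        return float(sum(x[i] for i in self.cargo_states(cargo, compartment)))

    def nc_ratio(self, x: np.ndarray, cargo: str) -> float:
        """Nuclear ÷ cytoplasmic total cargo concentration (pore excluded)."""
        nuc = self.cargo_concentration(x, cargo, NUCLEUS)
        cyt = self.cargo_concentration(x, cargo, CYTOPLASM)
        if cyt <= 0:
            return np.inf if nuc > 0 else 0.0
        return max(nuc, 0.0) / cyt


# ---------------------------------------------------------------------------
# network construction


def _both(net, name, a, b, ab, kon, koff, comps=(CYTOPLASM, NUCLEUS)):
    """Reversible binding a + b ↔ ab in the given compartments."""
    for comp in comps:
        net.add_reaction(Reaction(f"{name}_on_{comp}", ((a, comp), (b, comp)), ((ab, comp),), kon, comp))
        net.add_reaction(Reaction(f"{name}_off_{comp}", ((ab, comp),), ((a, comp), (b, comp)), koff, comp))


def _translocate(net: ReactionNetwork, model: TransportModel, species: str, k: float | None = None):
    """Facilitated cytoplasm ↔ pore ↔ nucleus diffusion of one species.

    Each step carries flux P·C(source) where the permeability P (fL/s) sums
    pore-class conductances scaled by pore count relative to the reference
    count.  ``k`` (1/s) is the escape rate from the cytoplasm, so
    P = k·V_cytoplasm.  Equal concentrations in all three compartments give
    zero net flux, and the pore holds a negligible amount at steady state.
    """
    cfg = model.config
    classical = {n for n, c in model.cargoes.items() if c.import_mode == "classical"}
    ibb = {n for n, c in model.cargoes.items() if c.import_mode == "ibb"}
    if k is None:
        # cargo-laden complexes transit faster than the bulk carrier cycle:
        # loading, not the pore, is rate-limiting for facilitated cargo
        is_cargo_complex = bool(set(species.split(":")) & (classical | ibb))
        k_base = cfg.rate("k_trans_cargo") if is_cargo_complex else cfg.rate("k_trans")
        k = sum(
            k_base * pc.count / cfg.pores.reference_count
            for pc in cfg.pores.classes
            if pc.admits(species, classical, ibb)
        )
    if k <= 0:
        raise ValueError(f"species {species}: no pore class admits it")
    vols = {c: net.compartments[c].volume for c in (CYTOPLASM, NUCLEUS, PORE)}
    permeability = k * vols[CYTOPLASM]
    net.add_state(species, PORE)
    for a, b in ((CYTOPLASM, PORE), (PORE, NUCLEUS)):
        net.add_reaction(Reaction(
            f"t_{species}_{a}_{b}", ((species, a),), ((species, b),),
            permeability / vols[a], a))
        net.add_reaction(Reaction(
            f"t_{species}_{b}_{a}", ((species, b),), ((species, a),),
            permeability / vols[b], b))


def build_network(config: ModelConfig) -> TransportModel:
    """Assemble the cargo-free base network from a model configuration."""
    comps = {n: Compartment(n, v) for n, v in config.compartments.items()}
    net = ReactionNetwork(comps)
    model = TransportModel(net, config)
    r = config.rate

    # free species in both reactive compartments; initial amounts in the home
    # compartment (Ran enters as RanGDP)
    for name, (conc, home) in config.species.items():
        state_name = "RanGDP" if name == "Ran" else name
        for comp in (CYTOPLASM, NUCLEUS):
            net.add_state(state_name, comp, conc if comp == home else 0.0)
    for comp in (CYTOPLASM, NUCLEUS):
        net.add_state("RanGTP", comp, 0.0)

    complexes = [
        "ImpA:ImpB", "NTF2:RanGDP", "RanBP1:RanGTP", "RCC1:RanGDP",
        "ImpB:RanGTP", "CAS:ImpA", "CAS:RanGTP", "CAS:RanGTP:ImpA",
        "CRM1:RanGTP", "CRM1:RanBP3", "CRM1:RanBP3:RanGTP",
    ]
    for sp in complexes:
        for comp in (CYTOPLASM, NUCLEUS):
            net.add_state(sp, comp, 0.0)

    # -- import module ------------------------------------------------------
    _both(net, "impab", "ImpA", "ImpB", "ImpA:ImpB", r("kon_impab"), r("koff_impab"))
    _both(net, "impb_rangtp", "ImpB", "RanGTP", "ImpB:RanGTP",
          r("kon_impb_rangtp"), r("koff_impb_rangtp"))
    for comp in (CYTOPLASM, NUCLEUS):
        # RanGTP-driven disassembly of the heterodimer
        net.add_reaction(Reaction(
            f"rangtp_impab_{comp}",
            (("ImpA:ImpB", comp), ("RanGTP", comp)),
            (("ImpA", comp), ("ImpB:RanGTP", comp)),
            r("k_rangtp_impb"), comp))

    # -- CAS / importin-α recycling ----------------------------------------
    _both(net, "cas_rangtp", "CAS", "RanGTP", "CAS:RanGTP",
          r("kon_cas_rangtp"), r("koff_cas_rangtp"))
    _both(net, "cas_impa", "CAS", "ImpA", "CAS:ImpA",
          r("kon_cas_impa"), r("koff_cas_impa"))
    _both(net, "casrangtp_impa", "CAS:RanGTP", "ImpA", "CAS:RanGTP:ImpA",
          r("kon_casrangtp_impa"), r("koff_casrangtp_impa"), comps=(NUCLEUS,))
    net.add_reaction(Reaction(
        "rangtp_casimpa_nuc",
        (("CAS:ImpA", NUCLEUS), ("RanGTP", NUCLEUS)),
        (("CAS:RanGTP:ImpA", NUCLEUS),),
        r("k_rangtp_casimpa"), NUCLEUS))

    # -- CRM1 / RanBP3 export machinery ------------------------------------
    _both(net, "crm1_rangtp", "CRM1", "RanGTP", "CRM1:RanGTP",
          r("kon_crm1_rangtp"), r("koff_crm1_rangtp"))
    _both(net, "crm1_ranbp3", "CRM1", "RanBP3", "CRM1:RanBP3",
          r("kon_crm1_ranbp3"), r("koff_crm1_ranbp3"), comps=(NUCLEUS,))
    _both(net, "crm1ranbp3_rangtp", "CRM1:RanBP3", "RanGTP", "CRM1:RanBP3:RanGTP",
          r("kon_crm1ranbp3_rangtp"), r("koff_crm1ranbp3_rangtp"), comps=(NUCLEUS,))

    # -- Ran cycle ----------------------------------------------------------
    _both(net, "ntf2_rangdp", "NTF2", "RanGDP", "NTF2:RanGDP",
          r("kon_ntf2_rangdp"), r("koff_ntf2_rangdp"))
    _both(net, "rcc1_rangdp", "RCC1", "RanGDP", "RCC1:RanGDP",
          r("kon_rcc1_rangdp"), r("koff_rcc1_rangdp"), comps=(NUCLEUS,))
    net.add_reaction(Reaction(
        "rcc1_exchange", (("RCC1:RanGDP", NUCLEUS),),
        (("RCC1", NUCLEUS), ("RanGTP", NUCLEUS)), r("kcat_rcc1"), NUCLEUS))
    _both(net, "ranbp1_rangtp", "RanBP1", "RanGTP", "RanBP1:RanGTP",
          r("kon_ranbp1_rangtp"), r("koff_ranbp1_rangtp"), comps=(CYTOPLASM,))
    net.add_reaction(Reaction(
        "rangap_ranbp1", (("RanBP1:RanGTP", CYTOPLASM), ("RanGAP", CYTOPLASM)),
        (("RanBP1", CYTOPLASM), ("RanGDP", CYTOPLASM), ("RanGAP", CYTOPLASM)),
        r("kcat_rangap"), CYTOPLASM))
    net.add_reaction(Reaction(
        "rangap_basal", (("RanGTP", CYTOPLASM), ("RanGAP", CYTOPLASM)),
        (("RanGDP", CYTOPLASM), ("RanGAP", CYTOPLASM)),
        r("k_rangap_basal"), CYTOPLASM))

    # -- RanBP1 stripping of carrier:RanGTP complexes in the cytoplasm ------
    strips = {
        "ImpB:RanGTP": ("ImpB",),
        "CAS:RanGTP": ("CAS",),
        "CAS:RanGTP:ImpA": ("CAS", "ImpA"),
        "CRM1:RanGTP": ("CRM1",),
        "CRM1:RanBP3:RanGTP": ("CRM1", "RanBP3"),
    }
    for carrier, released in strips.items():
        net.add_reaction(Reaction(
            f"strip_{carrier.replace(':', '_')}",
            ((carrier, CYTOPLASM), ("RanBP1", CYTOPLASM)),
            tuple((sp, CYTOPLASM) for sp in released) + (("RanBP1:RanGTP", CYTOPLASM),),
            r("k_ranbp1_strip"), CYTOPLASM))

    # -- translocation ------------------------------------------------------
    for sp in ("ImpB", "ImpA:ImpB", "ImpB:RanGTP", "NTF2", "NTF2:RanGDP",
               "CAS", "CAS:RanGTP", "CAS:RanGTP:ImpA", "CRM1", "CRM1:RanGTP",
               "CRM1:RanBP3:RanGTP"):
        _translocate(net, model, sp)
    _translocate(net, model, "RanBP3", k=r("k_trans_ranbp3"))
    # slow CAS-independent shuttling of free importin-α
    _translocate(net, model, "ImpA", k=r("k_trans_impa"))

    net.compile()
    return model


def add_cargo(model: TransportModel, cargo: CargoSpec) -> TransportModel:
    """Return a new model with the cargo's species and reactions added."""
    if cargo.name in model.cargoes:
        raise ValueError(f"cargo {cargo.name!r} already present")
    for part in cargo.name.split(":"):
        if model.network.has_species(part):
            raise ValueError(f"cargo name {cargo.name!r} collides with a model species")
    model = model.copy()
    model.cargoes[cargo.name] = cargo
    net, r = model.network, model.config.rate
    x = cargo.name

    for comp in (CYTOPLASM, NUCLEUS):
        net.add_state(x, comp, cargo.total_concentration if comp == CYTOPLASM else 0.0)

    # slow passive permeation of the free cargo through the pore; set the
    # rate to 0 in the configuration to model a strictly excluded cargo
    k_passive = r("k_passive_cargo")
    if k_passive > 0:
        _translocate(net, model, x, k=k_passive)

    kd_uM = cargo.kd_import * 1e-3
    if cargo.import_mode == "classical":
        carrier, bound = "ImpA:ImpB", f"{x}:ImpA:ImpB"
    elif cargo.import_mode == "ibb":
        carrier, bound = "ImpB", f"{x}:ImpB"
    if cargo.import_mode != "inert":
        for comp in (CYTOPLASM, NUCLEUS):
            net.add_state(bound, comp, 0.0)
        kon = cargo.kon if cargo.kon is not None else r("kon_cargo")
        _both(net, f"{x}_load", x, carrier, bound, kon, kd_uM * kon)
        for comp in (CYTOPLASM, NUCLEUS):
            products = [(x, comp), ("ImpB:RanGTP", comp)]
            if cargo.import_mode == "classical":
                products.insert(1, ("ImpA", comp))
            net.add_reaction(Reaction(
                f"rangtp_{x}_{comp}", ((bound, comp), ("RanGTP", comp)),
                tuple(products), r("k_rangtp_impb"), comp))
        _translocate(net, model, bound)

    if cargo.has_nes:
        exp = f"{x}:CRM1:RanBP3:RanGTP"
        for comp in (CYTOPLASM, NUCLEUS):
            net.add_state(exp, comp, 0.0)
        kon_e = r("kon_cargo_export")
        _both(net, f"{x}_export_load", x, "CRM1:RanBP3:RanGTP", exp,
              kon_e, cargo.kd_export * 1e-3 * kon_e, comps=(NUCLEUS,))
        net.add_reaction(Reaction(
            f"strip_{x}_export", ((exp, CYTOPLASM), ("RanBP1", CYTOPLASM)),
            ((x, CYTOPLASM), ("CRM1", CYTOPLASM), ("RanBP3", CYTOPLASM),
             ("RanBP1:RanGTP", CYTOPLASM)),
            r("k_ranbp1_strip"), CYTOPLASM))
        _translocate(net, model, exp)

    net.compile()
    return model


# ---------------------------------------------------------------------------
# simulation


def integrate(model: TransportModel, t_end: float, x0: np.ndarray | None = None,
              rtol: float = 1e-8, atol: float = 1e-12, n_out: int = 50):
    """Integrate the network ODEs to ``t_end``; returns (t, X[states, t])."""
    if not t_end > 0:
        if t_end == 0:
            x = model.network.x0 if x0 is None else np.asarray(x0, float)
            return np.array([0.0]), x[:, None].copy()
        raise ValueError("t_end must be >= 0")
    net = model.network
    net.compile()
    x0 = net.x0 if x0 is None else np.asarray(x0, float)
    sol = solve_ivp(
        lambda t, y: net.rhs(y), (0.0, t_end), x0, method="BDF",
        jac=lambda t, y: net.jacobian(y), rtol=rtol, atol=atol,
        t_eval=np.linspace(0.0, t_end, n_out),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y


def steady_state(model: TransportModel, cargo: str | None = None,
                 x0: np.ndarray | None = None, tol: float = 1e-9,
                 newton_polish: bool = True) -> SteadyStateResult:
    """Solve dC/dt = 0 by staged integration with a damped-Newton polish.

    The Newton (Levenberg–Marquardt) polish is accepted only if it reduces the
    residual while preserving nonnegativity and the volume-weighted moiety
    totals to 1e-6 relative; otherwise the integration result stands.
    """
    net = model.network
    net.compile()
    x = (net.x0 if x0 is None else np.asarray(x0, float)).copy()
    mos, W = net.moiety_matrix()
    totals0 = W @ net.x0 if x0 is None else W @ x
    method = "integration"

    t_stage = 200.0
    resid = float(np.abs(net.rhs(x)).max())
    for _ in range(8):
        if resid < tol:
            break
        t, X = integrate(model, t_stage, x0=x, n_out=2)
        x = X[:, -1]
        resid = float(np.abs(net.rhs(x)).max())
        t_stage *= 5.0

    if newton_polish and resid >= tol * 1e-3:
        sol = root(net.rhs, x, jac=net.jacobian, method="lm",
                   options={"xtol": 1e-14, "ftol": 1e-14})
        xn = sol.x
        rn = float(np.abs(net.rhs(xn)).max())
        scale = np.maximum(np.abs(totals0), 1e-12)
        cons_ok = np.all(np.abs(W @ xn - totals0) / scale < 1e-6)
        if rn < resid and cons_ok and xn.min() > -1e-9:
            x, resid, method = xn, rn, "integration+newton"

    converged = resid < tol
    nc = model.nc_ratio(np.clip(x, 0.0, None), cargo) if cargo else np.nan
    totals = {
        c: {sp: float(x[net.state_index(sp, c)])
            for sp, comp in net.states if comp == c}
        for c in (CYTOPLASM, NUCLEUS, PORE)
    }
    return SteadyStateResult(x, nc, resid, converged, method, totals)


# ---------------------------------------------------------------------------
# abundance scaling and scans


def scale_initial_conditions(profile: dict[str, float], config: ModelConfig,
                             notes: list[str] | None = None) -> ModelConfig:
    """Scale species abundances by relative transcript levels.

    KPNA1–7 aggregate onto Imp-α as the mean of their relative levels (equal
    base isoform shares).  Unmapped genes are ignored; mapped genes absent
    from the profile fall back to base with a note.
    """
    for g, v in profile.items():
        if g in TRANSCRIPT_MAP and not v > 0:
            raise ValueError(f"gene {g}: relative level must be > 0")
    factors: dict[str, float] = {}
    kpna = [v for g, v in profile.items() if TRANSCRIPT_MAP.get(g) == "ImpA"]
    if kpna:
        factors["ImpA"] = float(np.mean(kpna))
    for gene, sp in TRANSCRIPT_MAP.items():
        if sp == "ImpA":
            continue
        if gene in profile:
            factors[sp] = float(profile[gene])
    scaled = {}
    for sp, (conc, _) in config.species.items():
        if sp in factors:
            scaled[sp] = conc * factors[sp]
        elif notes is not None:
            notes.append(f"{sp}: no transcript in profile, kept at base")
    return config.with_species(scaled)


def sensitivity_scan(config: ModelConfig, species: str, fold_grid,
                     cargoes: list[CargoSpec]):
    """Steady-state N/C of each cargo across fold-changes of one species.

    Returns a dict cargo name → list of (fold, nc_ratio, converged).
    Each cargo is simulated separately, as in the reporter experiments.
    """
    fold_grid = np.asarray(fold_grid, float)
    if np.any(fold_grid <= 0):
        raise ValueError("fold multipliers must be > 0")
    base_conc = config.species[species][0]
    out = {c.name: [] for c in cargoes}
    for cargo in cargoes:
        for fold in fold_grid:
            # no warm start: the initial state fixes the conserved totals,
            # which differ at every grid point
            cfg = config.with_species({species: base_conc * fold})
            model = add_cargo(build_network(cfg), cargo)
            res = steady_state(model, cargo.name)
            out[cargo.name].append((float(fold), res.nc_ratio, res.converged))
    return out


def stratified_prediction_test(values, stratifier, percentile: float = 65.0):
    """Split samples at an abundance percentile and rank-sum test the split.

    The high group is the top ⌈(100−percentile)/100·n⌉ samples of the
    stratifier (ties broken by stable sample order); returns group medians
    and the one-sided Mann-Whitney p for high > low.
    """
    values = np.asarray(values, float)
    stratifier = np.asarray(stratifier, float)
    if values.shape != stratifier.shape:
        raise ValueError("values and stratifier must align")
    if np.ptp(stratifier) == 0:
        raise ValueError("degenerate stratifier: all values tied")
    n = len(values)
    n_high = int(np.ceil((100.0 - percentile) / 100.0 * n))
    order = np.argsort(-stratifier, kind="stable")
    high_idx = np.sort(order[:n_high])
    mask = np.zeros(n, bool)
    mask[high_idx] = True
    high, low = values[mask], values[~mask]
    if len(high) < 3 or len(low) < 3:
        raise ValueError("need >= 3 samples per group after the split")
    stat, p = stats.mannwhitneyu(high, low, alternative="greater")
    return {
        "median_high": float(np.median(high)),
        "median_low": float(np.median(low)),
        "n_high": len(high),
        "n_low": len(low),
        "u_statistic": float(stat),
        "p_one_sided": float(p),
        "direction": "high>low",
    }
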