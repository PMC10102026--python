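"""Compartmental mass-action reaction networks.

The model state is the concentration (µM) of every species *instance*, i.e.
every (species, compartment) pair the network declares.  Reactions are
elementary mass-action steps with at most two reactant molecules; transport
steps move one molecule between compartments.  Rates are defined with respect
to a reference compartment volume, so fluxes are converted with volume ratios
and volume-weighted moiety totals are conserved exactly by construction.

Units: concentrations in µM, volumes in fL, time in s, bimolecular rate
constants in µM⁻¹ s⁻¹, unimolecular in s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CYTOPLASM = "cytoplasm"
NUCLEUS = "nucleus"
PORE = "pore"
COMPARTMENT_NAMES = (CYTOPLASM, NUCLEUS, PORE)

#: species-name parts that count as one Ran moiety
_RAN_PARTS = {"RanGTP", "RanGDP"}


@dataclass(frozen=True)
class Compartment:
    name: str
    volume: float  # fL

    def __post_init__(self):
        if self.name not in COMPARTMENT_NAMES:
            raise ValueError(f"unknown compartment {self.name!r}")
        if not self.volume > 0:
            raise ValueError(f"compartment {self.name}: volume must be > 0")


def species_composition(name: str) -> dict[str, int]:
    """Moiety composition of a species from its colon-separated name.

    ``"CAS:RanGTP:ImpA"`` → ``{"CAS": 1, "Ran": 1, "ImpA": 1}``.  Both
    nucleotide states of Ran map to the single conserved "Ran" moiety.
    """
    comp: dict[str, int] = {}
    for part in name.split(":"):
        moiety = "Ran" if part in _RAN_PARTS else part
        comp[moiety] = comp.get(moiety, 0) + 1
    return comp


@dataclass(frozen=True)
class Reaction:
    """Elementary mass-action reaction inside one compartment, or a
    one-molecule transport step between compartments.

    ``reactants`` / ``products`` are tuples of (species, compartment) pairs.
    The rate is ``k * Π [reactant]`` referenced to ``rate_compartment``.
    """

    name: str
    reactants: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    k: float
    rate_compartment: str

    def __post_init__(self):
        if self.k < 0:
            raise ValueError(f"reaction {self.name}: negative rate constant")
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError(f"reaction {self.name}: needs 1 or 2 reactant molecules")


class ReactionNetwork:
    """A set of compartments, species instances and mass-action reactions.

    Species instances are registered lazily; ``compile()`` freezes the state
    ordering and builds the vectorized rate/stoichiometry arrays.
    """

    def __init__(self, compartments: dict[str, Compartment]):
        missing = set(COMPARTMENT_NAMES) - set(compartments)
        if missing:
            raise ValueError(f"missing compartments: {sorted(missing)}")
        self.compartments = dict(compartments)
        self._index: dict[tuple[str, str], int] = {}
        self._states: list[tuple[str, str]] = []
        self._x0: list[float] = []
        self.reactions: list[Reaction] = []
        self._compiled = False

    # -- construction -------------------------------------------------------

    def add_state(self, species: str, compartment: str, conc: float = 0.0) -> int:
        if compartment not in self.compartments:
            raise ValueError(f"unknown compartment {compartment!r}")
        if conc < 0:
            raise ValueError(f"{species}@{compartment}: negative concentration")
        key = (species, compartment)
        if key in self._index:
            if conc:
                self._x0[self._index[key]] += conc
            return self._index[key]
        self._index[key] = len(self._states)
        self._states.append(key)
        self._x0.append(conc)
        self._compiled = False
        return self._index[key]

    def has_state(self, species: str, compartment: str) -> bool:
        return (species, compartment) in self._index

    def has_species(self, species: str) -> bool:
        return any(s == species for s, _ in self._states)

    def add_reaction(self, rxn: Reaction) -> None:
        for sp, comp in rxn.reactants + rxn.products:
            if (sp, comp) not in self._index:
                raise ValueError(
                    f"reaction {rxn.name}: unknown species instance {sp}@{comp}"
                )
        self._check_balance(rxn)
        self.reactions.append(rxn)
        self._compiled = False

    def _check_balance(self, rxn: Reaction) -> None:
        lhs: dict[str, int] = {}
        rhs: dict[str, int] = {}
        for side, acc in ((rxn.reactants, lhs), (rxn.products, rhs)):
            for sp, _ in side:
                for m, n in species_composition(sp).items():
                    acc[m] = acc.get(m, 0) + n
        if lhs != rhs:
            raise ValueError(f"reaction {rxn.name}: moiety imbalance {lhs} != {rhs}")

    # -- compiled views -----------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self._states)

    @property
    def states(self) -> list[tuple[str, str]]:
        return list(self._states)

    def state_index(self, species: str, compartment: str) -> int:
        return self._index[(species, compartment)]

    @property
    def x0(self) -> np.ndarray:
        return np.asarray(self._x0, dtype=float)

    def set_initial(self, species: str, compartment: str, conc: float) -> None:
        if conc < 0:
            raise ValueError("negative concentration")
        self._x0[self._index[(species, compartment)]] = conc

    def compile(self) -> None:
        if self._compiled:
            return
        n = self.n_states
        m = len(self.reactions)
        self._k = np.array([r.k for r in self.reactions])
        self._r1 = np.zeros(m, dtype=np.intp)
        self._r2 = np.full(m, -1, dtype=np.intp)
        vols = np.array(
            [self.compartments[c].volume for _, c in self._states]
        )
        self._volumes = vols
        self._Neff = np.zeros((n, m))
        for j, rxn in enumerate(self.reactions):
            vref = self.compartments[rxn.rate_compartment].volume
            idxs = [self._index[p] for p in rxn.reactants]
            self._r1[j] = idxs[0]
            if len(idxs) == 2:
                self._r2[j] = idxs[1]
            for p in rxn.reactants:
                i = self._index[p]
                self._Neff[i, j] -= vref / vols[i]
            for p in rxn.products:
                i = self._index[p]
                self._Neff[i, j] += vref / vols[i]
        self._bimol = self._r2 >= 0
        self._compiled = True

    # -- dynamics -----------------------------------------------------------

    def rates(self, x: np.ndarray) -> np.ndarray:
        self.compile()
        v = self._k * x[self._r1]
        v[self._bimol] *= x[self._r2[self._bimol]]
        return v

    def rhs(self, x: np.ndarray) -> np.ndarray:
        self.compile()
        return self._Neff @ self.rates(x)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        self.compile()
        m = len(self.reactions)
        dv = np.zeros((m, self.n_states))
        rows = np.arange(m)
        uni = ~self._bimol
        dv[rows[uni], self._r1[uni]] = self._k[uni]
        bi = self._bimol
        np.add.at(dv, (rows[bi], self._r1[bi]), self._k[bi] * x[self._r2[bi]])
        np.add.at(dv, (rows[bi], self._r2[bi]), self._k[bi] * x[self._r1[bi]])
        return self._Neff @ dv

    # -- conservation -------------------------------------------------------

    def moieties(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp, _ in self._states:
            for mo in species_composition(sp):
                seen.setdefault(mo)
        return list(seen)

    def moiety_matrix(self) -> tuple[list[str], np.ndarray]:
        """Rows = moieties; W @ x gives volume-weighted totals (µM·fL)."""
        self.compile()
        mos = self.moieties()
        W = np.zeros((len(mos), self.n_states))
        for i, (sp, comp) in enumerate(self._states):
            cm = species_composition(sp)
            for r, mo in enumerate(mos):
                if mo in cm:
                    W[r, i] = cm[mo] * self.compartments[comp].volume
        return mos, W

    def conserved_totals(self, x: np.ndarray) -> dict[str, float]:
        mos, W = self.moiety_matrix()
        return dict(zip(mos, W @ x))

    def copy(self) -> "ReactionNetwork":
        net = ReactionNetwork(self.compartments)
        for (sp, comp), c0 in zip(self._states, self._x0):
            net.add_state(sp, comp, c0)
        net.reactions = list(self.reactions)
        return net

    def summary(self) -> dict[str, int]:
        return {
            "n_species": len({s for s, _ in self._states}),
            "n_states": self.n_states,
            "n_reactions": len(self.reactions),
        }
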