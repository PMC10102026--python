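"""Model configuration loading (TOML, with a TSV option for species tables)."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .network import COMPARTMENT_NAMES


@dataclass
class PoreClass:
    count: float
    selectivity: str = "all"  # all | classical | ibb | nls

    def admits(self, species: str, classical_cargo: set[str], ibb_cargo: set[str]) -> bool:
        """Whether this pore class translocates the given species.

        Selective classes gate only cargo-bearing complexes by NLS class;
        free carriers and Ran-cycle components always pass.
        """
        if self.selectivity == "all":
            return True
        parts = set(species.split(":"))
        cargo_parts = parts & (classical_cargo | ibb_cargo)
        if not cargo_parts:
            return True
        if self.selectivity == "classical":
            return bool(parts & classical_cargo)
        if self.selectivity == "ibb":
            return bool(parts & ibb_cargo)
        if self.selectivity == "nls":  # any recognized import signal
            return bool(parts & (classical_cargo | ibb_cargo))
        raise ValueError(f"unknown selectivity {self.selectivity!r}")


@dataclass
class PoreConfig:
    classes: list[PoreClass]
    reference_count: float = 2770.0

    def __post_init__(self):
        if not 1 <= len(self.classes) <= 2:
            raise ValueError("1 or 2 pore classes supported")
        for c in self.classes:
            if not c.count > 0:
                raise ValueError("pore count must be > 0")
        if len(self.classes) == 1 and self.classes[0].selectivity != "all":
            raise ValueError("a single pore class must admit all carriers")


@dataclass
class ModelConfig:
    compartments: dict[str, float]          # name -> volume (fL)
    species: dict[str, tuple[float, str]]   # name -> (µM, home compartment)
    rates: dict[str, float]
    pores: PoreConfig

    def __post_init__(self):
        for name in COMPARTMENT_NAMES:
            if name not in self.compartments:
                raise ValueError(f"missing compartment {name!r}")
        for name, (conc, comp) in self.species.items():
            if conc < 0:
                raise ValueError(f"species {name}: negative concentration")
            if comp not in self.compartments:
                raise ValueError(f"species {name}: unknown compartment {comp!r}")
        for name, k in self.rates.items():
            if k < 0:
                raise ValueError(f"rate {name}: negative value")

    def rate(self, name: str) -> float:
        """Look up a rate constant; a missing rate is an error, never a default."""
        try:
            return self.rates[name]
        except KeyError:
            raise KeyError(f"rate constant {name!r} missing from configuration") from None

    def with_species(self, scaled: dict[str, float]) -> "ModelConfig":
        sp = dict(self.species)
        for name, conc in scaled.items():
            if name not in sp:
                raise KeyError(f"unknown species {name!r}")
            sp[name] = (conc, sp[name][1])
        return ModelConfig(dict(self.compartments), sp, dict(self.rates), self.pores)


def _parse(doc: dict) -> ModelConfig:
    species = {
        name: (float(entry["conc"]), str(entry["compartment"]))
        for name, entry in doc["species"].items()
    }
    pores_doc = doc.get("pores", {})
    classes = [
        PoreClass(float(c["count"]), c.get("selectivity", "all"))
        for c in pores_doc.get("classes", [{"count": 2770.0}])
    ]
    pores = PoreConfig(classes, float(pores_doc.get("reference_count", 2770.0)))
    return ModelConfig(
        compartments={k: float(v) for k, v in doc["compartments"].items()},
        species=species,
        rates={k: float(v) for k, v in doc["rates"].items()},
        pores=pores,
    )


def load_config(path: str | Path) -> ModelConfig:
    with open(path, "rb") as fh:
        return _parse(tomllib.load(fh))


def default_config() -> ModelConfig:
    text = resources.files("nct.data").joinpath("base_model.toml").read_bytes()
    return _parse(tomllib.loads(text.decode()))


def load_species_tsv(path: str | Path) -> dict[str, tuple[float, str]]:
    """Species table as TSV with columns: species, conc_uM, compartment."""
    species = {}
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].rstrip("\n").split("\t")
    expected = ["species", "conc_uM", "compartment"]
    if [h.strip() for h in header] != expected:
        raise ValueError(f"species TSV must have columns {expected}")
    for line in lines[1:]:
        name, conc, comp = line.rstrip("\n").split("\t")
        species[name] = (float(conc), comp)
    return species
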