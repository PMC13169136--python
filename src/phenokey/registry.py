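"""Editable rule registries: acyl residues, hexaric ester substituents,
sugars, aglycones and backbone signatures.

The shipped YAML files under :mod:`phenokey.registries` encode the
diagnostic-ion knowledge the annotation key runs on; all of them can be
replaced by pointing :func:`load_registries` (or the CLI ``--registries``
flag) at a directory with alternate files of the same layout.

Marker m/z values left ``null`` in the YAML are derived from the residue's
neutral-loss formula under the package ion convention:

* ``acid``            -- loss + H2O - proton (the free-acid anion)
* ``decarboxylated``  -- acid - CO2
* ``dehydrated``      -- acid - H2O
* ``demethylated``    -- acid - CO2 - CH3 (radical anion)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .chem import Formula, monoisotopic_mass, PROTON_MASS

__all__ = [
    "AcylResidue",
    "EsterSubstituent",
    "Sugar",
    "Aglycone",
    "BackboneSignature",
    "Registries",
    "load_registries",
]

_H2O = monoisotopic_mass("H2O")
_CO2 = monoisotopic_mass("CO2")
_CH3 = monoisotopic_mass("CH3")

_MARKER_DERIVATION = {
    "acid": lambda acid: acid,
    "decarboxylated": lambda acid: acid - _CO2,
    "dehydrated": lambda acid: acid - _H2O,
    "demethylated": lambda acid: acid - _CO2 - _CH3,
}


def _derive_markers(loss: Formula, markers: dict | None) -> dict[str, float]:
    acid_mz = loss.mass + _H2O - PROTON_MASS
    out: dict[str, float] = {}
    for role, mz in (markers or {}).items():
        if mz is not None:
            out[role] = float(mz)
        elif role in _MARKER_DERIVATION:
            out[role] = _MARKER_DERIVATION[role](acid_mz)
        else:
            raise ValueError(f"marker role {role!r} has no m/z and no derivation")
    return out


@dataclass(frozen=True)
class AcylResidue:
    """An acyl residue: its ester neutral loss and diagnostic marker ions."""

    name: str
    loss: Formula
    contexts: frozenset[str]
    markers: dict[str, float] = field(default_factory=dict)

    @property
    def loss_mass(self) -> float:
        return self.loss.mass

    @property
    def acid_anion_mz(self) -> float:
        return self.markers.get("acid", self.loss.mass + _H2O - PROTON_MASS)


@dataclass(frozen=True)
class EsterSubstituent:
    """A small ester substituent of a hexaric core (attach = acid - H2O)."""

    name: str
    attach: Formula
    acid: Formula
    markers: dict[str, float] = field(default_factory=dict)

    @property
    def attach_mass(self) -> float:
        return self.attach.mass


@dataclass(frozen=True)
class Sugar:
    name: str
    loss: Formula

    @property
    def loss_mass(self) -> float:
        return self.loss.mass


@dataclass(frozen=True)
class Aglycone:
    name: str
    formula: Formula
    compound_class: str
    isobaric_with: str | None = None

    @property
    def anion_mz(self) -> float:
        return self.formula.mass - PROTON_MASS

    @property
    def label(self) -> str:
        """Reported name; isobaric partners are collapsed to an either/or."""
        if self.isobaric_with:
            pair = sorted([self.name, self.isobaric_with])
            return "/".join(pair)
        return self.name


@dataclass(frozen=True)
class BackboneSignature:
    name: str
    neutral: Formula
    positions: tuple[int, ...]
    series: tuple[tuple[float, str], ...]  # (m/z, ion label)

    @property
    def anion_mz(self) -> float:
        return self.neutral.mass - PROTON_MASS


@dataclass(frozen=True)
class Registries:
    """The full rule-registry bundle the annotation key consumes."""

    acyls: dict[str, AcylResidue]
    esters: dict[str, EsterSubstituent]
    sugars: dict[str, Sugar]
    cross_ring_losses: dict[str, Formula]
    aglycones: dict[str, Aglycone]
    backbones: dict[str, BackboneSignature]

    def acyls_in_context(self, context: str) -> list[AcylResidue]:
        return [a for a in self.acyls.values() if context in a.contexts]


def _read_yaml(directory: Path | None, filename: str) -> dict:
    if directory is not None:
        text = (Path(directory) / filename).read_text(encoding="utf-8")
    else:
        text = (
            resources.files("phenokey.registries").joinpath(filename).read_text("utf-8")
        )
    return yaml.safe_load(text)


def load_registries(directory: str | Path | None = None) -> Registries:
    """Load all registries from ``directory``, or the shipped defaults."""
    directory = Path(directory) if directory is not None else None

    acyls = {}
    for name, entry in _read_yaml(directory, "acyls.yaml")["acyls"].items():
        loss = Formula(entry["loss"])
        acyls[name] = AcylResidue(
            name=name,
            loss=loss,
            contexts=frozenset(entry.get("contexts", [])),
            markers=_derive_markers(loss, entry.get("markers")),
        )

    esters = {}
    for name, entry in _read_yaml(directory, "esters.yaml")["esters"].items():
        attach = Formula(entry["attach"])
        esters[name] = EsterSubstituent(
            name=name,
            attach=attach,
            acid=Formula(entry["acid"]),
            markers=_derive_markers(attach, entry.get("markers")),
        )

    sugar_doc = _read_yaml(directory, "sugars.yaml")
    sugars = {
        name: Sugar(name=name, loss=Formula(entry["loss"]))
        for name, entry in sugar_doc["sugars"].items()
    }
    cross_ring = {
        label: Formula(formula)
        for label, formula in sugar_doc["cross_ring_losses"].items()
    }

    aglycones = {}
    for name, entry in _read_yaml(directory, "aglycones.yaml")["aglycones"].items():
        aglycones[name] = Aglycone(
            name=name,
            formula=Formula(entry["formula"]),
            compound_class=entry["class"],
            isobaric_with=entry.get("isobaric_with"),
        )

    backbones = {}
    for name, entry in _read_yaml(directory, "backbones.yaml")["backbones"].items():
        backbones[name] = BackboneSignature(
            name=name,
            neutral=Formula(entry["neutral"]),
            positions=tuple(entry["positions"]),
            series=tuple((float(s["mz"]), s["label"]) for s in entry["series"]),
        )

    return Registries(
        acyls=acyls,
        esters=esters,
        sugars=sugars,
        cross_ring_losses=cross_ring,
        aglycones=aglycones,
        backbones=backbones,
    )
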