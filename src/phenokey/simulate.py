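"""Ground-truthed synthetic MS/MS spectra for end-to-end testing.

The generator inverts the annotation key: given a structure (backbone, acyl
positions, sugar decoration, ester substituent) it emits the [M-H]- ion,
the full sequential-loss ladder, the backbone diagnostic series, residue
marker ions and a base-peak placement that follows the regiochemistry rules
(5-acyl quinate -> 191-dominant with suppressed acid ions, 4-acyl ->
173-dominant, 3-acyl -> prominent acid anion, ...).  Abundance archetypes
are fixed lookup profiles resembling published spectra of each regio class;
no physical fragmentation model is attempted.

A :class:`NoiseModel` then applies a ppm-scale calibration bias to every
fragment m/z (high-resolution MS2 axes commonly read a few ppm low against
theory; the default bias is -5 ppm), multiplicative log-normal abundance
jitter, and uniform decoy peaks.  A single integer seed drives named
substreams, so jitter and decoys are independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import Registries, load_registries
from .rules import AnnotationConfig, AnnotationResult, annotate
from .spectra import FragmentPeak, MsMsSpectrum

__all__ = [
    "StructureSpec",
    "NoiseModel",
    "synthesize_spectrum",
    "enumerate_structures",
    "generate_dataset",
    "truth_matches",
    "evaluate_recovery",
]

_QUINIC_POSITIONS = (1, 3, 4, 5)
_HEXARIC_POSITIONS = (2, 3, 4, 5)


@dataclass(frozen=True)
class StructureSpec:
    """Ground-truth structure for one synthetic spectrum.

    ``backbone`` is ``"quinic"``, ``"hexaric"`` or an aglycone name from
    the aglycone registry (flavonoid or phenolic acid).  ``acyl_positions``
    maps backbone positions to acyl residue names; ``ester`` is the
    optional small ester substituent of a hexaric core; ``sugar`` +
    ``linkage`` decorate an aglycone backbone.
    """

    backbone: str
    acyl_positions: tuple[tuple[int, str], ...] = ()
    ester: str | None = None
    sugar: str | None = None
    linkage: str = "O-glycoside"

    def validate(self, reg: Registries) -> None:
        positions = [p for p, _ in self.acyl_positions]
        if len(set(positions)) != len(positions):
            raise ValueError("at most one acyl decoration per site")
        if self.backbone in ("quinic", "hexaric"):
            valid = (
                _QUINIC_POSITIONS if self.backbone == "quinic" else _HEXARIC_POSITIONS
            )
            bad = [p for p in positions if p not in valid]
            if bad:
                raise ValueError(
                    f"invalid position(s) {bad} for {self.backbone} backbone"
                )
            if not self.acyl_positions:
                raise ValueError(f"{self.backbone} spec needs >= 1 acyl")
            for _, r in self.acyl_positions:
                if r not in reg.acyls:
                    raise ValueError(f"unknown acyl residue {r!r}")
            if self.ester is not None:
                if self.backbone != "hexaric":
                    raise ValueError("ester substituents only on hexaric cores")
                if self.ester not in reg.esters:
                    raise ValueError(f"unknown ester substituent {self.ester!r}")
                if len(positions) + 1 > len(_HEXARIC_POSITIONS):
                    raise ValueError("no free site left for the ester")
            if self.sugar is not None:
                raise ValueError("sugar decorations only on aglycone backbones")
        else:
            if self.backbone not in reg.aglycones:
                raise ValueError(f"unknown backbone/aglycone {self.backbone!r}")
            if self.acyl_positions or self.ester:
                raise ValueError("acyl positions apply to quinic/hexaric cores only")
            if self.sugar is not None and self.sugar not in reg.sugars:
                raise ValueError(f"unknown sugar {self.sugar!r}")

    @property
    def acyl_names(self) -> tuple[str, ...]:
        return tuple(sorted(r for _, r in self.acyl_positions))

    def truth(self, reg: Registries) -> dict:
        """The expected annotation, as a flat record."""
        if self.backbone == "quinic":
            cls = "acylquinic acid"
        elif self.backbone == "hexaric":
            cls = "caffeoylhexaric acid"
        else:
            agl = reg.aglycones[self.backbone]
            if self.sugar is None:
                cls = (
                    "flavonoid aglycone"
                    if agl.compound_class == "flavonoid"
                    else "phenolic acid"
                )
            else:
                cls = (
                    "flavonoid glycoside"
                    if agl.compound_class == "flavonoid"
                    else "phenolic-acid glycoside/ester"
                )
        return {
            "class": cls,
            "backbone": self.backbone if self.backbone in ("quinic", "hexaric") else "",
            "acyls": ",".join(self.acyl_names),
            # the key resolves positions on the quinic backbone only: CHA
            # ester sites are not claimed, so they are not scored either
            "positions": (
                ";".join(f"{p}:{r}" for p, r in sorted(self.acyl_positions))
                if self.backbone == "quinic"
                else ""
            ),
            "ester": self.ester or "",
            "aglycone": (
                "" if self.backbone in ("quinic", "hexaric") else self.backbone
            ),
            "sugar": self.sugar or "",
            "linkage": self.linkage if self.sugar else "",
        }


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections applied to an exact rule-derived spectrum."""

    calibration_bias_ppm: float = -5.0
    abundance_jitter: float = 0.15  # sd of log-normal multiplicative noise
    decoy_peaks: int = 3
    decoy_abundance: tuple[float, float] = (1.0, 10.0)
    seed: int = 0

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(calibration_bias_ppm=0.0, abundance_jitter=0.0, decoy_peaks=0)


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


class _PeakSet:
    """Accumulates (m/z, abundance); near-duplicates keep the larger."""

    def __init__(self):
        self.peaks: list[list[float]] = []

    def add(self, mz: float, abundance: float) -> None:
        for p in self.peaks:
            if abs(p[0] - mz) < 1e-3:
                p[1] = max(p[1], abundance)
                return
        self.peaks.append([mz, abundance])

    def build(self, precursor: float) -> tuple[FragmentPeak, ...]:
        return tuple(
            FragmentPeak(mz, ab)
            for mz, ab in sorted(self.peaks)
            if 0 < mz <= precursor + 1e-6 and ab > 0
        )


def _quinic_fragments(spec: StructureSpec, reg: Registries, ps: _PeakSet) -> float:
    backbone = reg.backbones["quinic"]
    residues = dict(spec.acyl_positions)
    losses = [reg.acyls[r].loss_mass for r in residues.values()]
    precursor = backbone.anion_mz + sum(losses)
    positions = sorted(residues)
    n = len(positions)

    # base-peak archetypes per regio class (cf. published monoester and
    # diester spectra); series abundances follow
    series_ab = {"[QA-H]-": 100.0, "[QA-H-H2O]-": 5.0}
    acid_ab = {p: 2.0 for p in positions}
    if n == 1:
        p = positions[0]
        if p == 4:
            series_ab = {"[QA-H]-": 55.0, "[QA-H-H2O]-": 100.0}
            acid_ab[p] = 65.0
        elif p in (1, 3):
            acid_ab[p] = 60.0
        ps.add(precursor, 30.0)
    else:
        vicinal = 4 in positions
        # the acyl on the highest non-4 position departs first
        non4 = [p for p in positions if p != 4]
        first = max(non4) if non4 else positions[-1]
        if vicinal:
            series_ab = {"[QA-H]-": 30.0, "[QA-H-H2O]-": 100.0}
        for p in positions:
            acid_ab[p] = 30.0
        ps.add(precursor, 25.0)
        # sequential losses: [M-H-first]- prominent, the other(s) faint
        for p in positions:
            ion = precursor - reg.acyls[residues[p]].loss_mass
            ps.add(ion, 70.0 if p == first else 3.0)
        if n == 3:
            # full ladder down to the quinate ion
            mz = precursor
            for k, p in enumerate(sorted(positions, reverse=True)):
                mz -= reg.acyls[residues[p]].loss_mass
                ps.add(mz, 48.0 - 8 * k)

    for mz, label in backbone.series:
        default = {"[QA-H-2H2O-CO2]-": 3.0, "[QA-H-3H2O-CO2]-": 8.0}.get(label, 7.0)
        ps.add(mz, series_ab.get(label, default))
    for p in positions:
        residue = reg.acyls[residues[p]]
        a = acid_ab[p]
        ps.add(residue.acid_anion_mz, a)
        for role, mz in residue.markers.items():
            if role != "acid":
                ps.add(mz, a * 0.8)
    return precursor


def _hexaric_fragments(spec: StructureSpec, reg: Registries, ps: _PeakSet) -> float:
    backbone = reg.backbones["hexaric"]
    caffeoyl = reg.acyls["caffeoyl"]
    n_caf = len(spec.acyl_positions)
    ester = reg.esters[spec.ester] if spec.ester else None
    precursor = (
        backbone.anion_mz
        + n_caf * caffeoyl.loss_mass
        + (ester.attach_mass if ester else 0.0)
    )
    ps.add(precursor, 40.0)
    # caffeoyl ladder first, ester cleaved last (leontopodic-A pattern)
    mz = precursor
    for k in range(n_caf):
        mz -= caffeoyl.loss_mass
        ps.add(mz, 60.0 - 12 * k)
    if ester is not None:
        ps.add(mz - ester.attach_mass, 70.0)  # = hexarate anion
        for role, marker_mz in ester.markers.items():
            ps.add(marker_mz, 35.0)
    series_ab = {"[HA-H]-": 70.0, "[HA-H-H2O]-": 100.0}
    for smz, label in backbone.series:
        ps.add(smz, series_ab.get(label, 15.0))
    ps.add(caffeoyl.acid_anion_mz, 50.0)
    for role, marker_mz in caffeoyl.markers.items():
        if role != "acid":
            ps.add(marker_mz, 40.0)
    return precursor


def _glycoside_fragments(spec: StructureSpec, reg: Registries, ps: _PeakSet) -> float:
    agl = reg.aglycones[spec.backbone]
    if spec.sugar is None:
        precursor = agl.anion_mz
        ps.add(precursor, 100.0)
        return precursor
    sugar = reg.sugars[spec.sugar]
    precursor = agl.anion_mz + sugar.loss_mass
    ps.add(precursor, 25.0)
    ps.add(agl.anion_mz, 100.0)
    if spec.linkage == "sugar ester":
        for formula in reg.cross_ring_losses.values():
            ps.add(precursor - formula.mass, 25.0)
    if spec.sugar == "caffeoylhexose":
        caffeoyl = reg.acyls["caffeoyl"]
        ps.add(precursor - caffeoyl.loss_mass, 30.0)
        for mz in caffeoyl.markers.values():
            ps.add(mz, 20.0)
    return precursor


def synthesize_spectrum(
    spec: StructureSpec,
    noise: NoiseModel | None = None,
    registries: Registries | None = None,
    identifier: str = "synthetic",
) -> tuple[MsMsSpectrum, dict]:
    """Emit one rule-consistent spectrum plus its ground-truth record.

    With ``NoiseModel.zero()`` (the default) the spectrum is exact: every
    fragment sits on its theoretical m/z and the archetype abundances are
    untouched.
    """
    reg = registries or load_registries()
    spec.validate(reg)
    noise = noise or NoiseModel.zero()

    ps = _PeakSet()
    if spec.backbone == "quinic":
        precursor = _quinic_fragments(spec, reg, ps)
    elif spec.backbone == "hexaric":
        precursor = _hexaric_fragments(spec, reg, ps)
    else:
        precursor = _glycoside_fragments(spec, reg, ps)
    raw = [(p.mz, p.abundance) for p in ps.build(precursor)]

    if noise.decoy_peaks > 0:
        rng = _stream(noise.seed, f"decoys:{identifier}")
        lo, hi = noise.decoy_abundance
        for _ in range(noise.decoy_peaks):
            raw.append(
                (float(rng.uniform(80.0, precursor)), float(rng.uniform(lo, hi)))
            )
    if noise.abundance_jitter > 0:
        rng = _stream(noise.seed, f"jitter:{identifier}")
        factors = np.exp(rng.normal(0.0, noise.abundance_jitter, size=len(raw)))
        raw = [(mz, ab * f) for (mz, ab), f in zip(raw, factors)]
    bias = 1.0 + noise.calibration_bias_ppm * 1e-6
    top = max(ab for _, ab in raw)
    peaks = [
        FragmentPeak(mz * bias, ab * 100.0 / top) for mz, ab in raw
    ]

    spectrum = MsMsSpectrum(
        identifier=identifier,
        precursor_mz=precursor * bias,
        peaks=tuple(peaks),
        formula=None,
        metadata={"synthetic": "true"},
    ).normalized()
    truth = {"id": identifier, "precursor_mz": precursor, **spec.truth(reg)}
    return spectrum, truth


# ---------------------------------------------------------------------------
# shipped structure enumeration and dataset generation


def enumerate_structures(registries: Registries | None = None) -> list[StructureSpec]:
    """The shipped enumeration of valid structures (round-trip test set)."""
    reg = registries or load_registries()
    specs: list[StructureSpec] = []
    mono_residues = [
        "caffeoyl", "feruloyl", "p-coumaroyl", "dihydrocaffeoyl",
        "hydroxydihydrocaffeoyl",
    ]
    for pos in (3, 4, 5):
        for r in mono_residues:
            specs.append(StructureSpec("quinic", ((pos, r),)))
    for pair in ((3, 5), (1, 5), (3, 4), (4, 5), (1, 4)):
        specs.append(
            StructureSpec("quinic", ((pair[0], "caffeoyl"), (pair[1], "caffeoyl")))
        )
    for pair in ((3, 5), (4, 5)):
        for other in ("feruloyl", "p-coumaroyl"):
            specs.append(
                StructureSpec("quinic", ((pair[0], "caffeoyl"), (pair[1], other)))
            )
            specs.append(
                StructureSpec("quinic", ((pair[0], other), (pair[1], "caffeoyl")))
            )
    specs.append(
        StructureSpec(
            "quinic", ((3, "caffeoyl"), (4, "caffeoyl"), (5, "caffeoyl"))
        )
    )
    for k in (1, 2, 3, 4):
        specs.append(
            StructureSpec(
                "hexaric", tuple((p, "caffeoyl") for p in _HEXARIC_POSITIONS[:k])
            )
        )
    for ester in reg.esters:
        specs.append(
            StructureSpec(
                "hexaric",
                ((2, "caffeoyl"), (3, "caffeoyl"), (4, "caffeoyl")),
                ester=ester,
            )
        )
    flavonoids = [
        n for n, a in reg.aglycones.items() if a.compound_class == "flavonoid"
    ]
    phenolics = [
        n for n, a in reg.aglycones.items() if a.compound_class == "phenolic-acid"
    ]
    for name in flavonoids:
        specs.append(StructureSpec(name, sugar="hexose"))
        specs.append(StructureSpec(name))
    specs.append(StructureSpec("quercetin", sugar="rutinosyl"))
    specs.append(StructureSpec("kaempferol", sugar="di-hexose"))
    specs.append(StructureSpec("myricetin", sugar="acetylhexose"))
    specs.append(StructureSpec("apigenin", sugar="caffeoylhexose"))
    for name in phenolics:
        specs.append(StructureSpec(name, sugar="hexose"))
        specs.append(StructureSpec(name))
    specs.append(
        StructureSpec("hydroxybenzoic acid", sugar="hexose", linkage="sugar ester")
    )
    specs.append(
        StructureSpec("vanillic acid", sugar="hexose", linkage="sugar ester")
    )
    return specs


_CLASS_KEYS = (
    "acylquinic acid",
    "caffeoylhexaric acid",
    "flavonoid glycoside",
    "flavonoid aglycone",
    "phenolic-acid glycoside/ester",
    "phenolic acid",
    "decoy",
)

#: default class mix for generated datasets: proportional to the profiled
#: class sizes (39 AQA : 26 CHA : 34 phenolics : 31 flavonoids), flavonoids
#: and phenolics split between glycosides and free forms
DEFAULT_CLASS_MIX = {
    "acylquinic acid": 0.30,
    "caffeoylhexaric acid": 0.20,
    "flavonoid glycoside": 0.15,
    "flavonoid aglycone": 0.09,
    "phenolic-acid glycoside/ester": 0.16,
    "phenolic acid": 0.10,
}


def _decoy_spectrum(rng: np.random.Generator, identifier: str) -> tuple[MsMsSpectrum, dict]:
    precursor = float(rng.uniform(300.0, 900.0))
    n = int(rng.integers(8, 16))
    peaks = tuple(
        FragmentPeak(float(mz), float(ab))
        for mz, ab in zip(
            rng.uniform(80.0, precursor, size=n), rng.uniform(1.0, 100.0, size=n)
        )
    )
    spectrum = MsMsSpectrum(
        identifier=identifier, precursor_mz=precursor, peaks=peaks
    ).normalized()
    truth = {
        "id": identifier, "precursor_mz": precursor, "class": "decoy",
        "backbone": "", "acyls": "", "positions": "", "ester": "",
        "aglycone": "", "sugar": "", "linkage": "",
    }
    return spectrum, truth


def generate_dataset(
    n: int,
    class_mix: dict[str, float] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    registries: Registries | None = None,
) -> tuple[list[MsMsSpectrum], pd.DataFrame]:
    """Draw ``n`` ground-truthed spectra with the requested class mix."""
    if n <= 0:
        raise ValueError(f"dataset size must be positive, got {n}")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    bad = [c for c in mix if c not in _CLASS_KEYS]
    if bad:
        raise ValueError(f"unknown class(es) in mix: {bad}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class-mix proportions must sum to 1, got {total}")
    reg = registries or load_registries()
    noise = noise if noise is not None else NoiseModel(seed=seed)
    by_class: dict[str, list[StructureSpec]] = {c: [] for c in _CLASS_KEYS}
    for spec in enumerate_structures(reg):
        by_class[spec.truth(reg)["class"]].append(spec)

    rng = _stream(seed, "dataset")
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    draws = rng.choice(len(classes), size=n, p=probs / probs.sum())
    spectra, truths = [], []
    for i, ci in enumerate(draws):
        cls = classes[ci]
        ident = f"syn{i:04d}"
        if cls == "decoy":
            s, t = _decoy_spectrum(_stream(seed, f"decoy:{ident}"), ident)
        else:
            pool = by_class[cls]
            spec = pool[int(rng.integers(len(pool)))]
            s, t = synthesize_spectrum(
                spec, replace(noise, seed=noise.seed + i), reg, identifier=ident
            )
        spectra.append(s)
        truths.append(t)
    return spectra, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# recovery scoring


def truth_matches(
    truth: dict, result: AnnotationResult, require_positions: bool = True
) -> dict[str, bool]:
    """Compare an annotation against a ground-truth record.

    ``class``: predicted class equals the truth (decoys count as recovered
    when unannotated).  ``composition``: acyl multiset / aglycone / sugar /
    ester all agree (isobaric either/or aglycones count when the truth is
    among the candidates).  ``positions``: every true position lies in the
    emitted candidate set of a label for that residue.
    """
    out = {}
    if truth["class"] == "decoy":
        out["class"] = result.compound_class == "unannotated"
        out["composition"] = out["class"]
        out["positions"] = out["class"]
        return out
    out["class"] = result.compound_class == truth["class"]

    comp = result.acyls == tuple(
        sorted(a for a in truth["acyls"].split(",") if a)
    )
    if truth["aglycone"]:
        comp = comp and result.aglycone is not None and (
            truth["aglycone"] in result.aglycone.split("/")
        )
    if truth["sugar"]:
        comp = comp and result.sugar == truth["sugar"]
        comp = comp and result.linkage == truth["linkage"]
    if truth["ester"]:
        comp = comp and truth["ester"] in result.substituents
    out["composition"] = out["class"] and comp

    pos_ok = True
    printed = [p.split(":") for p in truth["positions"].split(";") if p]
    if printed and require_positions:
        by_residue: dict[str, list[set[int]]] = {}
        for lab in result.positions:
            by_residue.setdefault(lab.residue, []).append(set(lab.candidates))
        if len(result.positions) != len(printed):
            pos_ok = False
        used: set[tuple[str, int]] = set()
        for pos, residue in printed:
            sets = by_residue.get(residue, [])
            hit = next(
                (
                    i
                    for i, cs in enumerate(sets)
                    if int(pos) in cs and (residue, i) not in used
                ),
                None,
            )
            if hit is None:
                pos_ok = False
            else:
                used.add((residue, hit))
    out["positions"] = out["composition"] and pos_ok
    return out


def evaluate_recovery(
    spectra: Sequence[MsMsSpectrum],
    truths: pd.DataFrame,
    config: AnnotationConfig = AnnotationConfig(),
    registries: Registries | None = None,
) -> dict[str, float]:
    """Annotate every spectrum and score recovery rates (percent)."""
    reg = registries or load_registries()
    scores = {"class": 0, "composition": 0, "positions": 0}
    for spectrum, (_, truth) in zip(spectra, truths.iterrows()):
        res = annotate(spectrum, config, reg)
        m = truth_matches(dict(truth), res)
        for k in scores:
            scores[k] += bool(m[k])
    n = len(spectra)
    return {k: 100.0 * v / n for k, v in scores.items()} | {"n": n}
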