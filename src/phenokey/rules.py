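"""The hierarchical dereplication key for negative-mode MS/MS spectra of
plant phenolics.

The engine classifies a spectrum into one of the compound classes
(acylquinic acid, caffeoylhexaric acid, phenolic-acid glycoside/ester,
flavonoid aglycone/glycoside), resolves the acyl composition and -- where
the diagnostic ions allow -- the substitution positions, and grades the
identification confidence.  Every claim carries an evidence trail of the
matched peaks that justify it.

The key, in dispatch order:

1. backbone recognition from diagnostic ion series (quinate vs hexarate);
2. quinic branch: acyl composition by mass closure over the residue
   registry, checked against marker ions and the sequential-loss ladder;
   regiochemistry from the identity of the diagnostic base peak (191.056 ->
   C-5, 173.046 "dehydrated quinate" -> C-4 i.e. vicinal, free-acid anion
   -> C-3) refined by marker prominences and the relative abundances of the
   two [M-H-acyl]- ions for diacyl esters;
3. hexaric branch: caffeoyl count from the loss ladder/mass closure plus
   one optional small ester substituent (leontopodic-acid patterns);
4. glycoside branch: sugar neutral loss -> aglycone lookup; >= 2 hexose
   cross-ring cleavages (-60/-90/-120 Da) mark an ester-bound sugar.

C-1 and C-3 esters are not separable from MS/MS alone; such labels are
emitted as "3 (or 1)" rather than guessed.  Numbering follows the
convention in which chlorogenic acid is 5-caffeoylquinic acid (the
alternative numbering exists in the older literature; all shipped rules and
fixtures use the 5-CQA convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .registry import AcylResidue, Registries, load_registries
from .spectra import FragmentPeak, MsMsSpectrum, Tolerance, find_peak

__all__ = [
    "AnnotationConfig",
    "Evidence",
    "PositionLabel",
    "AnnotationResult",
    "AnnotationRecord",
    "StandardsRegistry",
    "detect_backbone",
    "detect_acyls",
    "count_acyl_losses",
    "assign_quinic_regiochemistry",
    "assign_diacyl_order",
    "assign_hexaric_substituents",
    "assign_glycoside",
    "annotate",
    "assign_confidence",
    "specificity",
    "CONFIDENCE_LEVELS",
]

CONFIDENCE_LEVELS = ("A2", "B", "C", "D1", "D2", "E")


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunables of the key.

    The prominence thresholds quantify the qualitative "prominent" /
    "negligible" wording of the hierarchical keys: a secondary marker counts
    as prominent at >= 20% of the base peak, negligible at <= 5%, and the
    order of acyl loss in diacyl esters is only called when the two
    [M-H-acyl]- abundances differ by at least a factor of 3.
    """

    tolerance: Tolerance = Tolerance(mda=10.0)
    prominence: float = 20.0
    negligible: float = 5.0
    order_ratio: float = 3.0
    min_series_ions: int = 3
    max_acyls: int = 4
    standard_no_stereo: str = "C"  # grade for a standard match without stereo proof


@dataclass(frozen=True)
class Evidence:
    """One fired rule: what it claims and the peaks that support it."""

    rule: str
    detail: str
    peaks: tuple[float, ...] = ()


@dataclass(frozen=True)
class PositionLabel:
    """A substitution-position claim for one acyl residue.

    ``position`` is the primary call (None when the key cannot decide);
    ``alternatives`` lists every other position compatible with the
    evidence.  ``candidates`` is their union.
    """

    residue: str
    position: int | None
    alternatives: tuple[int, ...] = ()

    @property
    def ambiguous(self) -> bool:
        return self.position is None or bool(self.alternatives)

    @property
    def candidates(self) -> tuple[int, ...]:
        cand = ([self.position] if self.position is not None else []) + list(
            self.alternatives
        )
        return tuple(sorted(set(cand)))

    def __str__(self) -> str:
        if self.position is None:
            inner = "/".join(str(p) for p in self.alternatives) or "?"
            return f"{inner}?:{self.residue}"
        if self.alternatives:
            alts = "/".join(str(p) for p in self.alternatives)
            return f"{self.position} (or {alts}):{self.residue}"
        return f"{self.position}:{self.residue}"


@dataclass(frozen=True)
class AnnotationResult:
    """The structured outcome of the key for one spectrum."""

    compound_class: str
    backbone: str | None = None
    acyls: tuple[str, ...] = ()
    positions: tuple[PositionLabel, ...] = ()
    substituents: tuple[str, ...] = ()
    aglycone: str | None = None
    sugar: str | None = None
    linkage: str | None = None
    label: str | None = None
    confidence: str | None = None
    evidence: tuple[Evidence, ...] = ()
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnnotationRecord:
    """A spectrum identifier paired with its annotation result."""

    spectrum_id: str
    result: AnnotationResult

    @property
    def evidence(self) -> tuple[Evidence, ...]:
        return self.result.evidence


class StandardsRegistry:
    """The set of compound names for which an authentic standard was run."""

    def __init__(self, names: Iterable[str] = ()):
        self._names = {self._canon(n) for n in names}

    @staticmethod
    def _canon(name: str) -> str:
        return " ".join(name.strip().lower().split())

    def __contains__(self, name: str) -> bool:
        return self._canon(name) in self._names

    def __len__(self) -> int:
        return len(self._names)


# ---------------------------------------------------------------------------
# backbone recognition


def _match_series(
    spectrum: MsMsSpectrum, series, tol: Tolerance
) -> list[tuple[float, str, FragmentPeak]]:
    out = []
    for mz, label in series:
        p = find_peak(spectrum, mz, tol)
        if p is not None:
            out.append((mz, label, p))
    return out


def detect_backbone(
    spectrum: MsMsSpectrum,
    registries: Registries | None = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[str | None, tuple[Evidence, ...]]:
    """Recognize the quinate or hexarate diagnostic ion series.

    Requires at least ``config.min_series_ions`` matched series ions; when
    both series qualify the one with more matches wins, ties going to the
    series whose parent anion (191.056 quinate / 209.030 hexarate) is
    present.  Returns (backbone name or None, evidence).
    """
    reg = registries or load_registries()
    scored = []
    for name, sig in reg.backbones.items():
        matches = _match_series(spectrum, sig.series, config.tolerance)
        if len(matches) >= config.min_series_ions:
            parent_hit = any(
                abs(m[0] - sig.anion_mz) < 1e-6 for m in matches
            )
            scored.append((len(matches), parent_hit, name, matches))
    if not scored:
        return None, ()
    scored.sort(key=lambda t: (t[0], t[1]), reverse=True)
    n, _, name, matches = scored[0]
    ev = Evidence(
        rule="backbone-series",
        detail=f"{name} series: {n} diagnostic ions matched "
        + ", ".join(label for _, label, _ in matches),
        peaks=tuple(p.mz for _, _, p in matches),
    )
    return name, (ev,)


# ---------------------------------------------------------------------------
# acyl detection and composition


def detect_acyls(
    spectrum: MsMsSpectrum,
    registries: Registries | None = None,
    context: str = "quinic",
    config: AnnotationConfig = AnnotationConfig(),
) -> dict[str, tuple[Evidence, ...]]:
    """Residues with a matched primary (acid anion) or secondary marker."""
    reg = registries or load_registries()
    found: dict[str, tuple[Evidence, ...]] = {}
    for residue in reg.acyls_in_context(context):
        evs = []
        for role, mz in residue.markers.items():
            p = find_peak(spectrum, mz, config.tolerance)
            if p is not None:
                evs.append(
                    Evidence(
                        rule="acyl-marker",
                        detail=f"{residue.name} {role} marker at {mz:.4f}",
                        peaks=(p.mz,),
                    )
                )
        if evs:
            found[residue.name] = tuple(evs)
    return found


def _solve_composition(
    delta: float,
    candidates: Sequence[tuple[str, float]],
    max_k: int,
    tol_da: float,
    support: dict[str, int] | None = None,
) -> tuple[tuple[str, ...], float] | None:
    """Best residue multiset whose total loss mass matches ``delta``.

    Preference order: most marker-supported members, smallest |error|,
    fewest residues, lexicographic.  Returns (sorted names, error) or None.
    """
    support = support or {}
    best = None
    for k in range(1, max_k + 1):
        for combo in itertools.combinations_with_replacement(candidates, k):
            total = sum(m for _, m in combo)
            err = abs(delta - total)
            if err > tol_da:
                continue
            names = tuple(sorted(n for n, _ in combo))
            supported = sum(1 for n in set(names) if support.get(n))
            key = (-supported, err, k, names)
            if best is None or key < best[0]:
                best = (key, (names, err))
    return best[1] if best else None


def count_acyl_losses(
    spectrum: MsMsSpectrum,
    residue: AcylResidue,
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[tuple[float, ...], int]:
    """Longest sequential-loss chain of ``residue`` starting at the precursor.

    Consecutive chain members differ by the residue's neutral-loss mass
    within tolerance; the count is the chain length minus one (number of
    losses).  Returns (chain of m/z values, loss count).
    """
    chain = [spectrum.precursor_mz]
    current = spectrum.precursor_mz
    while True:
        target = current - residue.loss_mass
        if target <= 0:
            break
        p = find_peak(spectrum, target, config.tolerance)
        if p is None:
            break
        chain.append(p.mz)
        current = p.mz
    return tuple(chain), len(chain) - 1


# ---------------------------------------------------------------------------
# quinic regiochemistry


def _abundance_at(spectrum, mz, tol) -> tuple[float, float | None]:
    p = find_peak(spectrum, mz, tol)
    return (p.abundance, p.mz) if p is not None else (0.0, None)


def assign_diacyl_order(
    spectrum: MsMsSpectrum,
    residues: tuple[AcylResidue, AcylResidue],
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[AcylResidue | None, AcylResidue | None, tuple[Evidence, ...]]:
    """Which of two distinct residues is lost first.

    The residue whose [M-H-residue]- ion is the more abundant departs
    first; the call requires the two loss-ion abundances to differ by at
    least ``config.order_ratio``.  Returns (first_lost, second_lost,
    evidence); (None, None, evidence) when below the separation threshold.
    """
    a, b = residues
    tol = config.tolerance
    ab_a, mz_a = _abundance_at(spectrum, spectrum.precursor_mz - a.loss_mass, tol)
    ab_b, mz_b = _abundance_at(spectrum, spectrum.precursor_mz - b.loss_mass, tol)
    peaks = tuple(m for m in (mz_a, mz_b) if m is not None)
    detail = (
        f"[M-H-{a.name}]- {ab_a:.1f}% vs [M-H-{b.name}]- {ab_b:.1f}%"
    )
    hi, lo = max(ab_a, ab_b), min(ab_a, ab_b)
    if hi > 0 and (lo == 0 or hi / lo >= config.order_ratio):
        first, second = (a, b) if ab_a > ab_b else (b, a)
        ev = Evidence("diacyl-order", f"{detail}: {first.name} lost first", peaks)
        return first, second, (ev,)
    ev = Evidence("diacyl-order", f"{detail}: order ambiguous", peaks)
    return None, None, (ev,)


def assign_quinic_regiochemistry(
    spectrum: MsMsSpectrum,
    acyl_names: Sequence[str],
    registries: Registries | None = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[tuple[PositionLabel, ...], tuple[Evidence, ...]]:
    """Substitution positions on the quinic backbone from the base-peak key.

    Diagnostic candidates are the quinate ion (191.056), its dehydrated
    form (173.046, the vicinal/C-4 key ion) and the free-acid anion of each
    detected acyl; the most abundant of these is the *diagnostic base peak*
    driving the assignment.  C-1 vs C-3 is never decided (emitted as
    "3 (or 1)"); for vicinal diesters the non-C-4 slot is left as a 1/3/5
    candidate set -- the printed keys resolve it only with retention
    priors or standards.
    """
    reg = registries or load_registries()
    tol = config.tolerance
    quinate = reg.backbones["quinic"].anion_mz
    dehydrated = quinate - 18.0105646
    residues = [reg.acyls[n] for n in acyl_names]

    cands: list[tuple[str, float, float, float | None]] = []
    for label, mz in [("191", quinate), ("173", dehydrated)]:
        ab, hit = _abundance_at(spectrum, mz, tol)
        cands.append((label, mz, ab, hit))
    for r in {r.name: r for r in residues}.values():
        ab, hit = _abundance_at(spectrum, r.acid_anion_mz, tol)
        cands.append((f"acid:{r.name}", r.acid_anion_mz, ab, hit))

    present = [c for c in cands if c[2] > 0]
    if not present:
        ev = Evidence("regio-base", "no diagnostic base-peak candidate present")
        return (
            tuple(PositionLabel(r.name, None, (1, 3, 4, 5)) for r in residues),
            (ev,),
        )
    kind, mz, ab, hit = max(present, key=lambda c: c[2])
    ev_base = Evidence(
        "regio-base",
        f"diagnostic base peak {kind} ({ab:.1f}%)",
        peaks=(hit,),
    )
    if ab < config.prominence:
        # the spectrum is dominated by something other than the key ions
        # (e.g. a secondary marker): conflicting evidence, keep candidates
        ev = Evidence(
            "regio-base",
            f"strongest diagnostic ion {kind} only {ab:.1f}% "
            f"(< {config.prominence}%): regiochemistry ambiguous",
            peaks=(hit,),
        )
        return (
            tuple(PositionLabel(r.name, None, (1, 3, 4, 5)) for r in residues),
            (ev,),
        )
    evidence = [ev_base]
    n = len(residues)

    def acid_ab(r: AcylResidue) -> float:
        return _abundance_at(spectrum, r.acid_anion_mz, tol)[0]

    if n == 1:
        r = residues[0]
        if kind == "173":
            labels = (PositionLabel(r.name, 4),)
        elif kind.startswith("acid:"):
            labels = (PositionLabel(r.name, 3, (1,)),)
        elif kind == "191":
            a = acid_ab(r)
            if a >= config.prominence:
                labels = (PositionLabel(r.name, 3, (1,)),)
                evidence.append(
                    Evidence(
                        "regio-mono",
                        f"191 base with prominent {r.name} acid anion "
                        f"({a:.1f}% >= {config.prominence}%): C-3 pattern",
                        peaks=(_abundance_at(spectrum, r.acid_anion_mz, tol)[1],),
                    )
                )
            else:
                labels = (PositionLabel(r.name, 5),)
                evidence.append(
                    Evidence(
                        "regio-mono",
                        f"191 base with weak acid anion ({a:.1f}%): C-5 pattern",
                        peaks=ev_base.peaks,
                    )
                )
        else:
            labels = (PositionLabel(r.name, None, (1, 3, 4, 5)),)
        return labels, tuple(evidence)

    if n == 2:
        distinct = residues[0].name != residues[1].name
        first = second = None
        if distinct:
            first, second, ev_order = assign_diacyl_order(
                spectrum, (residues[0], residues[1]), config
            )
            evidence.extend(ev_order)

        if kind.startswith("acid:"):
            # the acid-anion base marks its residue as the C-3 (or C-1) ester;
            # a prominent 173 ion pulls the partner onto the vicinal C-4.
            r3 = next(r for r in residues if f"acid:{r.name}" == kind)
            other = next(
                (r for r in residues if r is not r3), residues[0]
            )
            ab173 = _abundance_at(spectrum, dehydrated, tol)[0]
            partner_pos = 4 if ab173 >= config.prominence else 5
            evidence.append(
                Evidence(
                    "regio-diacyl",
                    f"acid-anion base -> {r3.name} at C-3(or 1); 173 at "
                    f"{ab173:.1f}% -> partner at C-{partner_pos}",
                    peaks=ev_base.peaks,
                )
            )
            labels = (
                PositionLabel(r3.name, 3, (1,)),
                PositionLabel(other.name, partner_pos),
            )
        elif kind == "173":
            # vicinal diester: one acyl sits at C-4; MS/MS alone cannot fix
            # the partner at C-3 vs C-5 (nor exclude C-1).
            if distinct and first is not None:
                labels = (
                    PositionLabel(first.name, None, (1, 3, 5)),
                    PositionLabel(second.name, 4),
                )
                evidence.append(
                    Evidence(
                        "regio-diacyl",
                        f"173 base (vicinal): {second.name} at C-4, "
                        f"{first.name} lost first -> C-1/3/5 slot",
                        peaks=ev_base.peaks,
                    )
                )
            elif not distinct:
                labels = (
                    PositionLabel(residues[0].name, None, (1, 3, 5)),
                    PositionLabel(residues[1].name, 4),
                )
                evidence.append(
                    Evidence(
                        "regio-diacyl",
                        "173 base (vicinal): C-4 plus an undecided C-1/3/5 slot",
                        peaks=ev_base.peaks,
                    )
                )
            else:  # distinct residues, loss order below threshold
                labels = tuple(
                    PositionLabel(r.name, None, (1, 3, 4, 5)) for r in residues
                )
                evidence.append(
                    Evidence(
                        "regio-diacyl",
                        "173 base (vicinal) but the loss order is ambiguous: "
                        "which residue sits at C-4 is undecided",
                        peaks=ev_base.peaks,
                    )
                )
        elif kind == "191":
            # non-vicinal diester: 3,5- (or 1,5-) substitution.
            if distinct and first is not None:
                labels = (
                    PositionLabel(second.name, 3, (1,)),
                    PositionLabel(first.name, 5),
                )
                evidence.append(
                    Evidence(
                        "regio-diacyl",
                        f"191 base: {first.name} lost first from C-5, "
                        f"{second.name} at C-3(or 1)",
                        peaks=ev_base.peaks,
                    )
                )
            elif not distinct:
                labels = (
                    PositionLabel(residues[0].name, 3, (1,)),
                    PositionLabel(residues[1].name, 5),
                )
                evidence.append(
                    Evidence(
                        "regio-diacyl",
                        "191 base: 3,5- (or 1,5-) disubstitution",
                        peaks=ev_base.peaks,
                    )
                )
            else:  # distinct but order below threshold
                labels = tuple(
                    PositionLabel(r.name, None, (1, 3, 5)) for r in residues
                )
        else:
            labels = tuple(
                PositionLabel(r.name, None, (1, 3, 4, 5)) for r in residues
            )
        return labels, tuple(evidence)

    if n == 3 and kind == "173":
        # the only triester pattern the key resolves: 3,4,5-trisubstitution
        labels = tuple(
            PositionLabel(r.name, p) for r, p in zip(residues, (3, 4, 5))
        )
        evidence.append(
            Evidence(
                "regio-triacyl",
                "173 base with three acyls: 3,4,5-trisubstitution",
                peaks=ev_base.peaks,
            )
        )
        return labels, tuple(evidence)

    return (
        tuple(PositionLabel(r.name, None, (1, 3, 4, 5)) for r in residues),
        tuple(evidence),
    )


# ---------------------------------------------------------------------------
# branch annotators


_COUNT_PREFIX = {1: "mono", 2: "di", 3: "tri", 4: "tetra"}


def _annotate_quinic(spectrum, reg, config) -> AnnotationResult:
    evidence: list[Evidence] = []
    marker_hits = detect_acyls(spectrum, reg, "quinic", config)
    for evs in marker_hits.values():
        evidence.extend(evs)
    delta = spectrum.precursor_mz - reg.backbones["quinic"].anion_mz
    candidates = [
        (r.name, r.loss_mass) for r in reg.acyls_in_context("quinic")
    ]
    support = {name: len(evs) for name, evs in marker_hits.items()}
    solved = (
        _solve_composition(
            delta, candidates, config.max_acyls,
            config.tolerance.window_da(spectrum.precursor_mz), support,
        )
        if delta > 50  # smaller residuals cannot be an acyl ester
        else None
    )
    if solved is None:
        return AnnotationResult(
            compound_class="unannotated",
            backbone="quinic",
            evidence=tuple(evidence),
            notes=(
                "quinate series present but the precursor-minus-quinate mass "
                "matches no acyl multiset in the registry",
            ),
        )
    names, err = solved
    evidence.append(
        Evidence(
            "acyl-composition",
            f"precursor - quinate = {delta:.4f} Da = "
            + " + ".join(names)
            + f" (|error| {err * 1e3:.1f} mDa)",
            peaks=(spectrum.precursor_mz,),
        )
    )
    # ladder evidence for the dominant residue
    for name in dict.fromkeys(names):
        chain, n_loss = count_acyl_losses(spectrum, reg.acyls[name], config)
        if n_loss:
            evidence.append(
                Evidence(
                    "loss-ladder",
                    f"{n_loss} sequential {name} loss(es): "
                    + " -> ".join(f"{m:.3f}" for m in chain),
                    peaks=chain[1:],
                )
            )
    positions, ev_regio = assign_quinic_regiochemistry(
        spectrum, names, reg, config
    )
    evidence.extend(ev_regio)
    label = _COUNT_PREFIX.get(len(names), str(len(names))) + "acylquinic acid"
    return AnnotationResult(
        compound_class="acylquinic acid",
        backbone="quinic",
        acyls=names,
        positions=positions,
        label=label,
        evidence=tuple(evidence),
    )


def _annotate_hexaric(spectrum, reg, config) -> AnnotationResult:
    evidence: list[Evidence] = []
    tol_da = config.tolerance.window_da(spectrum.precursor_mz)
    delta = spectrum.precursor_mz - reg.backbones["hexaric"].anion_mz
    caffeoyl = reg.acyls["caffeoyl"]
    best = None  # (err, n_caffeoyl, ester_name)
    for k in range(0, config.max_acyls + 1):
        residual = delta - k * caffeoyl.loss_mass
        if abs(residual) <= tol_da and k >= 1:
            cand = (abs(residual), k, None)
            best = min(best, cand) if best else cand
        if residual > 40:
            for ester in reg.esters.values():
                err = abs(residual - ester.attach_mass)
                if err <= tol_da:
                    cand = (err, k, ester.name)
                    best = min(best, cand) if best else cand
    chain, ladder_n = count_acyl_losses(spectrum, caffeoyl, config)
    if best is None:
        if delta <= tol_da:
            # bare hexaric acid core: class only
            return AnnotationResult(
                compound_class="caffeoylhexaric acid",
                backbone="hexaric",
                label="hexaric acid",
                evidence=tuple(evidence),
                notes=("hexarate series only; no acyl residues",),
            )
        sub = f"unknown(+{delta % caffeoyl.loss_mass:.3f} Da)"
        n = int(delta // caffeoyl.loss_mass)
        return AnnotationResult(
            compound_class="caffeoylhexaric acid",
            backbone="hexaric",
            acyls=("caffeoyl",) * max(n, 0),
            substituents=(sub,),
            label="caffeoylhexaric acid, unresolved ester",
            evidence=tuple(evidence),
            notes=("residual loss matched no registered ester substituent",),
        )
    err, n_caf, ester_name = best
    evidence.append(
        Evidence(
            "acyl-composition",
            f"precursor - hexarate = {delta:.4f} Da = {n_caf} x caffeoyl"
            + (f" + {ester_name}" if ester_name else "")
            + f" (|error| {err * 1e3:.1f} mDa)",
            peaks=(spectrum.precursor_mz,),
        )
    )
    if ladder_n:
        evidence.append(
            Evidence(
                "loss-ladder",
                f"{ladder_n} sequential caffeoyl loss(es): "
                + " -> ".join(f"{m:.3f}" for m in chain),
                peaks=chain[1:],
            )
        )
    for evs in detect_acyls(spectrum, reg, "hexaric", config).values():
        evidence.extend(evs)
    if ester_name and ester_name in reg.esters:
        for role, mz in reg.esters[ester_name].markers.items():
            p = find_peak(spectrum, mz, config.tolerance)
            if p is not None:
                evidence.append(
                    Evidence(
                        "ester-marker",
                        f"{ester_name} {role} marker at {mz:.4f}",
                        peaks=(p.mz,),
                    )
                )
    core = _COUNT_PREFIX.get(n_caf, str(n_caf)) + "caffeoylhexaric acid"
    if ester_name:
        label = f"{ester_name}-{core}"
        if ester_name == "hydroxybutanyl" and n_caf == 3:
            label += " (leontopodic A-type)"
    else:
        label = core
        if n_caf == 3:
            label += " (leontopodic B-type)"
    return AnnotationResult(
        compound_class="caffeoylhexaric acid",
        backbone="hexaric",
        acyls=("caffeoyl",) * n_caf,
        substituents=(ester_name,) if ester_name else (),
        label=label,
        evidence=tuple(evidence),
    )


def assign_hexaric_substituents(
    spectrum: MsMsSpectrum,
    registries: Registries | None = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(caffeoyl multiset, extra ester substituents) for a hexaric spectrum."""
    reg = registries or load_registries()
    res = _annotate_hexaric(spectrum, reg, config)
    return res.acyls, res.substituents


def assign_glycoside(
    spectrum: MsMsSpectrum,
    registries: Registries | None = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> AnnotationResult:
    """Sugar-loss / aglycone-lookup branch of the key."""
    reg = registries or load_registries()
    tol = config.tolerance
    evidence: list[Evidence] = []

    def aglycone_at(mz: float):
        best, best_err = None, tol.window_da(mz)
        for agl in reg.aglycones.values():
            err = abs(agl.anion_mz - mz)
            if err <= best_err:
                best, best_err = agl, err
        return best

    # cross-ring cleavages of an ester-bound hexose
    ring_hits = []
    for label, formula in reg.cross_ring_losses.items():
        p = find_peak(spectrum, spectrum.precursor_mz - formula.mass, tol)
        if p is not None:
            ring_hits.append((label, p))
    if ring_hits:
        evidence.append(
            Evidence(
                "cross-ring",
                "hexose cross-ring cleavage(s): "
                + ", ".join(l for l, _ in ring_hits),
                peaks=tuple(p.mz for _, p in ring_hits),
            )
        )
    linkage = "sugar ester" if len(ring_hits) >= 2 else "O-glycoside"

    # sugar neutral losses, largest first so di-hexose beats hexose
    sugar_hit = None
    for sugar in sorted(reg.sugars.values(), key=lambda s: -s.loss_mass):
        p = find_peak(spectrum, spectrum.precursor_mz - sugar.loss_mass, tol)
        if p is not None:
            sugar_hit = (sugar, p)
            break

    if sugar_hit is not None:
        sugar, residual_peak = sugar_hit
        evidence.append(
            Evidence(
                "sugar-loss",
                f"neutral loss {sugar.loss_mass:.4f} Da ({sugar.name}) to "
                f"{residual_peak.mz:.4f}",
                peaks=(residual_peak.mz,),
            )
        )
        agl = aglycone_at(residual_peak.mz)
        if agl is None:
            return AnnotationResult(
                compound_class="unknown glycoside",
                sugar=sugar.name,
                linkage=linkage,
                label=f"unknown {sugar.name} conjugate",
                evidence=tuple(evidence),
                notes=(
                    f"sugar loss to {residual_peak.mz:.4f} matches no "
                    "registered aglycone",
                ),
            )
        evidence.append(
            Evidence(
                "aglycone-lookup",
                f"residual ion {residual_peak.mz:.4f} = {agl.label} "
                f"[M-H]- ({agl.anion_mz:.4f})",
                peaks=(residual_peak.mz,),
            )
        )
        if agl.compound_class == "flavonoid":
            cls = "flavonoid glycoside"
            label = f"{agl.label} {sugar.name} ({linkage})"
        else:
            cls = "phenolic-acid glycoside/ester"
            label = f"{agl.label} {sugar.name} {linkage}"
        return AnnotationResult(
            compound_class=cls,
            aglycone=agl.label,
            sugar=sugar.name,
            linkage=linkage,
            label=label,
            evidence=tuple(evidence),
        )

    # no sugar loss: bare aglycone / free phenolic acid?
    agl = aglycone_at(spectrum.precursor_mz)
    if agl is not None:
        evidence.append(
            Evidence(
                "aglycone-lookup",
                f"precursor {spectrum.precursor_mz:.4f} = {agl.label} [M-H]-",
                peaks=(spectrum.precursor_mz,),
            )
        )
        cls = (
            "flavonoid aglycone"
            if agl.compound_class == "flavonoid"
            else "phenolic acid"
        )
        return AnnotationResult(
            compound_class=cls,
            aglycone=agl.label,
            label=agl.label,
            evidence=tuple(evidence),
        )

    return AnnotationResult(
        compound_class="unannotated",
        evidence=tuple(evidence),
        notes=("no backbone series, sugar loss or aglycone match",),
    )


# ---------------------------------------------------------------------------
# dispatch, confidence, specificity


def annotate(
    spectrum: MsMsSpectrum,
    config: AnnotationConfig = AnnotationConfig(),
    registries: Registries | None = None,
) -> AnnotationResult:
    """Run the full hierarchical key on one spectrum.

    Never raises on spectrum content; undecidable inputs come back as
    ``unannotated`` with the reasons in ``notes``.
    """
    reg = registries or load_registries()
    spectrum = spectrum.normalized()
    backbone, ev_backbone = detect_backbone(spectrum, reg, config)
    if backbone == "quinic":
        res = _annotate_quinic(spectrum, reg, config)
    elif backbone == "hexaric":
        res = _annotate_hexaric(spectrum, reg, config)
    else:
        res = assign_glycoside(spectrum, reg, config)
    return replace(res, evidence=tuple(ev_backbone) + res.evidence)


def specificity(result: AnnotationResult) -> int:
    """Coarse specificity of a result.

    0 unannotated < 1 class only < 2 composition with unresolved aspects
    < 3 full structural proposal.  A position label counts as informative
    when its candidate set excludes at least one backbone position (the
    inherent C-1/C-3 pair and the vicinal C-3/C-5 slot remain informative).
    """
    if result.compound_class == "unannotated":
        return 0
    if not (result.acyls or result.aglycone):
        return 1
    if any(s.startswith("unknown") for s in result.substituents):
        return 2
    if result.positions:
        informative = all(
            p.position is not None or 0 < len(p.alternatives) < 4
            for p in result.positions
        )
        return 3 if informative else 2
    return 3


def assign_confidence(
    result: AnnotationResult,
    standards: StandardsRegistry | None = None,
    stereo_confirmed: bool = False,
    matched_name: str | None = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> str:
    """Grade the identification on the A2/B/C/D1/D2/E scheme.

    A2 -- matched to an authentic standard with stereochemistry confirmed;
    B or C (per ``config.standard_no_stereo``) -- standard match without a
    stereo proof; D1 -- no standard but full positional/structural
    assignment; D2 -- structure with ambiguous aspects; E -- class-level
    only.  Stereochemistry is never inferred from MS/MS: the stereo flag is
    external input.
    """
    standards = standards or StandardsRegistry()
    name = matched_name or result.label
    if name and name in standards:
        return "A2" if stereo_confirmed else config.standard_no_stereo
    level = specificity(result)
    if level <= 1:
        return "E"
    if level == 2:
        return "D2"
    if result.aglycone and "/" in result.aglycone:
        return "D2"  # isobaric aglycones unresolved without a retention prior
    return "D1"
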