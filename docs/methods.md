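# Methods

## Scope and model

`phenokey` is a deterministic rule engine, not a statistical classifier.
Its input is a single centroided negative-mode MS/MS spectrum — precursor
[M−H]⁻ m/z, optional [2M−H]⁻, fragment m/z values with relative abundances
normalized to the base peak — and its output is a structured annotation
(class, backbone, acyl multiset, positions, sugar/aglycone/linkage,
confidence grade) with an evidence trail.  The engine assumes singly
charged deprotonated ions, centroided peaks, and abundances comparable
across fragments of one spectrum; it does not model isotopologues,
in-source fragmentation, chromatography or collision-energy dependence.

## Ion-mass conventions

All theoretical m/z values derive from monoisotopic atomic masses
(CODATA/IUPAC: C 12, H 1.00782503, N 14.00307400, O 15.99491462) with
anion m/z = neutral mass − 1.00727646 (proton mass).  Electron mass is not
book-kept separately; at the fourth decimal place this convention agrees
with conventionally printed calculated values (e.g. 781.1622 for
C₃₇H₃₃O₁₉⁻).  Display rounding is round-half-up at the requested number of
decimals.  Formula parsing accepts Hill notation with underscores
stripped, because typeset tables often render C16H18O9 as `C_16_H_18_O_9_`.

## Matching tolerances

* **MS2 matching: absolute 10 mDa by default** (configurable, also as
  ppm).  An absolute window was chosen over ppm because published
  high-resolution MS2 axes commonly sit a few ppm *below* theory (measured
  179.0339 vs theoretical 179.0350 caffeate is −6 ppm), and because the
  diagnostic ions span 85–900 m/z: one absolute setting keeps the low-mass
  key ions matchable without opening the high-mass region excessively.
  The quinate/dehydrated-hexarate pair (191.0561 vs 191.0197) demands a
  tolerance below 18 mDa, which 10 mDa respects.
* **MS1/EIC windows: 5 ppm**, symmetric multiplicative
  (c·(1 ± t·10⁻⁶)), the standard extracted-ion-chromatogram practice.

## The hierarchical key

**Backbone.**  A backbone is called when ≥ 3 ions of its diagnostic series
match (quinic: 191.056/173.046/111.045/93.035/85.029; hexaric:
209.030/191.020/173.009/147.030/129.019/111.009/85.029).  When both
series reach 3, more matches win; ties go to the series whose parent anion
is present.  Series m/z values are anchored on theory, never on any
individual measured spectrum.

**Acyl composition by mass closure.**  The acyl multiset is the best
multiset (≤ 4 residues) from the registry whose summed losses equal
precursor − backbone anion within tolerance, preferring marker-supported
residues, then smaller mass error, then fewer residues.  Pure
marker-based detection is insufficient in practice — dihydrocaffeoyl
conjugates, for instance, can lack a visible acid anion — while the mass
closure plus the sequential-loss ladder and marker ions as corroborating
evidence recovers every reference spectrum.  Isobaric residues are
context-gated: C₉H₈O₄ is hydroxydihydrocaffeoyl on a quinic backbone but
syringoyl in the phenolic-glycoside branch; the 197.045 marker is never
resolved globally.

**Regiochemistry (quinic).**  The decision ion is the *diagnostic base
peak*: the most abundant among 191.056, 173.046 and the free-acid anions
of the composition residues.  If even that ion is below the prominence
threshold the spectrum is dominated by non-key ions and the positions are
declared ambiguous rather than guessed.  Monoesters: 173-dominant → C-4;
acid-anion-dominant → C-3; 191-dominant → C-3 when the acid anion is
prominent, else C-5.  Diesters: 191-dominant → {3,5}-type; 173-dominant →
vicinal with one residue at C-4; acid-anion-dominant → that residue at
C-3 with the partner at C-4 (if 173 is prominent) or C-5.  For two
distinct residues, the one whose [M−H−acyl]⁻ ion is ≥ 3× the other
departs first and takes the C-5 (non-vicinal) or non-C-4 (vicinal) slot.
Triesters resolve only the 173-dominant 3,4,5 pattern.

Two ambiguities are *inherent* and always reported instead of resolved:
C-1 vs C-3 (labels read "3 (or 1)"), and the non-C-4 slot of a vicinal
diester (a 1/3/5 candidate set) — MS/MS alone cannot separate these;
published assignments rely on standards or elution order.  A
retention-time prior table could sharpen both and is a deliberate
extension point, not implemented as a default.

**Thresholds.**  The qualitative wording of published keys ("prominent",
"negligible") is quantified once: prominent ≥ 20 % of base peak,
negligible ≤ 5 %, diacyl loss-order ratio ≥ 3×.  These reproduce the
reference calls (59.5 % caffeate in the 3-acyl pattern vs 1.0 % in the
5-acyl pattern; 68.1 % vs 2.4 % loss ions in the decisive vicinal
diester) with an order of magnitude of slack on either side.

**Hexaric branch.**  Caffeoyl count and at most one small ester
substituent are solved by mass closure against the ester registry
(hydroxybutanyl C₄H₆O₂, hydroxyvaleryl C₅H₈O₂, butanyl C₄H₆O,
methylbutanyl C₅H₈O, hydroxybenzoyl C₇H₄O₂ with its 137.024/93.035
markers); the caffeoyl ladder and markers supply evidence.  Hexaric ester
positions are never claimed — the key cannot resolve them.  An unmatched
residual is reported as `unknown(Δm)`, not dropped.

**Glycoside branch.**  Sugar losses are tried largest-first so di-hexose
(324.1057) is tested before caffeoylhexose (324.0845); the 21-mDa gap
keeps them separable at 10 mDa.  The residual fragment is looked up in
the aglycone registry; isobaric aglycone pairs (luteolin/kaempferol
285.041, nepetin/isorhamnetin 315.051) are reported as either/or and
graded D2.  Linkage is "sugar ester" when ≥ 2 of the −60/−90/−120 Da
cross-ring cleavages are present, else "O-glycoside".

**Confidence.**  A2 requires an external stereo-confirmation flag —
stereochemistry is never inferred from MS/MS.  Standard match without
stereo proof grades B or C by policy (default C).  D1 requires every
position label to exclude at least one backbone position; the inherent
1/3 and vicinal 1/3/5 ambiguities still qualify for D1, matching how such
assignments are graded in practice.

## Reference fixture

The bundled table transcribes the 39 published acylquinic-acid peak lists
verbatim, including their defects: duplicated fragment entries (kept
first, with a warning), and "exact mass" cells inconsistent with their own
molecular formula (353.0867 printed for C₁₆H₁₈O₉, computed 353.0878;
C₁₇H₂₀O₈ printed where the fragments imply C₁₇H₂₀O₉; one cell truncated to
"677").  The loader flags such rows (`exact_mz_flag`) and theoretical
values are always recomputed from the formula.  Concordance with the
printed names is scored as candidate containment: every printed position
must lie in the candidate set the key emits for that residue, and for
rows where the key is decisive (all strict monoesters) the primary call
must equal the printed position.  Rows the source itself grades as poor
evidence (D2) or names as either/or are excluded from positional scoring.

## Synthetic data

The generator inverts the key: it emits the precursor, the full
sequential-loss ladder, backbone series, residue markers, and base-peak
placement per regio archetype (fixed abundance profiles resembling
reference spectra of each class; no physical fragmentation model).  Noise
is (i) a multiplicative calibration bias applied to every m/z, default
−5 ppm, emulating the low-reading MS2 axis of real instruments; (ii)
log-normal abundance jitter, default sd 0.15, a mild run-to-run
variability; (iii) uniform decoy peaks, default 3 per spectrum at 1–10 %.
A single integer seed drives named substreams (dataset draws, per-spectrum
jitter, decoys), so outputs are byte-reproducible.

What passing the synthetic experiments shows — and does not.  They show
the key is self-consistent (exact round-trip over the shipped 74-structure
enumeration), robust to the modelled imperfections (≥ 95 % class and
≥ 85 % position recovery at n = 200 under bias + jitter + decoys), and
specific (≥ 90 % of decoy-only spectra left unannotated).  They do not
show performance on real chimeric spectra, co-eluting isomers,
in-source fragments, or compound classes outside the registries; the
39-row reference concordance is the only real-data anchor.

## Default dataset conditions

The default class mix of `generate_dataset` follows the profiled class
sizes of a phenolic-rich Asteraceae extract (39 AQA : 26 CHA : 34
phenolic acids and derivatives : 31 flavonoids), with flavonoids and
phenolics split between glycosides and free forms.  Experiment sizes
(n = 200 mixed, n = 50 decoys, 74-structure enumeration) keep the full
acceptance run under a minute on one CPU while leaving the rate estimates
stable to a few percent.

## Percent peak area

`class_percentages` is validated by construction (sums to 100 within
class and overall, scale invariance, NaN for an all-zero class) and on
synthetic tables.  Published extract-level shares cannot serve as checks:
the underlying raw AUC values are not public.  Class shares are
area-weighted; whether a published share was area- or count-weighted is
not always stated, and the area-weighted definition is documented here as
this package's fixed choice.

## Known limitations

* C-1 vs C-3 and the vicinal non-C-4 slot are reported as ambiguous
  without a retention-prior table (none is shipped).
* Same-residue vicinal diesters (e.g. 3,4- vs 4,5-diCQA) are not
  separable by the key; standards or retention order are required.
* The acyl/sugar/aglycone registries are editable but finite; compounds
  outside them surface as `unknown(Δm)` or `unknown glycoside`.
* Positive-ion adducts, multiply charged ions and isotope patterns are
  out of scope.
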