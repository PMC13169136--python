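# phenokey

Diagnostic fragment-ion dereplication of plant phenolics from
negative-mode ESI-MS/MS spectra.

## The problem

Extracts of Asteraceae (and many other plants) are dominated by a few
families of phenolic esters and glycosides — acylquinic acids (AQAs,
"chlorogenic acids"), caffeoylhexaric acids (CHAs, the leontopodic-acid
family), hydroxybenzoic/hydroxycinnamic acid hexosides and sugar esters,
and flavonoid glycosides.  Telling the positional isomers of these
compounds apart (3- vs 4- vs 5-caffeoylquinic acid, 3,4- vs 3,5- vs
4,5-diesters, O-glycosides vs sugar esters) does not require isolating
them: high-resolution MS/MS spectra carry enough diagnostic structure,
provided the annotation rules are applied consistently.  `phenokey`
implements those hierarchical rules as a tested, configurable engine for
analysts doing LC-MS/MS dereplication of phenolic-rich extracts.

## The key

For a deprotonated precursor [M−H]⁻ with fragments (relative abundances in
% of base peak):

1. **Backbone recognition.**  Quinic-acid conjugates show the series
   *m/z* 191.056 [QA−H]⁻ → 173.046 [QA−H−H₂O]⁻ → 111.045 → 93.035 → 85.029;
   hexaric-acid conjugates the series 209.030 [HA−H]⁻ → 191.020 → 173.009 →
   147.030 → 129.019 → 111.009 → 85.029.  Three matched series ions call the
   backbone; 191.056 vs 191.020 keeps the two apart at the default 10-mDa
   MS2 tolerance.
2. **Acyl composition.**  The residue multiset is solved by mass closure —
   precursor minus backbone anion against the registry of acyl losses
   (caffeoyl 162.032, feruloyl 176.047, *p*-coumaroyl 146.037, ...) — and
   corroborated by the free-acid anions (179.035, 193.051, 163.040, 197.046)
   and their decarboxylated satellites (135.045, 134.037, 119.050), plus the
   sequential-loss ladder (e.g. tetraCHA 857.158 → 695.126 → 533.094 →
   371.062 → 209.030).
3. **Regiochemistry** (quinic backbone) from the *diagnostic base peak*:
   191.056-dominant with suppressed acid ions → C-5; prominent acid anion
   (≥ 20 %) or acid-anion base → C-3 (C-1 is never excluded by MS/MS alone,
   so labels read "3 (or 1)"); 173.046-dominant → vicinal ester at C-4.
   For diesters of two different acids, the more abundant [M−H−acyl]⁻ ion
   (≥ 3× its partner) marks the residue lost first and pins the assignment
   (e.g. 4-*p*-coumaroyl-5-caffeoylquinic acid).
4. **Glycosides.**  Sugar neutral losses (hexose 162.053, di-hexose
   324.106, rutinosyl 308.111, acetylhexose 204.063, caffeoylhexose
   324.085) expose the aglycone, identified by its anion mass (quercetin
   301.035, myricetin 317.030, ...).  Two or more hexose cross-ring
   cleavages (−60/−90/−120 Da) mark an ester-bound sugar instead of an
   O-glycoside.
5. **Confidence** on the A2/B/C/D1/D2/E scheme: authentic-standard match
   with stereochemical proof → A2; standard without stereo proof → B or C
   (policy); full positional proposal without a standard → D1; ambiguous
   aspects → D2; class-level only → E.

Numbering follows the convention in which **chlorogenic acid = 5-CQA**
(the older literature also uses a numbering where it is 3-CQA; all rules,
registries and outputs here use the 5-CQA convention).

Semi-quantitation is percent peak area: each compound's AUC as a share of
its class total, and each class as a share of the grand total.

## Worked example

The package ships the transcribed reference table of 39 acylquinic acids
(`phenokey.datasets`).  Annotating the 3,5-dicaffeoylquinic acid spectrum
(precursor *m/z* 515.1194; base fragment 353.0878; 191.0550 at 84.5 %,
179.0338 at 42.0 %):

```python
from phenokey import annotate, read_spectra, assign_confidence
from phenokey.datasets import table1_path

spectra = read_spectra(table1_path(), format="tsv")
s = next(x for x in spectra if x.identifier == "22")
res = annotate(s)
print(res.compound_class, res.acyls)
print([str(p) for p in res.positions])
print(assign_confidence(res))
```

prints

```
acylquinic acid ('caffeoyl', 'caffeoyl')
['3 (or 1):caffeoyl', '5:caffeoyl']
D1
```

— the caffeoyl count from the 515 → 353 → 191 mass closure, C-5 from the
quinate base peak and C-3 (or 1) from the prominent caffeate/135 ions, and
grade D1 because no standards registry was supplied.  Every claim carries
an evidence trail (`res.evidence`) naming the rule and the matched peaks.

The same pipeline from the shell:

```bash
phenokey mass C16H18O9 --dimer --decimals 3   # 707.183  ([2M-H]- of chlorogenic acid)
phenokey annotate --input spectra.mgf --out annotations.tsv
phenokey simulate --n 100 --seed 1 --out sim/
phenokey quant --areas areas.tsv --out percentages.tsv
```

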