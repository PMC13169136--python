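"""The dereplication key: backbone recognition, ladders, regiochemistry,
glycoside logic, confidence grading and the engine invariants."""

import dataclasses

import pytest

from phenokey.rules import (
    AnnotationConfig,
    StandardsRegistry,
    annotate,
    assign_confidence,
    assign_diacyl_order,
    assign_glycoside,
    assign_hexaric_substituents,
    assign_quinic_regiochemistry,
    count_acyl_losses,
    detect_acyls,
    detect_backbone,
    specificity,
)
from phenokey.spectra import FragmentPeak, MsMsSpectrum


def spectrum(identifier, precursor, peaks):
    return MsMsSpectrum(
        identifier, precursor, tuple(FragmentPeak(m, a) for m, a in peaks)
    ).normalized()


@pytest.fixture
def by_id(table1_spectra):
    return {s.identifier: s for s in table1_spectra}


# --- worked hexaric spectra assembled from the published transitions -------

@pytest.fixture
def leontopodic_a():
    """Hydroxybutanyl-tricaffeoylhexaric acid: 781.162 -> ... -> 295.067
    -> 209.030 (-C4H6O2) -> 191.019."""
    return spectrum(
        "54", 781.1622,
        [
            (781.1622, 35.0), (619.1305, 20.0), (457.0988, 25.0),
            (295.0671, 60.0), (209.0303, 70.0), (191.0197, 100.0),
            (173.0092, 20.0), (147.0299, 15.0),
            (179.0350, 45.0), (161.0244, 18.0), (135.0452, 40.0),
        ],
    )


@pytest.fixture
def tetra_cha():
    """857.158 -> 695.126 -> 533.094 -> 371.062 -> 209.030."""
    return spectrum(
        "60", 857.1571,
        [
            (857.1571, 30.0), (695.1254, 45.0), (533.0937, 55.0),
            (371.0620, 60.0), (209.0303, 70.0), (191.0197, 100.0),
            (173.0092, 25.0), (129.0193, 10.0),
            (179.0350, 50.0), (135.0452, 42.0),
        ],
    )


class TestDetectBackbone:
    def test_chlorogenic_is_quinic(self, by_id, registries, config):
        backbone, evidence = detect_backbone(by_id["7"], registries, config)
        assert backbone == "quinic"
        assert evidence and evidence[0].peaks

    def test_hexarate_series_is_hexaric(self, registries, config):
        s = spectrum(
            "40", 371.0620,
            [(371.0620, 30.0), (209.0303, 100.0), (191.0197, 80.0),
             (147.0299, 25.0), (129.0193, 12.0)],
        )
        backbone, _ = detect_backbone(s, registries, config)
        assert backbone == "hexaric"

    def test_no_series_returns_none(self, registries, config):
        s = spectrum("noise", 441.13, [(123.4567, 100.0), (234.5678, 40.0)])
        assert detect_backbone(s, registries, config)[0] is None

    def test_191_isobars_disambiguated(self, registries, config):
        """Quinate 191.056 vs dehydrated hexarate 191.020: the 36-mDa gap
        keeps the two series separate at the default 10-mDa tolerance."""
        s = spectrum(
            "x", 371.0620,
            [(209.0303, 100.0), (191.0197, 80.0), (173.0092, 30.0)],
        )
        assert detect_backbone(s, registries, config)[0] == "hexaric"


class TestDetectAcyls:
    def test_caffeoyl_markers_in_neochlorogenic(self, by_id, registries, config):
        found = detect_acyls(by_id["4"], registries, "quinic", config)
        assert "caffeoyl" in found
        assert any(e.peaks for e in found["caffeoyl"])

    def test_coumaroyl_markers(self, by_id, registries, config):
        found = detect_acyls(by_id["6"], registries, "quinic", config)
        assert "p-coumaroyl" in found

    def test_no_markers_empty(self, registries, config):
        s = spectrum("noise", 441.13, [(123.4567, 100.0)])
        assert detect_acyls(s, registries, "quinic", config) == {}


class TestCountAcylLosses:
    def test_tetracaffeoylhexaric_ladder(self, tetra_cha, registries, config):
        chain, n = count_acyl_losses(
            tetra_cha, registries.acyls["caffeoyl"], config
        )
        assert n == 4
        assert chain[-1] == pytest.approx(209.0303, abs=1e-3)

    def test_leontopodic_a_ladder_stops_at_ester_core(
        self, leontopodic_a, registries, config
    ):
        chain, n = count_acyl_losses(
            leontopodic_a, registries.acyls["caffeoyl"], config
        )
        assert n == 3
        assert chain[-1] == pytest.approx(295.0671, abs=1e-3)

    def test_single_peak_spectrum_counts_zero(self, registries, config):
        s = spectrum("x", 515.1190, [(515.1190, 100.0)])
        assert count_acyl_losses(s, registries.acyls["caffeoyl"], config)[1] == 0


class TestQuinicRegiochemistry:
    def test_neochlorogenic_pattern_is_c3(self, by_id, registries, config):
        labels, ev = assign_quinic_regiochemistry(
            by_id["4"], ("caffeoyl",), registries, config
        )
        assert labels[0].position == 3
        assert 1 in labels[0].alternatives  # C-1 never excluded by MS/MS
        assert any(e.peaks for e in ev)

    def test_chlorogenic_pattern_is_c5(self, by_id, registries, config):
        labels, _ = assign_quinic_regiochemistry(
            by_id["7"], ("caffeoyl",), registries, config
        )
        assert labels[0].position == 5
        assert not labels[0].alternatives

    def test_dehydrated_base_is_c4(self, by_id, registries, config):
        labels, _ = assign_quinic_regiochemistry(
            by_id["5"], ("caffeoyl",), registries, config
        )
        assert labels[0].position == 4

    def test_weak_diagnostics_stay_ambiguous(self, by_id, registries, config):
        # spectrum dominated by a secondary marker (135), key ions all weak
        labels, _ = assign_quinic_regiochemistry(
            by_id["1"], ("hydroxydihydrocaffeoyl",), registries, config
        )
        assert labels[0].position is None
        assert set(labels[0].candidates) == {1, 3, 4, 5}


class TestDiacylOrder:
    def test_compound_34_caffeoyl_lost_first(self, by_id, registries, config):
        first, second, ev = assign_diacyl_order(
            by_id["34"],
            (registries.acyls["caffeoyl"], registries.acyls["p-coumaroyl"]),
            config,
        )
        assert first.name == "caffeoyl"
        assert second.name == "p-coumaroyl"

    def test_compound_34_assignment_is_4cou_5caf(self, table1_results):
        res = table1_results["34"]
        by_residue = {l.residue: l for l in res.positions}
        assert by_residue["p-coumaroyl"].position == 4
        assert 5 in by_residue["caffeoyl"].candidates

    def test_compound_28_base_acid_anion_gives_3cou_5caf(self, table1_results):
        res = table1_results["28"]
        by_residue = {l.residue: l for l in res.positions}
        assert by_residue["p-coumaroyl"].position == 3
        assert by_residue["caffeoyl"].position == 5

    def test_near_equal_loss_ions_are_ambiguous(self, registries, config):
        s = spectrum(
            "x", 499.1251,
            [(499.1251, 30.0), (353.0883, 50.0), (337.0933, 45.0),
             (191.0561, 100.0), (173.0456, 5.0), (93.0346, 5.0), (85.0295, 5.0)],
        )
        first, second, _ = assign_diacyl_order(
            s, (registries.acyls["caffeoyl"], registries.acyls["p-coumaroyl"]),
            config,
        )
        assert first is None and second is None


class TestHexaricBranch:
    def test_leontopodic_a_pattern(self, leontopodic_a, registries, config):
        acyls, subs = assign_hexaric_substituents(
            leontopodic_a, registries, config
        )
        assert acyls == ("caffeoyl",) * 3
        assert subs == ("hydroxybutanyl",)

    def test_leontopodic_a_label(self, leontopodic_a, registries, config):
        res = annotate(leontopodic_a, config, registries)
        assert res.compound_class == "caffeoylhexaric acid"
        assert "leontopodic A-type" in res.label

    def test_hydroxybenzoyl_ester(self, registries, config):
        s = spectrum(
            "65", 815.1465,
            [(815.1465, 25.0), (653.1148, 20.0), (491.0831, 25.0),
             (329.0514, 40.0), (209.0303, 60.0), (191.0197, 100.0),
             (173.0092, 20.0), (137.0244, 55.0), (93.0346, 30.0),
             (179.0350, 35.0), (135.0452, 30.0)],
        )
        acyls, subs = assign_hexaric_substituents(s, registries, config)
        assert acyls == ("caffeoyl",) * 3
        assert subs == ("hydroxybenzoyl",)

    def test_plain_ladder_is_unsubstituted_cha(self, tetra_cha, registries, config):
        acyls, subs = assign_hexaric_substituents(tetra_cha, registries, config)
        assert acyls == ("caffeoyl",) * 4
        assert subs == ()

    def test_unmatched_residual_reported_as_unknown(self, registries, config):
        s = spectrum(
            "x", 209.0303 + 162.0317 + 55.5,
            [(209.0303 + 162.0317 + 55.5, 20.0), (209.0303, 60.0),
             (191.0197, 100.0), (147.0299, 25.0)],
        )
        _, subs = assign_hexaric_substituents(s, registries, config)
        assert subs and subs[0].startswith("unknown")


class TestGlycosideBranch:
    def test_quercetin_hexoside(self, registries, config):
        s = spectrum(
            "106", 463.0882, [(463.0882, 20.0), (301.0354, 100.0)]
        )
        res = assign_glycoside(s, registries, config)
        assert res.compound_class == "flavonoid glycoside"
        assert res.aglycone == "quercetin"
        assert res.sugar == "hexose"
        assert res.linkage == "O-glycoside"

    def test_myricetin_acetylhexoside(self, registries, config):
        s = spectrum(
            "104", 521.0937, [(521.0937, 15.0), (317.0303, 100.0)]
        )
        res = assign_glycoside(s, registries, config)
        assert res.aglycone == "myricetin"
        assert res.sugar == "acetylhexose"

    def test_cross_ring_cleavages_mark_sugar_ester(self, registries, config):
        s = spectrum(
            "70", 299.0772,
            [(299.0772, 20.0), (239.0561, 30.0), (209.0455, 25.0),
             (179.0349, 20.0), (137.0244, 100.0)],
        )
        res = assign_glycoside(s, registries, config)
        assert res.linkage == "sugar ester"
        assert res.aglycone == "hydroxybenzoic acid"
        assert res.compound_class == "phenolic-acid glycoside/ester"

    def test_sugar_loss_without_aglycone_is_unknown_glycoside(
        self, registries, config
    ):
        s = spectrum("x", 400.1230, [(400.1230, 50.0), (238.0702, 100.0)])
        res = assign_glycoside(s, registries, config)
        assert res.compound_class == "unknown glycoside"

    def test_caffeoyl_ester_glycoside_of_apigenin(self, registries, config):
        """Caffeoylhexose conjugate: loss 324.085 to the apigenin anion."""
        s = spectrum(
            "125", 593.1300,
            [(593.1300, 20.0), (431.0983, 25.0), (269.0455, 100.0),
             (179.0350, 30.0), (161.0244, 12.0), (135.0452, 25.0)],
        )
        res = assign_glycoside(s, registries, config)
        assert res.aglycone == "apigenin"
        assert res.sugar == "caffeoylhexose"


class TestAnnotateDispatch:
    def test_dicaffeoylquinic_3_5(self, table1_results):
        res = table1_results["22"]
        assert res.compound_class == "acylquinic acid"
        assert res.acyls == ("caffeoyl", "caffeoyl")
        cands = [set(l.candidates) for l in res.positions]
        assert any(3 in c for c in cands) and any(5 in c for c in cands)

    def test_white_noise_unannotated(self, registries, config):
        s = spectrum(
            "noise", 441.13,
            [(123.4567, 100.0), (234.5678, 40.0), (345.6789, 20.0)],
        )
        res = annotate(s, config, registries)
        assert res.compound_class == "unannotated"
        assert res.notes

    def test_never_raises_on_content(self, registries, config):
        s = spectrum("tiny", 100.0, [(99.9, 100.0)])
        res = annotate(s, config, registries)
        assert res.compound_class in ("unannotated",)

    def test_determinism(self, by_id, registries, config):
        a = annotate(by_id["22"], config, registries)
        b = annotate(by_id["22"], config, registries)
        assert a == b


class TestConfidence:
    def test_standard_with_stereo_is_a2(self, table1_results, config):
        standards = StandardsRegistry(["Chlorogenic acid"])
        level = assign_confidence(
            table1_results["7"], standards, stereo_confirmed=True,
            matched_name="Chlorogenic acid", config=config,
        )
        assert level == "A2"

    def test_standard_without_stereo_policy(self, table1_results):
        standards = StandardsRegistry(["Chlorogenic acid"])
        assert assign_confidence(
            table1_results["7"], standards, matched_name="Chlorogenic acid"
        ) == "C"
        policy_b = AnnotationConfig(standard_no_stereo="B")
        assert assign_confidence(
            table1_results["7"], standards, matched_name="Chlorogenic acid",
            config=policy_b,
        ) == "B"

    def test_resolved_positions_without_standard_is_d1(self, table1_results):
        assert assign_confidence(table1_results["10"]) == "D1"

    def test_ambiguous_positions_is_d2(self, table1_results):
        assert assign_confidence(table1_results["1"]) == "D2"

    def test_class_only_is_e(self, registries, config):
        s = spectrum("x", 400.1230, [(400.1230, 50.0), (238.0702, 100.0)])
        res = assign_glycoside(s, registries, config)
        assert assign_confidence(res) == "E"

    def test_isobaric_aglycone_is_d2(self, registries, config):
        s = spectrum("108", 447.0933, [(447.0933, 20.0), (285.0405, 100.0)])
        res = annotate(s, config, registries)
        assert "/" in res.aglycone
        assert assign_confidence(res) == "D2"


class TestEngineInvariants:
    def test_evidence_soundness_on_reference_spectra(self, table1_results):
        """Every positional claim cites at least one matched peak."""
        for res in table1_results.values():
            if res.positions:
                regio = [
                    e for e in res.evidence
                    if e.rule.startswith("regio") and e.peaks
                ]
                assert regio, res
            if res.acyls:
                assert any(e.rule == "acyl-composition" for e in res.evidence)

    def test_evidence_peaks_exist_in_spectrum(self, table1_spectra, table1_results):
        spectra = {s.identifier: s for s in table1_spectra}
        for ident, res in table1_results.items():
            mzs = {p.mz for p in spectra[ident].peaks} | {
                spectra[ident].precursor_mz
            }
            for e in res.evidence:
                for mz in e.peaks:
                    assert any(abs(mz - m) < 1e-6 for m in mzs)

    @pytest.mark.parametrize("ident", ["7", "22", "34", "54"])
    def test_peak_removal_never_increases_specificity(
        self, ident, by_id, leontopodic_a, registries, config
    ):
        s = leontopodic_a if ident == "54" else by_id[ident]
        base = specificity(annotate(s, config, registries))
        for i in range(len(s.peaks)):
            peaks = s.peaks[:i] + s.peaks[i + 1:]
            if not peaks:
                continue
            pruned = dataclasses.replace(s, peaks=peaks).normalized()
            assert specificity(annotate(pruned, config, registries)) <= base
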