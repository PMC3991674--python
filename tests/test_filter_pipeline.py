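import numpy as np
import pytest

from methylsieve.dataset_io import PSM, Spectrum
from methylsieve.digestion_decoy import ProteinEntry
from methylsieve.filter_pipeline import (
    FdrEstimate,
    PipelineConfig,
    apply_min_spectra,
    assess_spectrum_quality,
    estimate_fdr,
    map_psm_sites,
    run_pipeline,
    seed_and_corroborate,
)
from methylsieve.isobar import CalibrationDistribution
from methylsieve.masschem import (
    ModifiedPeptide,
    fragment_ions,
    mass_to_mz,
    peptide_mass,
)
from methylsieve.synthetic_data import SimulationConfig, simulate_dataset


def make_psm(seq, mods=(), score=60.0, spectrum_id="s1", acc="P1", decoy=False):
    pep = ModifiedPeptide(seq, mods, 2)
    return PSM(
        spectrum_id=spectrum_id,
        run_id="run1",
        peptide=pep,
        observed_precursor_mz=mass_to_mz(peptide_mass(pep), 2),
        charge=2,
        score=score,
        protein_accessions=(acc,),
        is_decoy=decoy,
    )


def full_spectrum(psm):
    peaks = tuple(
        (mz, 50.0) for _, mz in fragment_ions(psm.peptide, ("b", "y"), charge=1)
    )
    return Spectrum(psm.spectrum_id, psm.observed_precursor_mz, psm.charge, peaks)


class TestEstimateFdr:
    def test_paper_formula(self):
        psms = [make_psm("FYWHK", ((5, "monomethyl"),), spectrum_id=f"s{i}")
                for i in range(99)]
        psms.append(
            make_psm("FYWHK", ((5, "monomethyl"),), spectrum_id="d0", decoy=True)
        )
        est = estimate_fdr(psms, 20.0)
        assert est.n_rev == 1 and est.n_real == 99
        assert est.fdr == pytest.approx(0.02)

    def test_zero_decoys_gives_zero(self):
        psms = [make_psm("FYWHK", ((5, "monomethyl"),), spectrum_id=f"s{i}")
                for i in range(5)]
        assert estimate_fdr(psms, 0.0).fdr == 0.0

    def test_capped_at_one(self):
        psms = [
            make_psm("FYWHK", ((5, "monomethyl"),), spectrum_id=f"s{i}",
                     decoy=i < 5)
            for i in range(10)
        ]
        assert estimate_fdr(psms, 0.0).fdr == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError, match="FDR undefined"):
            estimate_fdr([], 0.0)

    def test_nonmethyl_psms_ignored(self):
        psms = [make_psm("FYWH")]
        with pytest.raises(ValueError):
            estimate_fdr(psms, 0.0)

    def test_threshold_applied(self):
        psms = [
            make_psm("FYWHK", ((5, "monomethyl"),), score=30.0, spectrum_id="a"),
            make_psm("FYWHK", ((5, "monomethyl"),), score=70.0, spectrum_id="b"),
        ]
        est = estimate_fdr(psms, 50.0)
        assert est.n_real == 1


class TestSpectrumQuality:
    def test_full_ladder_passes(self):
        psm = make_psm("FYWHLK", ((6, "monomethyl"),))
        result = assess_spectrum_quality(full_spectrum(psm), psm)
        assert result.passed
        assert result.matched_fraction == 1.0
        assert result.n_site_determining > 0

    def test_noise_only_fails(self):
        psm = make_psm("FYWHLK", ((6, "monomethyl"),))
        spec = Spectrum("s1", psm.observed_precursor_mz, 2, ((55.5, 1.0),))
        result = assess_spectrum_quality(spec, psm)
        assert not result.passed
        assert result.matched_fraction == 0.0

    def test_missing_site_fragments_fail_even_with_high_fraction(self):
        psm = make_psm("FFFFFK", ((6, "monomethyl"),))
        # keep only b1..b4 (none cover position 6) and no y ions
        ions = dict(fragment_ions(psm.peptide, ("b",), charge=1))
        peaks = tuple((ions[f"b{i}+"], 50.0) for i in range(1, 5))
        spec = Spectrum("s1", psm.observed_precursor_mz, 2, peaks)
        cfg = PipelineConfig(min_matched_fraction=0.3, min_site_determining_ions=1)
        result = assess_spectrum_quality(spec, psm, cfg)
        assert result.n_site_determining == 0
        assert not result.passed

    def test_id_mismatch_rejected(self):
        psm = make_psm("FYWHLK", ((6, "monomethyl"),))
        spec = Spectrum("other", psm.observed_precursor_mz, 2, ())
        with pytest.raises(ValueError, match="mismatch"):
            assess_spectrum_quality(spec, psm)


PROTEOME = {
    "P1": ProteinEntry("P1", "", "MAWFYWHLKGGFYWHPEK"),
}


class TestSeedAndCorroborate:
    def make_inputs(self, *psms):
        spectra = {p.spectrum_id: full_spectrum(p) for p in psms}
        return list(psms), spectra

    def test_seed_plus_support(self):
        seed = make_psm("FYWHLK", ((6, "monomethyl"),), score=62.0, spectrum_id="a")
        supp = make_psm("FYWHLK", ((6, "monomethyl"),), score=34.0, spectrum_id="b")
        psms, spectra = self.make_inputs(seed, supp)
        cands, _ = seed_and_corroborate(psms, spectra, PROTEOME)
        assert len(cands) == 1
        cand = next(iter(cands.values()))
        assert cand.key == ("P1", 9, "K")
        assert len(cand.support_psms) == 2

    def test_no_seed_no_candidate(self):
        supp = make_psm("FYWHLK", ((6, "monomethyl"),), score=47.0)
        psms, spectra = self.make_inputs(supp)
        cands, _ = seed_and_corroborate(psms, spectra, PROTEOME)
        assert cands == {}

    def test_overlapping_miscleaved_peptides_pool(self):
        short = make_psm("FYWHLK", ((6, "monomethyl"),), score=70.0, spectrum_id="a")
        extended = make_psm(
            "FYWHLKGGFYWHPEK", ((6, "monomethyl"),), score=33.0, spectrum_id="b"
        )
        psms, spectra = self.make_inputs(short, extended)
        cands, _ = seed_and_corroborate(psms, spectra, PROTEOME)
        assert len(cands) == 1
        cand = next(iter(cands.values()))
        assert cand.position == 9
        assert len(cand.support_psms) == 2

    def test_degrees_pooled_across_patterns(self):
        a = make_psm("FYWHLK", ((6, "monomethyl"),), score=70.0, spectrum_id="a")
        b = make_psm("FYWHLK", ((6, "dimethyl"),), score=55.0, spectrum_id="b")
        psms, spectra = self.make_inputs(a, b)
        cands, _ = seed_and_corroborate(psms, spectra, PROTEOME)
        cand = next(iter(cands.values()))
        assert cand.degrees_observed == {1, 2}


class TestMapPsmSites:
    def test_repeated_peptide_flags_alternatives(self):
        proteome = {"P2": ProteinEntry("P2", "", "AAFYWKGGFYWKPP")}
        psm = make_psm("FYWK", ((4, "monomethyl"),), acc="P2")
        hits = map_psm_sites(psm, proteome)
        assert len(hits) == 1
        assert hits[0].position == 6
        assert hits[0].alt_positions == (12,)

    def test_unmapped_peptide_gives_no_hits(self):
        psm = make_psm("GGGGK", ((5, "monomethyl"),))
        assert map_psm_sites(psm, PROTEOME) == []


class TestMinSpectra:
    def _candidate_set(self, n_psms):
        psms = [
            make_psm("FYWHLK", ((6, "monomethyl"),), score=70.0, spectrum_id=f"s{i}")
            for i in range(n_psms)
        ]
        spectra = {p.spectrum_id: full_spectrum(p) for p in psms}
        cands, _ = seed_and_corroborate(psms, spectra, PROTEOME)
        return cands

    def test_single_psm_removed(self):
        assert apply_min_spectra(self._candidate_set(1)) == {}

    def test_two_psms_retained(self):
        assert len(apply_min_spectra(self._candidate_set(2))) == 1

    def test_empty_input(self):
        assert apply_min_spectra({}) == {}


class TestAmbiguityFilters:
    # protein: clean segment FYWHLK then a D-containing extension segment
    PROTEOME = {"P3": ProteinEntry("P3", "", "AAKFYWHLKDFFWHRFWHTLKGGW")}

    def _calib(self):
        return CalibrationDistribution(errors=tuple(np.linspace(-2.0, 2.0, 25)))

    def _candidates(self, psms):
        spectra = {p.spectrum_id: full_spectrum(p) for p in psms}
        cands, _ = seed_and_corroborate(psms, spectra, self.PROTEOME)
        return cands, spectra

    def test_site_relying_solely_on_exact_substitution_removed(self):
        from methylsieve.filter_pipeline import apply_ambiguity_filters

        psms = [
            make_psm("FYWHLKDFFWHR", ((6, "monomethyl"),), score=70.0,
                     spectrum_id=f"s{i}", acc="P3")
            for i in range(2)
        ]
        cands, spectra = self._candidates(psms)
        assert len(cands) == 1
        kept, audit, _ = apply_ambiguity_filters(
            cands, spectra, self._calib(), self.PROTEOME
        )
        assert kept == {}
        assert audit["n_removed_step5"] == 1

    def test_mixed_support_survives_with_flag(self):
        from methylsieve.filter_pipeline import apply_ambiguity_filters

        ambiguous = make_psm(
            "FYWHLKDFFWHR", ((6, "monomethyl"),), score=70.0,
            spectrum_id="a", acc="P3",
        )
        clean = make_psm(
            "FYWHLK", ((6, "monomethyl"),), score=60.0, spectrum_id="b", acc="P3"
        )
        cands, spectra = self._candidates([ambiguous, clean])
        assert len(cands) == 1
        kept, audit, _ = apply_ambiguity_filters(
            cands, spectra, self._calib(), self.PROTEOME
        )
        assert len(kept) == 1
        cand = next(iter(kept.values()))
        assert "substitution" in cand.ambiguity_flags

    def test_acetyl_verdict_removes_site(self):
        from methylsieve.filter_pipeline import apply_ambiguity_filters
        from methylsieve.masschem import mod_delta

        gap = mod_delta("trimethyl") - mod_delta("acetyl")
        pep = ModifiedPeptide("FWHTLK", ((6, "trimethyl"),), 2)
        psms = [
            PSM(
                spectrum_id=f"s{i}",
                run_id="run1",
                peptide=pep,
                observed_precursor_mz=mass_to_mz(peptide_mass(pep) - gap, 2),
                charge=2,
                score=70.0,
                protein_accessions=("P3",),
            )
            for i in range(2)
        ]
        cands, spectra = self._candidates(psms)
        assert len(cands) == 1
        kept, audit, _ = apply_ambiguity_filters(
            cands, spectra, self._calib(), self.PROTEOME
        )
        assert kept == {}
        assert audit["n_removed_step6"] == 1


class TestRunPipeline:
    def test_default_scenario_recovers_truth(self, default_dataset, pipeline_result):
        validated = {s.key for s in pipeline_result.sites}
        assert validated == default_dataset.truth.true_site_keys()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no methyl-PSMs"):
            run_pipeline([], {}, {})

    def test_fdr_reduced_by_pipeline(self, pipeline_result):
        assert pipeline_result.fdr_final.fdr <= pipeline_result.fdr_initial.fdr

    def test_validated_sites_have_min_support(self, pipeline_result):
        cfg = PipelineConfig()
        for site in pipeline_result.sites:
            assert site.n_spectra >= cfg.min_spectra_per_site
            assert site.sc_methyl <= site.sc_total

    def test_audit_structure(self, pipeline_result):
        audit = pipeline_result.audit
        for key in (
            "n_psms_input",
            "n_psms_parsed",
            "fdr_initial",
            "sites_seeded",
            "n_removed_step4",
            "n_removed_step5",
            "n_removed_step6",
            "n_sites_validated",
        ):
            assert key in audit

    def test_raising_seed_score_shrinks_validated_set(self, default_dataset):
        ds = default_dataset
        base = run_pipeline(ds.psms, ds.spectra, ds.proteins, PipelineConfig())
        strict = run_pipeline(
            ds.psms, ds.spectra, ds.proteins, PipelineConfig(seed_score=80.0)
        )
        assert {s.key for s in strict.sites} <= {s.key for s in base.sites}

    def test_deterministic(self, default_dataset):
        ds = default_dataset
        a = run_pipeline(ds.psms, ds.spectra, ds.proteins)
        b = run_pipeline(ds.psms, ds.spectra, ds.proteins)
        assert [s.key for s in a.sites] == [s.key for s in b.sites]
        assert a.audit == b.audit

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(seed_score=10.0, support_score_floor=20.0)
        with pytest.raises(ValueError):
            PipelineConfig(min_spectra_per_site=0)


class TestFdrEstimate:
    def test_fields(self):
        est = FdrEstimate(n_rev=1, n_real=99, score_threshold=20.0)
        assert est.fdr == pytest.approx(0.02)

    def test_cap(self):
        assert FdrEstimate(n_rev=5, n_real=5, score_threshold=0.0).fdr == 1.0
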