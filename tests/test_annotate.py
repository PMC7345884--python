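"""Candidate generation, rule matching, sn assignment, isobar handling."""

import numpy as np
import pytest

from lipidnet.annotate import (
    annotate_dataset,
    contamination_hypotheses,
    disambiguate_isobars,
    generate_candidates,
    match_spectrum,
)
from lipidnet.chem import parse_lipid_name
from lipidnet.msio import Spectrum
from lipidnet.synthetic import (
    SimConfig,
    isobar_scenario,
    noiseless,
    simulate_dataset,
    simulate_spectrum,
    standard_mix,
)


class TestGenerateCandidates:
    def test_pc_precursor_found(self):
        names = [(c.lipid.name, c.ion) for c in generate_candidates(744.5540)]
        assert ("PC (34:1)", "[M-CH3]-") in names

    def test_pe_precursor_found(self):
        names = [(c.lipid.name, c.ion) for c in generate_candidates(800.619)]
        assert ("PE (40:1)", "[M-H]-") in names

    def test_no_candidate_is_valid(self):
        assert generate_candidates(100.0) == []

    def test_sorted_by_mass_error(self):
        errors = [abs(c.dppm) for c in generate_candidates(744.5540)]
        assert errors == sorted(errors)


class TestMatchSpectrum:
    def _candidate(self, mz, name):
        (cand,) = [c for c in generate_candidates(mz)
                   if c.lipid.name == name]
        return cand

    def test_sum_level_candidate_resolved_to_chains(self, noiseless_config):
        spectrum = simulate_spectrum(parse_lipid_name("PC (16:0/18:1)"),
                                     noiseless_config, rng=0)
        ann = match_spectrum(spectrum, self._candidate(744.5540, "PC (34:1)"))
        assert ann.status == "accepted"
        assert ann.name == "PC (16:0/18:1)"
        assert ann.species.chains[1].carbons == 18   # oleate at sn2
        assert ann.n_required_matched >= 6

    def test_sn_assignment_flips_with_intensities(self, noiseless_config):
        """Simulating the opposite regio-isomer flips the reported sn."""
        spectrum = simulate_spectrum(parse_lipid_name("PC (18:1/16:0)"),
                                     noiseless_config, rng=0)
        ann = match_spectrum(spectrum, self._candidate(744.5540, "PC (34:1)"))
        assert ann.name == "PC (18:1/16:0)"
        assert "carboxylate" in ann.sn_basis

    def test_coselected_mixture_yields_co_annotations(self):
        scenario = isobar_scenario(seed=0)
        cand = self._candidate(scenario.feature_mz, "PE (40:1)")
        ann = match_spectrum(scenario.spectrum, cand)
        assert ann.name == scenario.pe_major          # abundant splitting
        assert scenario.pe_minor in [a.name for a in ann.co_annotations]

    def test_missing_carboxylates_reject(self, noiseless_config):
        full = simulate_spectrum(parse_lipid_name("PC (16:0/18:1)"),
                                 noiseless_config, rng=0)
        keep = ~np.isin(np.round(full.mz, 3), [255.233, 281.249])
        gutted = Spectrum(id="gutted", precursor_mz=full.precursor_mz,
                          mz=full.mz[keep], intensity=full.intensity[keep])
        ann = match_spectrum(gutted, self._candidate(744.5540, "PC (34:1)"))
        assert ann.status in ("rejected_ions", "accepted")
        if ann.status == "accepted":   # head evidence allows sum-level only
            assert ann.sum_level_fallback
            assert ann.name == "PC (34:1)"

    def test_deterministic(self, noiseless_config):
        spectrum = simulate_spectrum(parse_lipid_name("PE (16:0/18:2)"),
                                     noiseless_config, rng=1)
        cand = generate_candidates(spectrum.precursor_mz)[0]
        first = match_spectrum(spectrum, cand)
        second = match_spectrum(spectrum, cand)
        assert first == second


class TestDisambiguate:
    def test_seven_percent_rejected_third_of_a_percent_retained(self):
        scenario = isobar_scenario(seed=0)
        anns = [match_spectrum(scenario.spectrum, c)
                for c in generate_candidates(scenario.feature_mz)]
        ranked = disambiguate_isobars(anns, scenario.rt_models,
                                      scenario.observed_rt)
        by_name = {a.name: a for a in ranked}
        decoy = by_name[scenario.pc_decoy]
        winner = by_name[scenario.pe_major]
        assert decoy.status == "rejected_rt"
        assert decoy.rt_relative_error == pytest.approx(0.07, abs=0.005)
        assert winner.status == "accepted"
        assert winner.rt_relative_error == pytest.approx(0.003, abs=0.002)
        assert ranked[0].name == scenario.pe_major

    def test_contamination_hypothesis_names_coselected_sm(self):
        scenario = isobar_scenario(seed=0)
        anns = [match_spectrum(scenario.spectrum, c)
                for c in generate_candidates(scenario.feature_mz)]
        ranked = disambiguate_isobars(anns, scenario.rt_models,
                                      scenario.observed_rt)
        hyps = contamination_hypotheses(scenario.spectrum, ranked[0],
                                        scenario.rt_models,
                                        scenario.observed_rt)
        names = [h.species for h in hyps]
        assert scenario.sm_contaminant.replace("d18:1/24:0", "d42:1") in names
        (sm,) = [h for h in names if h.startswith("SM")]
        hyp = hyps[names.index(sm)]
        assert hyp.delta_th < 1.0
        assert hyp.rt_relative_error < 0.05

    def test_absent_model_leaves_annotation_unchecked(self, noiseless_config):
        spectrum = simulate_spectrum(parse_lipid_name("PG (16:0/18:1)"),
                                     noiseless_config, rng=0)
        anns = [match_spectrum(spectrum, c)
                for c in generate_candidates(spectrum.precursor_mz)]
        ranked = disambiguate_isobars(anns, rt_models={}, observed_rt=7.5)
        assert ranked[0].status == "accepted"
        assert not ranked[0].rt_checked


class TestAnnotateDataset:
    def test_standards_recovered_at_level_one(self, standard_dataset):
        ds = standard_dataset
        models = ds.fit_rt_models()
        library = [s.name for s in standard_mix()]
        result = annotate_dataset(ds.features, ds.spectra,
                                  standards_library=library,
                                  rt_models=models)
        merged = result.merge(ds.truth, on="feature_id",
                              suffixes=("", "_true"))
        accepted = merged[merged["status"] == "accepted"]
        assert (accepted["msi_level"] == 1).all()
        assert (accepted["annotation"] == accepted["species"]).mean() >= 0.95

    def test_species_outside_library_get_level_two(self, standard_dataset):
        ds = standard_dataset
        result = annotate_dataset(ds.features, ds.spectra,
                                  standards_library=["PC (16:0/18:1)"],
                                  rt_models=ds.fit_rt_models())
        accepted = result[result["status"] == "accepted"]
        assert set(accepted["msi_level"]) <= {1, 2}
        assert (accepted.loc[accepted["annotation"] != "PC (16:0/18:1)",
                             "msi_level"] == 2).all()

    def test_zero_noise_closed_loop_is_exact(self):
        ds = simulate_dataset(standard_mix(), noiseless(SimConfig(seed=0)))
        result = annotate_dataset(ds.features, ds.spectra,
                                  rt_models=ds.fit_rt_models())
        merged = result.merge(ds.truth, on="feature_id",
                              suffixes=("", "_true"))
        assert (merged["annotation"] == merged["species"]).all()

    def test_rerun_is_byte_identical(self, standard_dataset):
        ds = standard_dataset
        models = ds.fit_rt_models()
        a = annotate_dataset(ds.features, ds.spectra, rt_models=models)
        b = annotate_dataset(ds.features, ds.spectra, rt_models=models)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_accepted_annotations_obey_tolerances(self, standard_dataset):
        ds = standard_dataset
        result = annotate_dataset(ds.features, ds.spectra,
                                  rt_models=ds.fit_rt_models())
        accepted = result[result["status"] == "accepted"]
        checked = accepted[accepted["rt_checked"].astype(bool)]
        assert (checked["rt_relative_error"] <= 0.05).all()
        assert (accepted["n_required_matched"]
                >= accepted["min_required"]).all()
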