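"""The synthetic-data generator and end-to-end recovery of its ground truth."""

import numpy as np
import pytest

from glycoform.annotate import Peak, Tolerance, annotate_spectrum, fractional_abundances
from glycoform.chem import MassMode, ProteinBackbone, backbone_mass, composition_mass
from glycoform.integrate import ChainLibrary, DimerLibrary, annotate_dimer, chain_pair_label
from glycoform.library import library_from_mapping
from glycoform.metrics import degree_of_core_fucosylation, degree_of_sialylation
from glycoform.simulate import (
    SimulationConfig,
    enumerate_glycoforms,
    simulate_dimer,
    simulate_library,
    simulate_spectrum,
)

BACKBONE = ProteinBackbone("sim", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY")

N_POOL = ["A2G2", "A2S1G1", "A2S2", "A2G2F", "A2S1G1F", "A2S2F", "M5", "A3S3"]
O_POOL = ["core-1", "core-1 + S", "core-1 + 2 S", "2 x core-1 + 2 S", "2 x core-1 + 4 S"]


def small_config(**kw):
    defaults = dict(
        seed=11,
        sites={"N1": N_POOL[:5], "O1": O_POOL[:3]},
        occupancy={"N1": 0.9},
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateLibrary:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        assert simulate_library(cfg).sites == simulate_library(cfg).sites

    def test_different_seeds_differ(self):
        a = simulate_library(small_config(seed=1))
        b = simulate_library(small_config(seed=2))
        assert a.sites != b.sites

    def test_occupancy_encoded_exactly(self):
        cfg = small_config(occupancy={"N1": 0.626})
        lib = simulate_library(cfg)
        assert lib.abundance("N1", "unmodified") == pytest.approx(0.374)

    def test_large_concentration_near_uniform(self):
        cfg = small_config(sites={"N1": N_POOL}, occupancy={}, dirichlet_concentration=1e6)
        lib = simulate_library(cfg)
        weights = [w for _, w in lib.sites["N1"]]
        assert max(weights) - min(weights) < 0.01

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty glycan pool"):
            simulate_library(SimulationConfig(sites={}))
        with pytest.raises(ValueError, match="empty glycan pool"):
            simulate_library(SimulationConfig(sites={"N1": []}))


class TestSimulateSpectrum:
    def test_noise_free_masses_and_intensities_exact(self):
        cfg = small_config(mass_error_sigma=0.0, resolution_window_da=0.001)
        lib = simulate_library(cfg)
        peaks, truth = simulate_spectrum(lib, BACKBONE, cfg)
        bb = backbone_mass(BACKBONE, MassMode.monoisotopic)
        for peak, contributors in zip(peaks, truth.contributors):
            assert peak.intensity == pytest.approx(sum(w for _, w in contributors))
            if len(contributors) == 1:
                entry = contributors[0][0]
                assert peak.mass == pytest.approx(
                    bb + composition_mass(entry.composition, MassMode.monoisotopic), abs=1e-9
                )

    def test_contributions_sum_to_peak_intensity(self):
        cfg = small_config(resolution_window_da=1.5)
        lib = simulate_library(cfg)
        peaks, truth = simulate_spectrum(lib, BACKBONE, cfg)
        for peak, contributors in zip(peaks, truth.contributors):
            assert peak.intensity == pytest.approx(sum(w for _, w in contributors))

    def test_isobaric_merge_within_window(self):
        """One Neu5Ac vs two fucoses (1.02 Da apart, monoisotopic) collapse
        into a single peak at a 3 Da resolution window."""
        lib = library_from_mapping(
            {"s1": [("A2S1G1", 0.5), ("A2G2F", 0.3)], "s2": [("A2G2F", 0.6), ("A2G2", 0.4)]}
        )
        cfg = SimulationConfig(seed=0, resolution_window_da=3.0)
        peaks, truth = simulate_spectrum(lib, BACKBONE, cfg)
        merged = [c for c in truth.contributors if len(c) > 1]
        assert merged, "expected at least one isobaric merge"
        # the Neu5Ac / 2xFuc collision must land in one cluster
        merged_labels = {e.label for c in merged for e, _ in c}
        assert {"A2S1G1/A2G2", "A2G2F/A2G2F"} <= merged_labels
        # every cluster spans less than the resolution window
        bb = backbone_mass(BACKBONE, MassMode.monoisotopic)
        for c in merged:
            masses = [
                bb + composition_mass(e.composition, MassMode.monoisotopic) for e, _ in c
            ]
            assert max(masses) - min(masses) <= 3.0

    def test_adduct_satellites_emitted(self):
        cfg = small_config(adduct_probability=1.0, adduct_intensity_ratio=0.25)
        lib = simulate_library(cfg)
        peaks, truth = simulate_spectrum(lib, BACKBONE, cfg)
        kinds = list(truth.peak_kinds)
        assert kinds.count("adduct") == kinds.count("signal")
        for i, kind in enumerate(kinds):
            if kind == "adduct":
                parent = peaks[i - 1]
                assert peaks[i].mass - parent.mass == pytest.approx(21.98194, abs=1e-6)
                assert peaks[i].intensity == pytest.approx(parent.intensity * 0.25)

    def test_determinism_end_to_end(self):
        cfg = small_config(mass_error_sigma=20.0, adduct_probability=0.3, intensity_noise_sigma=0.2)
        lib = simulate_library(cfg)
        p1, _ = simulate_spectrum(lib, BACKBONE, cfg)
        p2, _ = simulate_spectrum(lib, BACKBONE, cfg)
        assert [(p.mass, p.intensity) for p in p1] == [(p.mass, p.intensity) for p in p2]


class TestRecovery:
    def test_sigma_zero_exact_contributor_recovery(self):
        """With no mass error the engine recovers each merged peak's true
        contributor set exactly."""
        cfg = small_config(mass_error_sigma=0.0, resolution_window_da=0.1)
        lib = simulate_library(cfg)
        peaks, truth = simulate_spectrum(lib, BACKBONE, cfg)
        annotated = annotate_spectrum(peaks, BACKBONE, lib, Tolerance(20, "ppm"))
        for ap, contributors in zip(annotated, truth.contributors):
            true_labels = {e.label for e, _ in contributors}
            got_labels = {a.label for a in ap.assignments}
            assert true_labels <= got_labels

    def test_recovered_abundances_match_truth(self):
        cfg = small_config(mass_error_sigma=0.0)
        lib = simulate_library(cfg)
        peaks, truth = simulate_spectrum(lib, BACKBONE, cfg)
        annotated = annotate_spectrum(peaks, BACKBONE, lib, Tolerance(20, "ppm"))
        recovered = {e.label: e.abundance for e in fractional_abundances(annotated)}
        for entry in truth.entries:
            assert recovered.get(entry.label, 0.0) == pytest.approx(entry.abundance, abs=5e-3)

    def test_cqa_closure_sigma_zero(self):
        cfg = small_config(mass_error_sigma=0.0)
        lib = simulate_library(cfg)
        peaks, truth = simulate_spectrum(lib, BACKBONE, cfg)
        annotated = annotate_spectrum(peaks, BACKBONE, lib, Tolerance(20, "ppm"))
        entries = fractional_abundances(annotated)
        assert degree_of_sialylation(entries) == pytest.approx(truth.sialylation, abs=1e-6)
        assert degree_of_core_fucosylation(entries) == pytest.approx(
            truth.core_fucosylation, abs=1e-6
        )


class TestTransformConsistency:
    def test_desialylated_annotation_recovers_stripped_truth(self):
        """Annotating a synthetic sialidase-treated spectrum with the
        in-silico desialylated library recovers the Neu5Ac-stripped version
        of the sialylated ground truth (species merged by the transform)."""
        from glycoform.chem import desialylate_species
        from glycoform.library import desialylate_library

        lib = library_from_mapping(
            {
                "N1": [("A2S2", 0.5), ("A2S1G1", 0.3), ("A2G2F", 0.2)],
                "O1": [("core-1 + 2 S", 0.6), ("core-1", 0.4)],
            }
        )
        desial = desialylate_library(lib)
        cfg = SimulationConfig(seed=2, resolution_window_da=0.1)
        peaks, truth = simulate_spectrum(desial, BACKBONE, cfg)
        annotated = annotate_spectrum(peaks, BACKBONE, desial, Tolerance(20, "ppm"))
        recovered = {e.label: e.abundance for e in fractional_abundances(annotated)}
        # strip the sialylated truth by hand and merge
        expected: dict[str, float] = {}
        for entry in enumerate_glycoforms(lib):
            label = "/".join(desialylate_species(sp).name for sp in entry.species)
            expected[label] = expected.get(label, 0.0) + entry.abundance
        assert set(recovered) == set(expected)
        for label, w in expected.items():
            assert recovered[label] == pytest.approx(w, abs=1e-9)


class TestCrossLevelConsistency:
    def test_dimer_degree_combines_chain_degrees(self):
        """With uniform sialylation capacity per chain (every glycoform of a
        chain can carry the same number of Neu5Ac), the dimer-level degree is
        the capacity-weighted mean of the chain-level degrees."""
        ea = enumerate_glycoforms(
            library_from_mapping(
                {"N1": [("A2S2", 0.5), ("A2G2", 0.5)]}, mass_mode=MassMode.average
            )
        )
        eb = enumerate_glycoforms(
            library_from_mapping(
                {"O1": [("core-1 + 2 S", 0.4), ("core-1", 0.6)]},
                mass_mode=MassMode.average,
            )
        )
        cfg = SimulationConfig(
            seed=0, mass_mode=MassMode.average, resolution_window_da=3.0, abundance_floor=0.0
        )
        _, truth = simulate_dimer(ea, eb, BACKBONE, BACKBONE, cfg)
        d_a = degree_of_sialylation(ea)
        d_b = degree_of_sialylation(eb)
        # both chains have capacity 2 -> equal weights
        assert truth.sialylation == pytest.approx((d_a + d_b) / 2, abs=1e-12)


class TestSimulateDimer:
    def _chains(self):
        cfg_a = SimulationConfig(
            seed=3, sites={"N1": N_POOL[:4]}, mass_mode=MassMode.average
        )
        cfg_b = SimulationConfig(
            seed=4, sites={"N2": N_POOL[2:6], "O1": O_POOL[:3]}, mass_mode=MassMode.average
        )
        lib_a = simulate_library(cfg_a)
        lib_b = simulate_library(cfg_b)
        return enumerate_glycoforms(lib_a), enumerate_glycoforms(lib_b)

    def test_single_glycoform_chains_one_peak(self):
        ea = enumerate_glycoforms(
            library_from_mapping({"N1": [("A2S2", 1.0)]}, mass_mode=MassMode.average)
        )
        eb = enumerate_glycoforms(
            library_from_mapping({"O1": [("core-1 + S", 1.0)]}, mass_mode=MassMode.average)
        )
        cfg = SimulationConfig(seed=0, mass_mode=MassMode.average, resolution_window_da=3.0)
        peaks, truth = simulate_dimer(ea, eb, BACKBONE, BACKBONE, cfg)
        assert len(peaks) == 1
        expected = 2 * backbone_mass(BACKBONE, MassMode.average) + composition_mass(
            ea[0].composition + eb[0].composition, MassMode.average
        )
        assert peaks[0].mass == pytest.approx(expected, abs=1e-9)

    def test_pair_count_bounded_by_product(self):
        ea, eb = self._chains()
        cfg = SimulationConfig(
            seed=5, mass_mode=MassMode.average, resolution_window_da=3.0, abundance_floor=1e-6
        )
        peaks, truth = simulate_dimer(ea, eb, BACKBONE, BACKBONE, cfg)
        assert len(truth.entries) <= len(ea) * len(eb)

    def test_marginal_chain_abundances_recovered(self):
        """Independent pairing: summing pair abundances over one chain
        recovers the other chain's marginals."""
        ea, eb = self._chains()
        cfg = SimulationConfig(
            seed=5, mass_mode=MassMode.average, resolution_window_da=3.0, abundance_floor=0.0
        )
        _, truth = simulate_dimer(ea, eb, BACKBONE, BACKBONE, cfg)
        marg: dict[str, float] = {}
        for pair in truth.entries:
            label_a = pair.label.split(" // ")[0]
            marg[label_a] = marg.get(label_a, 0.0) + pair.abundance
        total_a = sum(e.abundance for e in ea)
        for e in ea:
            assert marg[e.label] == pytest.approx(e.abundance / total_a, abs=1e-12)

    def test_dimer_recovery_with_truncated_libraries(self):
        ea, eb = self._chains()
        cfg = SimulationConfig(
            seed=6, mass_mode=MassMode.average, resolution_window_da=3.0
        )
        chain_a = ProteinBackbone("A", BACKBONE.sequence)
        chain_b = ProteinBackbone("B", BACKBONE.sequence)
        peaks, truth = simulate_dimer(ea, eb, chain_a, chain_b, cfg)
        lib = DimerLibrary(
            chain_a=ChainLibrary(chain_a, tuple(ea)), chain_b=ChainLibrary(chain_b, tuple(eb))
        )
        annotated = annotate_dimer(peaks, lib, Tolerance(3.0, "Da"))
        for ap, contributors in zip(annotated, truth.contributors):
            true_pairs = {tuple(e.label.split(" // ")) for e, _ in contributors}
            got_pairs = {chain_pair_label(a) for a in ap.assignments}
            assert true_pairs <= got_pairs
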