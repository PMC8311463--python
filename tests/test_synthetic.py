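"""Synthetic-data generators: constraints, determinism, round trips."""

import numpy as np
import pytest

from cyclopept.errors import CyclopeptError
from cyclopept.masses import mz, peptide_neutral_mass
from cyclopept.msms import annotate_spectrum
from cyclopept.screen import ScreenParams, match_series
from cyclopept.synthetic import (
    GeneratorConfig,
    generate_cyclotide_like,
    simulate_derivatization_peaklists,
    simulate_dose_response,
    simulate_msms,
)


class TestGenerateCyclotideLike:
    def test_scaffold_constraints(self):
        cfg = GeneratorConfig(seed=42, n_peptides=25)
        peptides, truth = generate_cyclotide_like(cfg)
        assert len(peptides) == 25
        for p in peptides:
            assert p.topology == "cyclic"
            assert p.n_cys == 6
            assert p.sequence.count("E") == 1
            assert p.sequence[-1] in "ND"  # ligation residue closes loop 6
        assert (truth["n_cys"] == 6).all()
        assert (truth["n_glu"] == 1).all()

    def test_determinism_same_seed(self):
        cfg = GeneratorConfig(seed=42, n_peptides=10)
        a, _ = generate_cyclotide_like(cfg)
        b, _ = generate_cyclotide_like(cfg)
        assert [p.sequence for p in a] == [p.sequence for p in b]

    def test_masses_inside_screening_window(self):
        cfg = GeneratorConfig(seed=1, n_peptides=50)
        peptides, truth = generate_cyclotide_like(cfg)
        mhs = truth["native_mh"].to_numpy()
        assert (mhs >= 2900.0).all() and (mhs <= 3550.0).all()
        # truth table agrees with direct mass computation
        direct = [mz(peptide_neutral_mass(p)) for p in peptides]
        assert np.allclose(mhs, direct)

    def test_infeasible_loop_ranges_rejected(self):
        with pytest.raises(CyclopeptError):
            GeneratorConfig(loop_len_ranges={1: (3, 2)})


class TestDerivatizationPeaklists:
    def test_noise_free_round_trip_full_recovery(self):
        cfg = GeneratorConfig(seed=5, n_peptides=30, ppm_noise_sd=0.0,
                              decoys_per_list=0)
        peptides, _ = generate_cyclotide_like(cfg)
        lists, truth = simulate_derivatization_peaklists(peptides, cfg)
        series = match_series(
            lists["native"], lists["reduced"], lists["alkylated"],
            lists["linearized"],
            ScreenParams(tolerance_mode="ppm", tolerance_value=25.0),
        )
        assert len(series) == len(peptides)
        assert all(s.inferred_n_cys == 6 for s in series)

    def test_linearized_dropout_marks_incomplete(self):
        cfg = GeneratorConfig(seed=6, n_peptides=10, ppm_noise_sd=0.0,
                              decoys_per_list=0, dropout_prob=1.0)
        peptides, _ = generate_cyclotide_like(cfg)
        lists, _ = simulate_derivatization_peaklists(peptides, cfg)
        assert len(lists["linearized"]) == 0
        series = match_series(
            lists["native"], lists["reduced"], lists["alkylated"],
            lists["linearized"],
            ScreenParams(tolerance_mode="ppm", tolerance_value=25.0),
        )
        assert all(s.classification == "incomplete" for s in series)

    def test_recovery_at_reference_noise_and_tolerance(self):
        """8 ppm per-step mass error, 25 ppm tolerance: >=99% of 500
        planted peptides recovered with the true cysteine count, and no
        decoy-anchored series.  The 500 peptides are spread over 25
        extracts of 20, matching the ~20-peptide-per-extract density the
        screen is designed for."""
        params = ScreenParams(tolerance_mode="ppm", tolerance_value=25.0)
        total = recovered = false_pos = 0
        for extract in range(25):
            cfg = GeneratorConfig(seed=1000 + extract, n_peptides=20,
                                  ppm_noise_sd=8.0, decoys_per_list=10)
            peptides, _ = generate_cyclotide_like(cfg)
            lists, truth = simulate_derivatization_peaklists(peptides, cfg)
            series = match_series(
                lists["native"], lists["reduced"], lists["alkylated"],
                lists["linearized"], params,
            )
            planted = truth["native_mz"].to_numpy()
            total += len(peptides)
            for s in series:
                d = np.abs(planted - s.native_mz)
                if d.min() < 1e-9 and s.inferred_n_cys == 6:
                    recovered += 1
                else:
                    false_pos += 1  # decoy-anchored or wrong cysteine count
        assert total == 500
        assert recovered / total >= 0.99
        assert false_pos == 0

    def test_decoys_kept_away_from_true_peaks(self):
        cfg = GeneratorConfig(seed=8, n_peptides=20, ppm_noise_sd=0.0,
                              decoys_per_list=15)
        peptides, _ = generate_cyclotide_like(cfg)
        lists, truth = simulate_derivatization_peaklists(peptides, cfg)
        true_mzs = np.sort(
            np.concatenate(
                [truth[f"{lab}_mz"].to_numpy() for lab in lists]
            )
        )
        for pl in lists.values():
            for m in pl.mz:
                d = np.min(np.abs(true_mzs - m))
                if d > 1e-9:  # this is a decoy
                    assert d >= 3 * 25e-6 * m * 0.999

    def test_determinism(self):
        cfg = GeneratorConfig(seed=13, n_peptides=10, decoys_per_list=5)
        peptides, _ = generate_cyclotide_like(cfg)
        l1, t1 = simulate_derivatization_peaklists(peptides, cfg)
        l2, t2 = simulate_derivatization_peaklists(peptides, cfg)
        for lab in l1:
            assert np.array_equal(l1[lab].mz, l2[lab].mz)
        assert t1.equals(t2)


class TestSimulateMsms:
    def test_full_sampling_no_noise_gives_complete_coverage(self):
        cfg = GeneratorConfig(seed=3, msms_ion_prob=1.0, msms_loss_prob=0.0,
                              msms_noise_peaks=0, msms_mz_jitter_sd=0.0)
        seq = "GVIPCGESCVFIPCISAAIG"
        spec, truth = simulate_msms(seq, cfg)
        res = annotate_spectrum(spec, seq, "carbamidomethylated", 0.01)
        assert res.coverage == 1.0

    def test_zero_ion_probability_gives_zero_coverage(self):
        cfg = GeneratorConfig(seed=3, msms_ion_prob=0.0, msms_loss_prob=0.0,
                              msms_noise_peaks=0)
        seq = "GVIPCGESCVFIPCISAAIG"
        spec, truth = simulate_msms(seq, cfg)
        res = annotate_spectrum(spec, seq, "carbamidomethylated", 0.01)
        assert res.coverage == 0.0

    def test_mean_coverage_near_binomial_expectation(self):
        """Each internal boundary is verified unless both its b and y base
        ions are missing; termini follow from any match."""
        p = 0.7
        n = 20
        seq_rng = np.random.default_rng(100)
        aas = np.array(list("ACDFGHKNPQRSTVWY"))  # no I/L/M/E ambiguity needed
        covs = []
        for trial in range(100):
            cfg = GeneratorConfig(seed=trial, msms_ion_prob=p,
                                  msms_loss_prob=0.0, msms_noise_peaks=0,
                                  msms_mz_jitter_sd=0.0)
            seq = "".join(seq_rng.choice(aas, size=n))
            spec, _ = simulate_msms(seq, cfg, cys_state="reduced")
            covs.append(
                annotate_spectrum(spec, seq, "reduced", 0.01).coverage
            )
        q = 1 - (1 - p) ** 2  # boundary verified by b or y
        # interior residue unsupported iff both adjacent boundaries missing;
        # termini are anchored by the known precursor once anything matches
        expect = 1 - (n - 2) * (1 - q) ** 2 / n
        assert np.mean(covs) == pytest.approx(expect, abs=0.05)

    def test_truth_lists_every_ion(self):
        cfg = GeneratorConfig(seed=3)
        seq = "GVIPCGESCV"
        spec, truth = simulate_msms(seq, cfg)
        assert set(truth["series"]) == {"b", "y"}
        assert truth["index"].max() == len(seq) - 1
        assert {"none", "NH3", "H2O"} == set(truth["loss"])


class TestSimulateDoseResponse:
    def test_noise_free_exact_recovery(self):
        from cyclopept.assay import fit_4pl

        cfg = GeneratorConfig(seed=1, dr_noise_cv=0.0)
        table, truth = simulate_dose_response(cfg)
        fit = fit_4pl(
            np.log10(table["concentration"].to_numpy()),
            table["response"].to_numpy(),
        )
        assert fit.ic50 == pytest.approx(truth["ic50"], rel=1e-6)
        assert fit.hill_slope == pytest.approx(truth["hill_slope"], abs=1e-6)
        assert fit.top == pytest.approx(truth["top"], abs=1e-6)

    def test_shape_and_units(self):
        cfg = GeneratorConfig(seed=2)
        table, truth = simulate_dose_response(cfg)
        assert len(table) == len(cfg.dr_doses) * cfg.dr_replicates
        assert set(table["unit"]) == {"uM"}
        assert truth["seed"] == 2

    def test_saturating_design_flagged(self):
        from cyclopept.assay import fit_4pl

        cfg = GeneratorConfig(
            seed=3, dr_noise_cv=0.0,
            dr_doses=tuple(np.geomspace(1e3, 1e5, 6)),
        )
        table, _ = simulate_dose_response(cfg)
        fit = fit_4pl(
            np.log10(table["concentration"].to_numpy()),
            table["response"].to_numpy(),
        )
        assert not fit.converged
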