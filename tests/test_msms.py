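"""b/y ladders, spectrum annotation, evidence merging, Ile/Leu calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclopept.errors import CyclopeptError
from cyclopept.masses import PROTON, Peptide, peptide_neutral_mass
from cyclopept.msms import (
    AmbiguousSequence,
    annotate_spectrum,
    combine_evidence,
    resolve_ile_leu,
    theoretical_ions,
)
from cyclopept.peaks import PeakList
from cyclopept.refdata import ALCA2_SEQUENCE
from cyclopept.synthetic import GeneratorConfig, simulate_msms

seq_st = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=25)


def _ladder_spectrum(seq, cys_state="reduced", series=("b", "y")):
    ions = [
        i for i in theoretical_ions(seq, cys_state, losses=False)
        if i.series in series
    ]
    mzs = sorted({round(i.mz1, 6) for i in ions})
    return PeakList.from_pairs(mzs, "msms")


class TestTheoreticalIons:
    def test_ga_y1_is_protonated_alanine(self):
        ions = {
            (i.series, i.index): i.mz1
            for i in theoretical_ions("GA", "reduced", losses=False)
        }
        assert ions[("y", 1)] == pytest.approx(
            71.03711 + 18.010565 + 1.007276, abs=1e-4
        )

    def test_ladder_counts(self):
        seq = "SCVFIPCISAAIGCSCKNKVCYRDGVIPCGE"
        ions = theoretical_ions(seq, "carbamidomethylated", losses=True)
        n = len(seq)
        # (n-1) indices x 2 series x 3 loss states
        assert len(ions) == (n - 1) * 2 * 3
        per = [
            i for i in ions if i.series == "b" and i.loss == "none"
        ]
        assert len(per) == n - 1

    @given(seq=seq_st)
    @settings(max_examples=50, deadline=None)
    def test_by_complementarity_identity(self, seq):
        """mz(b_i) + mz(y_{n-i}) = M + 2 protons for every split."""
        n = len(seq)
        M = peptide_neutral_mass(Peptide(seq))
        ions = {
            (i.series, i.index): i.mz1
            for i in theoretical_ions(seq, "reduced", losses=False)
        }
        for i in range(1, n):
            total = ions[("b", i)] + ions[("y", n - i)]
            assert total == pytest.approx(M + 2 * PROTON, abs=1e-6)

    def test_single_residue_rejected(self):
        with pytest.raises(CyclopeptError):
            theoretical_ions("G")


class TestAnnotateSpectrum:
    def test_full_ladder_gives_complete_coverage(self):
        seq = "GVIPCGESCVFIPCI"
        res = annotate_spectrum(_ladder_spectrum(seq), seq, "reduced", 0.05)
        assert res.coverage == 1.0
        assert res.unsupported_positions == []

    def test_y_series_alone_suffices(self):
        seq = "GVIPCGESCVFIPCI"
        res = annotate_spectrum(
            _ladder_spectrum(seq, series=("y",)), seq, "reduced", 0.05
        )
        assert res.coverage == 1.0

    def test_empty_spectrum_coverage_zero(self):
        res = annotate_spectrum(
            PeakList(np.empty(0), np.empty(0), "msms"), "GVIPCGESC", "reduced", 0.3
        )
        assert res.coverage == 0.0
        assert res.matched_ions == []

    def test_removing_boundary_ions_unsupports_positions(self):
        """Dropping every ion bounding positions 3-4 leaves exactly those
        two residues unverified."""
        seq = "GVIPCGESCV"
        n = len(seq)
        drop = {("b", 2), ("b", 3), ("b", 4), ("y", n - 2), ("y", n - 3), ("y", n - 4)}
        ions = [
            i for i in theoretical_ions(seq, "reduced", losses=False)
            if (i.series, i.index) not in drop
        ]
        spec = PeakList.from_pairs(sorted({round(i.mz1, 6) for i in ions}), "msms")
        res = annotate_spectrum(spec, seq, "reduced", 0.05)
        assert res.unsupported_positions == [3, 4]
        assert res.coverage == pytest.approx((n - 2) / n)

    def test_coverage_monotone_in_tolerance(self):
        rng = np.random.default_rng(5)
        seq = "GVIPCGESCVFIPCI"
        ions = theoretical_ions(seq, "reduced", losses=False)
        mzs = sorted(i.mz1 + rng.normal(0, 0.1) for i in ions)
        spec = PeakList.from_pairs(mzs, "msms")
        covs = [
            annotate_spectrum(spec, seq, "reduced", tol).coverage
            for tol in (0.01, 0.05, 0.1, 0.3, 0.5)
        ]
        assert covs == sorted(covs)

    def test_simulated_noise_free_round_trip(self):
        cfg = GeneratorConfig(seed=2, msms_ion_prob=1.0, msms_loss_prob=0.0,
                              msms_noise_peaks=0, msms_mz_jitter_sd=0.0)
        seq = "SCVFIPCISAAIGCSCK"
        spec, truth = simulate_msms(seq, cfg)
        res = annotate_spectrum(spec, seq, "carbamidomethylated", 0.01)
        assert res.coverage == 1.0


class TestCombineEvidence:
    def test_single_input_identity(self):
        seq = "GVIPCGESCV"
        res = annotate_spectrum(_ladder_spectrum(seq), seq, "reduced", 0.05)
        merged = combine_evidence([res])
        assert merged.coverage == res.coverage
        assert list(merged.residue_support) == list(res.residue_support)

    def test_complementary_gaps_merge_to_full_coverage(self):
        """Two opened forms of one cyclic parent with disjoint gaps."""
        parent = "GVIPCGESCV"  # cyclic coordinates 0..9
        n = len(parent)
        # opening 1: as written; drop ions bounding position 4
        drop1 = {("b", 3), ("b", 4), ("y", n - 3), ("y", n - 4)}
        ions1 = [
            i for i in theoretical_ions(parent, "reduced", losses=False)
            if (i.series, i.index) not in drop1
        ]
        spec1 = PeakList.from_pairs(sorted({round(i.mz1, 6) for i in ions1}), "msms")
        r1 = annotate_spectrum(spec1, parent, "reduced", 0.05,
                               parent_offset=0, parent_length=n)
        assert 4 in r1.unsupported_positions
        # opening 2: rotated by 5; full ladder
        rot = parent[5:] + parent[:5]
        r2 = annotate_spectrum(_ladder_spectrum(rot), rot, "reduced", 0.05,
                               parent_offset=5, parent_length=n)
        merged = combine_evidence([r1, r2])
        assert merged.coverage == 1.0

    def test_inconsistent_lengths_rejected(self):
        a = annotate_spectrum(_ladder_spectrum("GVIPC"), "GVIPC", "reduced", 0.05)
        b = annotate_spectrum(_ladder_spectrum("GVIPCA"), "GVIPCA", "reduced", 0.05)
        with pytest.raises(CyclopeptError):
            combine_evidence([a, b])


class TestResolveIleLeu:
    def test_alca2_positions_resolved_from_chymo_fragments(self):
        """Written positions 2, 11, 14 are Ile (spanned uncut), 18 is Leu
        (observed fragment boundary after it)."""
        amb = "".join(
            "J" if i + 1 in (2, 11, 14, 18) else aa
            for i, aa in enumerate(ALCA2_SEQUENCE)
        )
        parent = Peptide(ALCA2_SEQUENCE, "cyclic", "carbamidomethylated", 0)
        # theoretical masses of the three diagnostic chymotryptic fragments
        from cyclopept.digest import CHYMOTRYPSIN, digest_peptide

        frags = {
            f.sequence: f.mz1
            for f in digest_peptide(parent, CHYMOTRYPSIN, max_missed=3)
        }
        observed = PeakList.from_pairs(
            sorted(
                frags[s]
                for s in ("IPCISGVL", "IPCISGVLGCSCSNKVCY", "RNGIPCGESCVF")
            ),
            "peaks",
        )
        res = resolve_ile_leu(AmbiguousSequence(amb), observed, parent, 0.2)
        assert res.resolved[18] == ("L", "chymotryptic_cleavage")
        for pos in (2, 11, 14):
            assert res.resolved[pos] == ("I", "chymotryptic_cleavage")
        assert res.apply() == ALCA2_SEQUENCE

    def test_no_j_positions_returns_input(self):
        parent = Peptide("GVAPCGESCV", "cyclic", "reduced", 0)
        amb = AmbiguousSequence("GVAPCGESCV")
        res = resolve_ile_leu(
            amb, PeakList.from_pairs([500.0], "peaks"), parent, 0.2
        )
        assert res.apply() == "GVAPCGESCV"
        assert res.resolved == {}

    def test_planted_leu_recovered_from_complete_fragment_set(self):
        seq = "GACISGVLGAKSF"  # L at 8, F at 13; I at 4 spanned
        parent = Peptide(seq, "cyclic", "reduced", 0)
        from cyclopept.digest import CHYMOTRYPSIN, digest_peptide

        frag_mzs = sorted(
            {round(f.mz1, 5) for f in digest_peptide(parent, CHYMOTRYPSIN, 2)}
        )
        amb = "".join("J" if i + 1 in (4, 8) else aa for i, aa in enumerate(seq))
        res = resolve_ile_leu(
            AmbiguousSequence(amb),
            PeakList.from_pairs(frag_mzs, "peaks"),
            parent,
            0.02,
        )
        assert res.resolved[8][0] == "L"
        assert res.resolved[4][0] == "I"

    def test_never_flips_without_observed_fragment(self):
        amb = "".join(
            "J" if i + 1 in (2, 11, 14, 18) else aa
            for i, aa in enumerate(ALCA2_SEQUENCE)
        )
        parent = Peptide(ALCA2_SEQUENCE, "cyclic", "carbamidomethylated", 0)
        res = resolve_ile_leu(
            AmbiguousSequence(amb),
            PeakList.from_pairs([123.456], "peaks"),
            parent,
            0.2,
        )
        assert all(v == ("J", "none") for v in res.resolved.values())
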