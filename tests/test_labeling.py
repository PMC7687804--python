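import numpy as np
import pytest

from silamdyn.classify import classify_psms
from silamdyn.io import FormatError, Modification, PsmRecord
from silamdyn.labeling import (
    call_label,
    incorporation_distribution,
    incorporation_profiles,
    labeled_peptidome_fraction,
    labeled_proteome_fraction,
)
from silamdyn.simulate import SyntheticConfig, generate_proteome, generate_psm_tables

from .conftest import psm

EC_CONTROL = ("Control", "EC")


class TestCallLabel:
    def test_single_labeled_lysine(self):
        call = call_label(psm("ASK(+6.02)LR", "s1"))
        assert call.labeled
        assert call.n_labeled_lysines == 1
        assert call.n_lysines == 1
        assert call.mass_shift == pytest.approx(6.0201)

    def test_no_lysine_never_labeled(self):
        call = call_label(psm("ASTLR", "s1"))
        assert not call.labeled
        assert call.n_lysines == 0
        assert call.mass_shift == 0.0

    def test_two_labels_additive_shift(self):
        call = call_label(psm("AK(+6.02)TK(+6.02)R", "s1"))
        assert call.n_labeled_lysines == 2
        assert call.mass_shift == pytest.approx(2 * 6.0201)

    def test_partial_labeling_counts_all_lysines(self):
        call = call_label(psm("AK(+6.02)TKR", "s1"))
        assert (call.n_labeled_lysines, call.n_lysines) == (1, 2)

    def test_k6_on_non_lysine_rejected(self):
        bad = PsmRecord.__new__(PsmRecord)  # bypass record validation
        object.__setattr__(bad, "peptide", "ASTLR")
        object.__setattr__(
            bad, "modifications", (Modification("label-K6", 6.0201, 2, "S"),)
        )
        object.__setattr__(bad, "protein_accessions", ("P1",))
        object.__setattr__(bad, "spectral_count", 1)
        object.__setattr__(bad, "sample_id", "s1")
        with pytest.raises(FormatError):
            call_label(bad)

    def test_order_independent(self):
        a = psm("AK(+6.02)TK(+6.02)R", "s1")
        b = PsmRecord(
            a.peptide, tuple(reversed(a.modifications)), a.protein_accessions, 1, "s1"
        )
        assert call_label(a) == call_label(b)


def _classified(psms, proteome):
    return classify_psms(psms, proteome)


class TestFractions:
    def _setup(self, two_group_design, tiny_proteome):
        # P1 labeled in 2 animals, P2 never labeled
        psms = [
            psm("LSTK(+6.02)PEWIDNK", "Control_EC_a1", 2, ("P1",)),
            psm("LSTK(+6.02)PEWIDNK", "Control_EC_a2", 1, ("P1",)),
            psm("AGER", "Control_EC_a3", 4, ("P1",)),
            psm("TTTRPLLVK", "Control_EC_a1", 5, ("P2",)),
            psm("YEEDR", "Control_EC_a2", 3, ("P2",)),
        ]
        return _classified(psms, tiny_proteome)

    def test_proteome_fraction_with_consistency(self, two_group_design, tiny_proteome):
        cl = self._setup(two_group_design, tiny_proteome)
        pf = labeled_proteome_fraction(cl, two_group_design, EC_CONTROL)
        assert (pf.n_labeled, pf.n_detected) == (1, 2)
        assert pf.fraction == 0.5

    def test_consistency_requires_two_animals(self, two_group_design, tiny_proteome):
        psms = [
            psm("LSTK(+6.02)PEWIDNK", "Control_EC_a1", 2, ("P1",)),
            psm("AGER", "Control_EC_a2", 4, ("P1",)),
            psm("YEEDR", "Control_EC_a2", 3, ("P2",)),
        ]
        cl = _classified(psms, tiny_proteome)
        pf = labeled_proteome_fraction(cl, two_group_design, EC_CONTROL)
        assert pf.n_labeled == 0  # labeled in only one animal

    def test_no_labels_gives_zero(self, two_group_design, tiny_proteome):
        psms = [psm("AGER", "Control_EC_a1", 1, ("P1",))]
        pf = labeled_proteome_fraction(
            _classified(psms, tiny_proteome), two_group_design, EC_CONTROL
        )
        assert pf.fraction == 0.0

    def test_empty_group_raises(self, two_group_design, tiny_proteome):
        with pytest.raises(ValueError):
            labeled_proteome_fraction([], two_group_design, EC_CONTROL)

    def test_peptidome_fraction_distinct(self, two_group_design, tiny_proteome):
        cl = self._setup(two_group_design, tiny_proteome)
        ppf = labeled_peptidome_fraction(cl, two_group_design, EC_CONTROL)
        # 4 distinct peptides, 1 labeled
        assert (ppf.n_labeled, ppf.n_total) == (1, 4)
        assert ppf.fraction == 0.25

    def test_peptidome_all_labeled(self, two_group_design, tiny_proteome):
        psms = [psm("LSTK(+6.02)PEWIDNK", "Control_EC_a1", 2, ("P1",))]
        ppf = labeled_peptidome_fraction(
            _classified(psms, tiny_proteome), two_group_design, EC_CONTROL
        )
        assert ppf.fraction == 1.0

    def test_conservation_labeled_plus_unlabeled(self, two_group_design, tiny_proteome):
        cl = self._setup(two_group_design, tiny_proteome)
        for p in incorporation_profiles(cl, two_group_design, EC_CONTROL):
            unlabeled = p.total_sc - p.labeled_sc
            assert unlabeled >= 0
            assert p.labeled_sc + unlabeled == p.total_sc
            assert 0.0 <= p.incorporation_fraction <= 1.0


class TestIncorporationDistribution:
    def test_single_protein_step_function(self, two_group_design, tiny_proteome):
        cl = _classified(
            [psm("LSTK(+6.02)PEWIDNK", "Control_EC_a1", 2, ("P1",)),
             psm("AGER", "Control_EC_a1", 3, ("P1",))],
            tiny_proteome,
        )
        profiles = incorporation_profiles(cl, two_group_design, EC_CONTROL)
        x, y = incorporation_distribution(profiles)
        assert x.tolist() == [0.4]
        assert y.tolist() == [1.0]

    def test_monotone_and_deterministic(self):
        cfg = SyntheticConfig(n_proteins=40, seed=5, groups=(EC_CONTROL,))
        proteome = generate_proteome(cfg)
        psms, design, _ = generate_psm_tables(cfg, proteome)
        cl = classify_psms(psms, proteome)
        profiles = incorporation_profiles(cl, design, EC_CONTROL)
        x1, y1 = incorporation_distribution(profiles)
        x2, y2 = incorporation_distribution(profiles)
        assert np.all(np.diff(y1) >= 0) and np.all(np.diff(x1) >= 0)
        assert np.array_equal(x1, x2) and np.array_equal(y1, y2)

    def test_lower_label_probability_shifts_curve_left(self):
        fracs = {}
        for p in (0.3, 0.15):
            cfg = SyntheticConfig(
                n_proteins=150, seed=42, groups=(EC_CONTROL,),
                protein_label_prob=1.0, peptide_label_prob=p,
            )
            proteome = generate_proteome(cfg)
            psms, design, _ = generate_psm_tables(cfg, proteome)
            cl = classify_psms(psms, proteome)
            profiles = incorporation_profiles(cl, design, EC_CONTROL)
            fracs[p] = np.array([pr.incorporation_fraction for pr in profiles])
        # stochastic dominance: the low-probability arm sits left
        grid = np.linspace(0, 1, 21)
        cdf_low = [(fracs[0.15] <= g).mean() for g in grid]
        cdf_high = [(fracs[0.3] <= g).mean() for g in grid]
        assert all(lo >= hi for lo, hi in zip(cdf_low, cdf_high))
        assert fracs[0.15].mean() < fracs[0.3].mean()


class TestParameterRecovery:
    def test_mean_absolute_error_below_two_points(self):
        """Across 20 simulated datasets at n=500 proteins the pipeline's
        labeled-proteome estimate tracks the generator probability to <2pp."""
        errors = []
        for seed in range(1, 21):
            p_true = 0.15 + 0.02 * (seed % 10)
            cfg = SyntheticConfig(
                n_proteins=500, seed=seed, groups=(EC_CONTROL,),
                protein_label_prob=p_true, endogenous_cleavage_prob=0.0,
            )
            proteome = generate_proteome(cfg)
            psms, design, _ = generate_psm_tables(cfg, proteome)
            cl = classify_psms(psms, proteome)
            pf = labeled_proteome_fraction(cl, design, EC_CONTROL)
            errors.append(abs(pf.fraction - p_true))
        assert float(np.mean(errors)) < 0.02
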