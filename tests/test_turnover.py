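import numpy as np

from silamdyn.classify import classify_psms
from silamdyn.digestion import digest
from silamdyn.simulate import SyntheticConfig, generate_proteome, generate_psm_tables
from silamdyn.turnover import map_cleavage_sites, score_turnover, turnover_matrix

from .conftest import psm

CTL = ("Control", "EC")
LPS = ("LPS", "EC")

# P1 = MAKRLSTKPEWIDNKAGER; "STKPE" (6-10) is semi-tryptic (N-term after L),
# "TKPEW" is non-tryptic, "LSTKPEWIDNK" and "AGER" fully tryptic.


class TestScoreTurnover:
    def test_semi_tryptic_counts_summed(self, two_group_design, tiny_proteome):
        psms = [
            psm("STKPE", "LPS_EC_a1", 2, ("P1",)),
            psm("STKPE", "LPS_EC_a2", 3, ("P1",)),
            psm("AGER", "LPS_EC_a1", 7, ("P1",)),
        ]
        cl = classify_psms(psms, tiny_proteome)
        scores = score_turnover(cl, two_group_design)
        s = scores[LPS]["P1"]
        assert s.nontryptic_sc == 5
        assert s.nontryptic_distinct == 1

    def test_fully_tryptic_only_scores_zero_not_omitted(
        self, two_group_design, tiny_proteome
    ):
        cl = classify_psms([psm("AGER", "Control_EC_a1", 3, ("P1",))], tiny_proteome)
        scores = score_turnover(cl, two_group_design)
        assert scores[CTL]["P1"].nontryptic_sc == 0

    def test_invariant_counted_peptides_absent_from_digest(self, tiny_proteome):
        cfg = SyntheticConfig(
            n_proteins=30, seed=3, groups=(CTL,), endogenous_cleavage_prob=0.3
        )
        proteome = generate_proteome(cfg)
        psms, design, _ = generate_psm_tables(cfg, proteome)
        cl = classify_psms(psms, proteome)
        digests = {
            p.accession: {d.sequence for d in digest(p.sequence, cfg.max_missed_cleavages)}
            for p in proteome
        }
        from silamdyn.digestion import is_nontryptic_evidence

        checked = 0
        for c in cl:
            if c.accession and is_nontryptic_evidence(c.specificity):
                assert c.psm.peptide not in digests[c.accession]
                checked += 1
        assert checked > 0

    def test_invariant_under_animal_relabeling(self, two_group_design, tiny_proteome):
        psms = [
            psm("STKPE", "Control_EC_a1", 2, ("P1",)),
            psm("STKPE", "Control_EC_a2", 3, ("P1",)),
        ]
        cl = classify_psms(psms, tiny_proteome)
        swapped = [
            psm("STKPE", "Control_EC_a2", 2, ("P1",)),
            psm("STKPE", "Control_EC_a1", 3, ("P1",)),
        ]
        cl2 = classify_psms(swapped, tiny_proteome)
        a = score_turnover(cl, two_group_design)[CTL]["P1"]
        b = score_turnover(cl2, two_group_design)[CTL]["P1"]
        assert a.nontryptic_sc == b.nontryptic_sc
        assert sorted(a.per_animal_sc) == sorted(b.per_animal_sc)


class TestTurnoverMatrix:
    def _scores(self, two_group_design, tiny_proteome, psms):
        cl = classify_psms(psms, tiny_proteome)
        return score_turnover(cl, two_group_design)

    def test_single_protein_two_groups(self, two_group_design, tiny_proteome):
        psms = [
            psm("STKPE", "LPS_EC_a1", 5, ("P1",)),
            psm("AGER", "Control_EC_a1", 2, ("P1",)),
        ]
        m = turnover_matrix(self._scores(two_group_design, tiny_proteome, psms))
        assert m.shape == (1, 2)
        assert m.loc["P1", "Control_EC"] == 0
        assert m.loc["P1", "LPS_EC"] == 5

    def test_permutation_invariance_and_column_sums(
        self, two_group_design, tiny_proteome
    ):
        psms = [
            psm("STKPE", "LPS_EC_a1", 5, ("P1",)),
            psm("TKPEW", "LPS_EC_a2", 1, ("P1",)),
            psm("TTTRPLLV", "Control_EC_a1", 2, ("P2",)),  # semi (C-term cut)
        ]
        scores = self._scores(two_group_design, tiny_proteome, psms)
        m1 = turnover_matrix(scores)
        m2 = turnover_matrix(
            self._scores(two_group_design, tiny_proteome, list(reversed(psms)))
        )
        assert m1.equals(m2)
        for (c, l), per_acc in scores.items():
            assert m1[f"{c}_{l}"].sum() == sum(s.nontryptic_sc for s in per_acc.values())

    def test_row_order_descending_total(self, two_group_design, tiny_proteome):
        psms = [
            psm("STKPE", "LPS_EC_a1", 2, ("P1",)),
            psm("TTTRPLLV", "LPS_EC_a1", 9, ("P2",)),
        ]
        m = turnover_matrix(self._scores(two_group_design, tiny_proteome, psms))
        assert list(m.index) == ["P2", "P1"]


class TestCleavageSites:
    def test_nontryptic_nterm_maps_to_preceding_residue(
        self, two_group_design, tiny_proteome
    ):
        # STKPE starts at protein position 6 -> cut after residue 5
        cl = classify_psms([psm("STKPE", "Control_EC_a1", 1, ("P1",))], tiny_proteome)
        df = map_cleavage_sites(cl, two_group_design)
        assert df.loc[0, ["accession", "position", "terminus"]].tolist() == ["P1", 5, "N"]

    def test_fully_tryptic_contributes_no_site(self, two_group_design, tiny_proteome):
        cl = classify_psms([psm("AGER", "Control_EC_a1", 1, ("P1",))], tiny_proteome)
        assert map_cleavage_sites(cl, two_group_design).empty

    def test_repeat_observations_aggregate(self, two_group_design, tiny_proteome):
        cl = classify_psms(
            [
                psm("STKPE", "Control_EC_a1", 1, ("P1",)),
                psm("STKPE", "Control_EC_a2", 1, ("P1",)),
            ],
            tiny_proteome,
        )
        df = map_cleavage_sites(cl, two_group_design)
        # STKPE spans 6-10: non-tryptic N (cut after 5) and C (cut after 10);
        # the two PSMs collapse onto the same sites with n_obs accumulated
        assert len(df) == 2
        assert df.n_obs.tolist() == [2, 2]
        assert set(zip(df.position, df.terminus)) == {(5, "N"), (10, "C")}

    def test_sites_within_protein_coordinates(self):
        cfg = SyntheticConfig(
            n_proteins=25, seed=8, groups=(CTL,), endogenous_cleavage_prob=0.3
        )
        proteome = generate_proteome(cfg)
        lengths = {p.accession: len(p.sequence) for p in proteome}
        psms, design, _ = generate_psm_tables(cfg, proteome)
        cl = classify_psms(psms, proteome)
        df = map_cleavage_sites(cl, design)
        assert len(df) > 0
        assert all(1 <= r.position <= lengths[r.accession] for r in df.itertuples())


class TestMonotonicity:
    def test_mean_score_increases_with_cleavage_rate(self):
        """Higher endogenous proteolysis must raise the mean turnover score
        (0.02 vs 0.2 arms, several seeds)."""
        means = {}
        for rate in (0.02, 0.2):
            vals = []
            for seed in range(1, 6):
                cfg = SyntheticConfig(
                    n_proteins=60, seed=seed, groups=(CTL,),
                    endogenous_cleavage_prob=rate,
                )
                proteome = generate_proteome(cfg)
                psms, design, _ = generate_psm_tables(cfg, proteome)
                cl = classify_psms(psms, proteome)
                scores = score_turnover(cl, design)[CTL]
                vals.append(np.mean([s.nontryptic_sc for s in scores.values()]))
            means[rate] = vals
        assert np.mean(means[0.2]) > np.mean(means[0.02])
        # arm-wise: every high-rate simulation beats every low-rate mean
        assert min(means[0.2]) > max(means[0.02])
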