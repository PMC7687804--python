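"""Parameter-recovery and operating-characteristic experiments.

Each function simulates data with the synthetic generator, runs the analysis
pipeline on it, and compares the estimate against the generator's ground
truth.  These are the package's self-validation experiments: recovery of
newly-synthesized proteome/peptidome fractions, the false-positive level of
regulation calls under a null, detection power under a global NSP
suppression, and monotonicity of the turnover score.
"""

from __future__ import annotations

import numpy as np

from .classify import classify_psms
from .dynamics import (
    CALL_DOWN,
    CALL_UNCHANGED,
    CALL_UP,
    aggregate_counts,
    regulation_table,
)
from .labeling import labeled_peptidome_fraction, labeled_proteome_fraction
from .simulate import SyntheticConfig, generate_proteome, generate_psm_tables
from .turnover import score_turnover


def _run_group(cfg: SyntheticConfig):
    proteome = generate_proteome(cfg)
    psms, design, truth = generate_psm_tables(cfg, proteome)
    return classify_psms(psms, proteome), design, truth, proteome


def proteome_fraction_recovery(
    label_prob: float,
    group: tuple[str, str],
    seeds: list[int],
    n_proteins: int = 500,
    n_animals: int = 3,
) -> dict:
    """Estimate the labeled-proteome fraction on datasets generated with a
    known per-protein labeling probability; returns per-seed estimates and
    their mean (as fractions)."""
    estimates = []
    for seed in seeds:
        cfg = SyntheticConfig(
            n_proteins=n_proteins,
            n_animals=n_animals,
            seed=seed,
            groups=(group,),
            protein_label_prob=label_prob,
            endogenous_cleavage_prob=0.0,
        )
        classified, design, _, _ = _run_group(cfg)
        estimates.append(
            labeled_proteome_fraction(classified, design, group).fraction
        )
    return {
        "true_value": label_prob,
        "estimates": estimates,
        "mean": float(np.mean(estimates)),
        "n_proteins": n_proteins,
        "n_seeds": len(seeds),
    }


def peptidome_fraction_recovery(
    label_prob: float,
    seeds: list[int],
    n_proteins: int = 70,
) -> dict:
    """Distinct-peptide labeled-fraction recovery in the marginal peptidome
    labeling mode (~2000 distinct peptides at the default 70 proteins)."""
    group = ("Control", "EC")
    estimates = []
    n_total = 0
    for seed in seeds:
        cfg = SyntheticConfig(
            n_proteins=n_proteins,
            seed=seed,
            groups=(group,),
            peptidome_label_prob=label_prob,
            endogenous_cleavage_prob=0.0,
        )
        classified, design, _, _ = _run_group(cfg)
        pf = labeled_peptidome_fraction(classified, design, group)
        estimates.append(pf.fraction)
        n_total = pf.n_total
    return {
        "true_value": label_prob,
        "estimates": estimates,
        "mean": float(np.mean(estimates)),
        "n_distinct_peptides": n_total,
        "n_seeds": len(seeds),
    }


def null_false_positive_rate(
    seeds: list[int], n_proteins: int = 300
) -> dict:
    """Fraction of testable proteins called up/down when both conditions are
    generated identically (type-I control at p<=0.05 and 1.5-fold)."""
    called = testable = 0
    per_seed = []
    for seed in seeds:
        cfg = SyntheticConfig.from_preset(
            "null",
            n_proteins=n_proteins,
            seed=seed,
            groups=(("Control", "EC"), ("LPS", "EC")),
            endogenous_cleavage_prob=0.0,
        )
        classified, design, _, _ = _run_group(cfg)
        counts = aggregate_counts(classified, design)
        res = regulation_table(counts, "EC")
        t = [r for r in res if r.call in (CALL_UP, CALL_DOWN, CALL_UNCHANGED)]
        c = [r for r in t if r.call in (CALL_UP, CALL_DOWN)]
        testable += len(t)
        called += len(c)
        per_seed.append(len(c) / len(t) if t else 0.0)
    return {
        "rate": called / testable if testable else 0.0,
        "per_seed": per_seed,
        "n_testable": testable,
    }


def suppression_power(
    seeds: list[int],
    n_proteins: int = 300,
    fold: float = 0.25,
    frac_modulated: float = 0.2,
    min_total_sc: int = 10,
) -> dict:
    """Down-call rate for truly modulated, synthesized, well-covered proteins
    under an LPS fold-change on labeled-peptide counts.

    The cohort is: generator-truth modulated AND in the Control NSP pool
    (an unsynthesized protein has no NSP signal to suppress) AND total
    spectral counts >= ``min_total_sc`` in each group.
    """
    hits = misses = 0
    for seed in seeds:
        cfg = SyntheticConfig(
            n_proteins=n_proteins,
            seed=seed,
            groups=(("Control", "EC"), ("LPS", "EC")),
            protein_label_prob=0.3,
            frac_modulated=frac_modulated,
            nsp_fold_change=fold,
            endogenous_cleavage_prob=0.0,
        )
        classified, design, truth, _ = _run_group(cfg)
        counts = aggregate_counts(classified, design)
        res = {r.accession: r for r in regulation_table(counts, "EC")}
        cohort = set(truth["modulated_proteins"]) & set(
            truth["groups"]["Control_EC"]["nsp_proteins"]
        )
        c_ctl = counts[("Control", "EC")]
        c_lps = counts[("LPS", "EC")]
        for acc in cohort:
            r = res.get(acc)
            cc, cl = c_ctl.get(acc), c_lps.get(acc)
            if r is None or cc is None or cl is None:
                continue
            if (
                cc.nsp_total + cc.nnsp_total < min_total_sc
                or cl.nsp_total + cl.nnsp_total < min_total_sc
            ):
                continue
            if r.call == CALL_DOWN:
                hits += 1
            else:
                misses += 1
    n = hits + misses
    return {"power": hits / n if n else 0.0, "n_cohort": n}


def turnover_monotonicity(
    seeds: list[int],
    low: float = 0.02,
    high: float = 0.2,
    n_proteins: int = 60,
) -> dict:
    """Mean non-tryptic turnover score per arm, matched by seed."""
    group = ("Control", "EC")

    def mean_score(rate: float, seed: int) -> float:
        cfg = SyntheticConfig(
            n_proteins=n_proteins,
            seed=seed,
            groups=(group,),
            endogenous_cleavage_prob=rate,
        )
        classified, design, _, _ = _run_group(cfg)
        scores = score_turnover(classified, design)[group]
        return float(np.mean([s.nontryptic_sc for s in scores.values()]))

    lows = [mean_score(low, s) for s in seeds]
    highs = [mean_score(high, s) for s in seeds]
    return {
        "low_rate": low,
        "high_rate": high,
        "mean_low": float(np.mean(lows)),
        "mean_high": float(np.mean(highs)),
        "per_seed_low": lows,
        "per_seed_high": highs,
        "all_pairs_increase": all(h > l for l, h in zip(lows, highs)),
    }
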