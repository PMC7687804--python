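"""Per-protein NSP / N-NSP quantification and LPS/Control regulation calls.

For every protein and (condition, layer) group, spectral counts of labeled
peptides (newly synthesized pool, NSP) and unlabeled peptides (pre-existing
pool, N-NSP) are summed per animal.  Condition ratios are computed on counts
pooled across animals; significance uses a two-sample pooled-variance
(Student's) t-test on the per-animal sums.  A protein is called regulated when
the NSP ratio passes the 1.5-fold threshold at p <= 0.05; a zero denominator
is categorical ("N.D."), yielding exclusive-synthesis calls rather than
infinite ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .digestion import is_nontryptic_evidence
from .io import SampleDesign

FOLD_THRESHOLD = 1.5
P_THRESHOLD = 0.05

CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"
CALL_EXCLUSIVE_LPS = "exclusive_LPS"
CALL_EXCLUSIVE_CONTROL = "exclusive_Control"
CALL_NOT_TESTABLE = "not_testable"


@dataclass(frozen=True)
class ProteinGroupCounts:
    """Per-animal spectral-count sums for one protein in one group."""

    accession: str
    group: tuple[str, str]
    animal_ids: tuple[str, ...]
    nsp_sc: tuple[int, ...]  # labeled peptides
    nnsp_sc: tuple[int, ...]  # unlabeled peptides
    nontryptic_sc: tuple[int, ...]  # >=1 non-tryptic terminus

    @property
    def nsp_total(self) -> int:
        return sum(self.nsp_sc)

    @property
    def nnsp_total(self) -> int:
        return sum(self.nnsp_sc)

    @property
    def n_animals_detected(self) -> int:
        return sum(1 for a, b in zip(self.nsp_sc, self.nnsp_sc) if a + b > 0)


def aggregate_counts(
    classified, design: list[SampleDesign]
) -> dict[tuple[str, str], dict[str, ProteinGroupCounts]]:
    """Aggregate classified PSMs into per-protein per-group count vectors.

    Returns {group: {accession: ProteinGroupCounts}}.  Only uniquely
    attributed peptides contribute (shared-peptide policy is applied during
    classification).  Animals without evidence are zero-filled so vector
    lengths always equal the group's animal count.
    """
    by_sample = {d.sample_id: d for d in design}
    animals: dict[tuple[str, str], list[str]] = {}
    for d in design:
        animals.setdefault(d.group, [])
        if d.animal_id not in animals[d.group]:
            animals[d.group].append(d.animal_id)

    # (group, accession, animal) -> [nsp, nnsp, nontryptic]
    acc: dict[tuple, list[int]] = {}
    for cp in classified:
        if cp.accession is None:
            continue
        d = by_sample.get(cp.psm.sample_id)
        if d is None:
            raise KeyError(f"sample_id {cp.psm.sample_id!r} not in design")
        key = (d.group, cp.accession, d.animal_id)
        cell = acc.setdefault(key, [0, 0, 0])
        if cp.label.labeled:
            cell[0] += cp.psm.spectral_count
        else:
            cell[1] += cp.psm.spectral_count
        if is_nontryptic_evidence(cp.specificity):
            cell[2] += cp.psm.spectral_count

    out: dict[tuple[str, str], dict[str, ProteinGroupCounts]] = {
        g: {} for g in animals
    }
    accessions: dict[tuple[str, str], set[str]] = {g: set() for g in animals}
    for (group, accession, _animal) in acc:
        accessions[group].add(accession)
    for group, accs in accessions.items():
        ids = tuple(animals[group])
        for accession in sorted(accs):
            cells = [acc.get((group, accession, a), [0, 0, 0]) for a in ids]
            out[group][accession] = ProteinGroupCounts(
                accession=accession,
                group=group,
                animal_ids=ids,
                nsp_sc=tuple(c[0] for c in cells),
                nnsp_sc=tuple(c[1] for c in cells),
                nontryptic_sc=tuple(c[2] for c in cells),
            )
    return out


def passes_consistency(counts: ProteinGroupCounts, min_animals: int = 2) -> bool:
    """Protein consistently identified in at least ``min_animals`` animals."""
    return counts.n_animals_detected >= min_animals


def test_protein(
    counts_a: tuple[int, ...] | list[int],
    counts_b: tuple[int, ...] | list[int],
    welch: bool = False,
) -> float | None:
    """Two-sample t-test on per-animal spectral-count sums.

    Pooled-variance (Student's) by default; ``welch=True`` for unequal
    variances.  Returns None (not testable) with fewer than 2 animals per
    group.  Degenerate zero-variance inputs: p = 1.0 for identical means,
    0.0 for perfectly separated ones.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return None
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    import warnings

    with warnings.catch_warnings():
        # scipy warns on near-identical samples; the p-value is still exact
        # enough for count data and the degenerate cases are handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    if math.isnan(p):
        return None
    return p


@dataclass(frozen=True)
class RegulationResult:
    accession: str
    layer: str
    nsp_ratio: float | None  # LPS/Control; None == N.D. (categorical)
    nnsp_ratio: float | None
    p_value_nsp: float | None
    p_value_nnsp: float | None
    call: str
    nsp_lps: int = 0
    nsp_control: int = 0
    nnsp_lps: int = 0
    nnsp_control: int = 0


def _ratio(lps_total: int, control_total: int) -> float | None:
    if control_total == 0:
        return None
    return lps_total / control_total


def compute_ratios(
    counts_lps: ProteinGroupCounts | None,
    counts_control: ProteinGroupCounts | None,
    min_animals: int = 2,
    welch: bool = False,
) -> RegulationResult:
    """LPS/Control NSP and N-NSP ratios plus the regulation call for one protein.

    Ratios divide counts pooled (summed) across animals.  A zero Control NSP
    total with LPS evidence yields ``exclusive_LPS`` (and symmetrically
    ``exclusive_Control``); both pools empty yields ``not_testable``.  The
    up/down call requires the NSP ratio beyond 1.5-fold AND p <= 0.05 from the
    per-animal t-test.
    """
    some = counts_lps or counts_control
    if some is None:
        raise ValueError("protein absent from both groups")
    accession = some.accession
    layer = some.group[1]
    zeros = lambda c: (0,) * (len(c.animal_ids) if c else 0)  # noqa: E731
    nsp_l = counts_lps.nsp_sc if counts_lps else zeros(counts_control)
    nsp_c = counts_control.nsp_sc if counts_control else zeros(counts_lps)
    nnsp_l = counts_lps.nnsp_sc if counts_lps else zeros(counts_control)
    nnsp_c = counts_control.nnsp_sc if counts_control else zeros(counts_lps)

    nsp_lt, nsp_ct = sum(nsp_l), sum(nsp_c)
    nnsp_lt, nnsp_ct = sum(nnsp_l), sum(nnsp_c)

    p_nsp = test_protein(nsp_l, nsp_c, welch=welch) if nsp_l and nsp_c else None
    p_nnsp = test_protein(nnsp_l, nnsp_c, welch=welch) if nnsp_l and nnsp_c else None

    nsp_ratio = _ratio(nsp_lt, nsp_ct)
    nnsp_ratio = _ratio(nnsp_lt, nnsp_ct)

    if nsp_ct == 0 and nsp_lt > 0:
        call = CALL_EXCLUSIVE_LPS
    elif nsp_lt == 0 and nsp_ct > 0:
        call = CALL_EXCLUSIVE_CONTROL
    elif nsp_lt == 0 and nsp_ct == 0:
        call = CALL_NOT_TESTABLE
    elif p_nsp is None:
        call = CALL_NOT_TESTABLE
    elif nsp_ratio >= FOLD_THRESHOLD and p_nsp <= P_THRESHOLD:
        call = CALL_UP
    elif nsp_ratio <= 1.0 / FOLD_THRESHOLD and p_nsp <= P_THRESHOLD:
        call = CALL_DOWN
    else:
        call = CALL_UNCHANGED

    return RegulationResult(
        accession=accession,
        layer=layer,
        nsp_ratio=nsp_ratio if nsp_ct > 0 else None,
        nnsp_ratio=nnsp_ratio,
        p_value_nsp=p_nsp,
        p_value_nnsp=p_nnsp,
        call=call,
        nsp_lps=nsp_lt,
        nsp_control=nsp_ct,
        nnsp_lps=nnsp_lt,
        nnsp_control=nnsp_ct,
    )


def regulation_table(
    grouped_counts: dict[tuple[str, str], dict[str, ProteinGroupCounts]],
    layer: str,
    min_animals: int = 2,
    welch: bool = False,
) -> list[RegulationResult]:
    """All per-protein LPS-vs-Control results for one layer.

    A protein enters if it passes the >= ``min_animals`` consistency filter in
    at least one of the two groups.
    """
    lps = grouped_counts.get(("LPS", layer), {})
    control = grouped_counts.get(("Control", layer), {})
    results = []
    for accession in sorted(set(lps) | set(control)):
        cl, cc = lps.get(accession), control.get(accession)
        ok = (cl is not None and passes_consistency(cl, min_animals)) or (
            cc is not None and passes_consistency(cc, min_animals)
        )
        if not ok:
            continue
        results.append(compute_ratios(cl, cc, min_animals=min_animals, welch=welch))
    return results


def call_regulation(results: list[RegulationResult]) -> pd.DataFrame:
    """Filter to regulated proteins (up/down at threshold, plus exclusives)."""
    rows = [
        r
        for r in results
        if r.call in (CALL_UP, CALL_DOWN, CALL_EXCLUSIVE_LPS, CALL_EXCLUSIVE_CONTROL)
    ]
    return results_to_frame(rows)


def results_to_frame(results: list[RegulationResult]) -> pd.DataFrame:
    def fmt_ratio(x):
        return "N.D." if x is None else x

    return pd.DataFrame(
        [
            (
                r.accession,
                r.layer,
                fmt_ratio(r.nsp_ratio),
                fmt_ratio(r.nnsp_ratio),
                r.p_value_nsp if r.p_value_nsp is not None else "",
                r.p_value_nnsp if r.p_value_nnsp is not None else "",
                r.call,
                r.nsp_lps,
                r.nsp_control,
                r.nnsp_lps,
                r.nnsp_control,
            )
            for r in results
        ],
        columns=[
            "accession",
            "layer",
            "nsp_ratio",
            "nnsp_ratio",
            "p_value_nsp",
            "p_value_nnsp",
            "call",
            "nsp_lps",
            "nsp_control",
            "nnsp_lps",
            "nnsp_control",
        ],
    )


def anova_bonferroni(groups: dict[str, list[float]]) -> dict:
    """One-way ANOVA across >2 groups with Bonferroni-corrected pairwise t-tests.

    Used for group-level comparisons (e.g. layer-wise site counts); per-protein
    two-group tests stay uncorrected.
    """
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f, p = stats.f_oneway(*arrays)
    pairs = {}
    m = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pp = test_protein(arrays[i], arrays[j])
            pairs[f"{names[i]}_vs_{names[j]}"] = (
                min(1.0, pp * m) if pp is not None else None
            )
    return {"anova_F": float(f), "anova_p": float(p), "pairwise_bonferroni": pairs}
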