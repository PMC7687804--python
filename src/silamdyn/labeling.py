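"""Lys(6) label calls and incorporation metrics.

A peptide carrying at least one heavy-lysine (K6, +6.0201 Da) modification
comes from a protein molecule synthesized during the labeling window; the
fraction of labeled proteins/peptides per vascular layer therefore measures
the newly synthesized share of each proteome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MOD_VOCAB, FormatError, PsmRecord, SampleDesign

K6_NAME = "label-K6"
K6_MASS = MOD_VOCAB[K6_NAME][0]  # 6.0201 Da


@dataclass(frozen=True)
class LabelCall:
    labeled: bool
    n_labeled_lysines: int
    n_lysines: int
    mass_shift: float


def call_label(psm: PsmRecord) -> LabelCall:
    """Count K6 modifications on a PSM.

    mass_shift = 6.0201 x number of labeled lysines.  A K6 on a non-lysine
    residue is a validation error (it cannot arise from the modification
    vocabulary, but hand-built records are checked too).
    """
    n_labeled = 0
    for mod in psm.modifications:
        if mod.name == K6_NAME:
            if mod.residue != "K":
                raise FormatError(
                    f"{K6_NAME} on residue {mod.residue} in {psm.peptide!r}"
                )
            n_labeled += 1
    return LabelCall(
        labeled=n_labeled >= 1,
        n_labeled_lysines=n_labeled,
        n_lysines=psm.peptide.count("K"),
        mass_shift=round(K6_MASS * n_labeled, 4),
    )


# ---------------------------------------------------------------------------
# Proteome / peptidome fractions


def _group_samples(
    design: list[SampleDesign], group: tuple[str, str]
) -> dict[str, SampleDesign]:
    rows = {d.sample_id: d for d in design if d.group == group}
    if not rows:
        raise ValueError(f"no samples for group {group}")
    return rows


@dataclass(frozen=True)
class ProteomeFraction:
    """Labeled-proteome fraction for one condition x layer group."""

    group: tuple[str, str]
    n_labeled: int  # proteins with labeled evidence in >= min_animals animals
    n_detected: int  # proteins with any evidence in the group
    fraction: float
    per_animal: dict[str, float]  # animal_id -> labeled/detected within animal
    mean: float  # across-animal mean of per-animal fractions
    sd: float


def labeled_proteome_fraction(
    classified,
    design: list[SampleDesign],
    group: tuple[str, str],
    min_animals: int = 2,
) -> ProteomeFraction:
    """Fraction of detected proteins that are newly synthesized in a group.

    A protein is *detected* if it has >= 1 attributed peptide in the group and
    *labeled* if it has >= 1 labeled peptide in at least ``min_animals``
    animals (the consistency rule).  Per-animal fractions (labeled/detected
    within each animal) and their mean ± SD are reported alongside.
    """
    samples = _group_samples(design, group)
    detected: set[str] = set()
    labeled_by_animal: dict[str, set[str]] = {}
    detected_by_animal: dict[str, set[str]] = {}
    for cp in classified:
        d = samples.get(cp.psm.sample_id)
        if d is None or cp.accession is None:
            continue
        detected.add(cp.accession)
        detected_by_animal.setdefault(d.animal_id, set()).add(cp.accession)
        if cp.label.labeled:
            labeled_by_animal.setdefault(d.animal_id, set()).add(cp.accession)
    if not detected:
        raise ValueError(f"group {group} has no attributed peptides")
    animal_count: dict[str, int] = {}
    for accs in labeled_by_animal.values():
        for acc in accs:
            animal_count[acc] = animal_count.get(acc, 0) + 1
    labeled = {acc for acc, n in animal_count.items() if n >= min_animals}
    per_animal = {
        aid: len(labeled_by_animal.get(aid, set())) / len(dets)
        for aid, dets in sorted(detected_by_animal.items())
        if dets
    }
    vals = np.array(list(per_animal.values()), dtype=float)
    return ProteomeFraction(
        group=group,
        n_labeled=len(labeled),
        n_detected=len(detected),
        fraction=len(labeled) / len(detected),
        per_animal=per_animal,
        mean=float(vals.mean()) if vals.size else 0.0,
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
    )


@dataclass(frozen=True)
class PeptidomeFraction:
    group: tuple[str, str]
    n_labeled: int
    n_total: int
    fraction: float  # distinct-peptide estimator
    fraction_sc_weighted: float


def labeled_peptidome_fraction(
    classified,
    design: list[SampleDesign],
    group: tuple[str, str],
    include_lysine_free: bool = True,
) -> PeptidomeFraction:
    """Fraction of the distinct peptidome carrying Lys(6) in a group.

    Peptides without lysine can never be labeled but are included in the
    denominator by default ("all analyzed peptidomes"); pass
    ``include_lysine_free=False`` to restrict to labelable peptides.
    Shared and unmapped peptides count: this is a peptidome-level measure.
    """
    samples = _group_samples(design, group)
    labeled: set[str] = set()
    total: set[str] = set()
    sc_labeled = 0
    sc_total = 0
    for cp in classified:
        if cp.psm.sample_id not in samples:
            continue
        if not include_lysine_free and cp.label.n_lysines == 0:
            continue
        total.add(cp.psm.peptide)
        sc_total += cp.psm.spectral_count
        if cp.label.labeled:
            labeled.add(cp.psm.peptide)
            sc_labeled += cp.psm.spectral_count
    if not total:
        raise ValueError(f"group {group} has no peptides")
    return PeptidomeFraction(
        group=group,
        n_labeled=len(labeled),
        n_total=len(total),
        fraction=len(labeled) / len(total),
        fraction_sc_weighted=sc_labeled / sc_total if sc_total else 0.0,
    )


# ---------------------------------------------------------------------------
# Per-protein incorporation


@dataclass(frozen=True)
class IncorporationProfile:
    accession: str
    group: tuple[str, str]
    labeled_sc: int
    total_sc: int
    incorporation_fraction: float  # spectral-count weighted
    labeled_peptides: int
    total_peptides: int
    incorporation_fraction_peptides: float  # distinct-peptide weighted


def incorporation_profiles(
    classified,
    design: list[SampleDesign],
    group: tuple[str, str],
) -> list[IncorporationProfile]:
    """Per-protein Lys(6) incorporation in one group.

    The headline fraction is spectral-count weighted (labeled_sc/total_sc);
    the distinct-peptide-weighted variant is emitted alongside.
    """
    samples = _group_samples(design, group)
    acc_data: dict[str, dict] = {}
    for cp in classified:
        if cp.psm.sample_id not in samples or cp.accession is None:
            continue
        d = acc_data.setdefault(
            cp.accession, {"lsc": 0, "tsc": 0, "lpep": set(), "tpep": set()}
        )
        d["tsc"] += cp.psm.spectral_count
        d["tpep"].add(cp.psm.peptide)
        if cp.label.labeled:
            d["lsc"] += cp.psm.spectral_count
            d["lpep"].add(cp.psm.peptide)
    profiles = []
    for acc in sorted(acc_data):
        d = acc_data[acc]
        profiles.append(
            IncorporationProfile(
                accession=acc,
                group=group,
                labeled_sc=d["lsc"],
                total_sc=d["tsc"],
                incorporation_fraction=d["lsc"] / d["tsc"] if d["tsc"] else 0.0,
                labeled_peptides=len(d["lpep"]),
                total_peptides=len(d["tpep"]),
                incorporation_fraction_peptides=(
                    len(d["lpep"]) / len(d["tpep"]) if d["tpep"] else 0.0
                ),
            )
        )
    return profiles


def incorporation_distribution(
    profiles: list[IncorporationProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative frequency curve of per-protein incorporation fractions.

    Returns (sorted fractions, cumulative proportion), a monotone
    non-decreasing step curve on [0, 1].
    """
    if not profiles:
        raise ValueError("no incorporation profiles")
    fractions = np.sort(np.array([p.incorporation_fraction for p in profiles]))
    cumulative = np.arange(1, len(fractions) + 1) / len(fractions)
    return fractions, cumulative


def ks_distance(
    profiles_a: list[IncorporationProfile],
    profiles_b: list[IncorporationProfile],
) -> float:
    """Two-sample Kolmogorov-Smirnov distance between incorporation curves."""
    from scipy import stats

    a = [p.incorporation_fraction for p in profiles_a]
    b = [p.incorporation_fraction for p in profiles_b]
    return float(stats.ks_2samp(a, b).statistic)
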