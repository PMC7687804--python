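"""Protein turnover scored from non-tryptic peptide evidence.

In a trypsin-digested sample every expected peptide terminus sits at a
trypsin cleavage site; a terminus that does not marks an endogenous
proteolytic event.  Spectral counts of peptides with at least one such
terminus are the turnover readout, aggregated per protein per group into a
proteins x groups matrix, and the non-tryptic termini are mapped back onto
protein coordinates as candidate endogenous cleavage sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .digestion import FULLY_TRYPTIC, UNMAPPED, is_nontryptic_evidence
from .io import SampleDesign


@dataclass(frozen=True)
class CleavageSite:
    """An inferred endogenous cleavage: scission after ``position``.

    ``terminus`` records which peptide terminus produced the evidence
    (N: the peptide starts right after the cut; C: the peptide ends at it).
    """

    accession: str
    position: int  # cut is between position and position+1 (1-based)
    terminus: str  # "N" or "C"


@dataclass(frozen=True)
class TurnoverScore:
    accession: str
    group: tuple[str, str]
    nontryptic_sc: int
    nontryptic_distinct: int
    cleavage_sites: tuple[CleavageSite, ...]
    per_animal_sc: tuple[int, ...]
    animal_ids: tuple[str, ...]


def _sites_for(cp) -> list[CleavageSite]:
    call = cp.specificity
    if call.specificity in (FULLY_TRYPTIC, UNMAPPED) or cp.accession is None:
        return []
    sites = []
    if not call.n_term_tryptic and call.start > 1:
        sites.append(CleavageSite(cp.accession, call.start - 1, "N"))
    if not call.c_term_tryptic:
        sites.append(CleavageSite(cp.accession, call.end, "C"))
    return sites


def score_turnover(
    classified, design: list[SampleDesign]
) -> dict[tuple[str, str], dict[str, TurnoverScore]]:
    """Per-protein per-group turnover scores.

    Counts spectral counts and distinct peptides with >= 1 non-tryptic
    terminus.  Proteins detected in a group but with zero such evidence are
    reported with score 0 (never omitted).
    """
    by_sample = {d.sample_id: d for d in design}
    animals: dict[tuple[str, str], list[str]] = {}
    for d in design:
        animals.setdefault(d.group, [])
        if d.animal_id not in animals[d.group]:
            animals[d.group].append(d.animal_id)

    data: dict[tuple, dict] = {}
    detected: dict[tuple[str, str], set[str]] = {g: set() for g in animals}
    for cp in classified:
        if cp.accession is None:
            continue
        d = by_sample.get(cp.psm.sample_id)
        if d is None:
            continue
        detected[d.group].add(cp.accession)
        if not is_nontryptic_evidence(cp.specificity):
            continue
        cell = data.setdefault(
            (d.group, cp.accession),
            {"peptides": set(), "sites": [], "per_animal": {}},
        )
        cell["peptides"].add(cp.psm.peptide)
        cell["sites"].extend(_sites_for(cp))
        cell["per_animal"][d.animal_id] = (
            cell["per_animal"].get(d.animal_id, 0) + cp.psm.spectral_count
        )

    out: dict[tuple[str, str], dict[str, TurnoverScore]] = {g: {} for g in animals}
    for group, accs in detected.items():
        ids = tuple(animals[group])
        for accession in sorted(accs):
            cell = data.get((group, accession), {"peptides": set(), "sites": [], "per_animal": {}})
            per_animal = tuple(cell["per_animal"].get(a, 0) for a in ids)
            out[group][accession] = TurnoverScore(
                accession=accession,
                group=group,
                nontryptic_sc=sum(per_animal),
                nontryptic_distinct=len(cell["peptides"]),
                cleavage_sites=tuple(cell["sites"]),
                per_animal_sc=per_animal,
                animal_ids=ids,
            )
    return out


def turnover_matrix(
    scores: dict[tuple[str, str], dict[str, TurnoverScore]]
) -> pd.DataFrame:
    """Proteins x groups matrix of non-tryptic spectral counts.

    Rows: proteins with nonzero evidence in >= 1 group, ordered by descending
    total then accession.  Values are raw spectral counts (no normalization).
    """
    groups = sorted(scores)
    cols = {f"{c}_{l}": {} for (c, l) in groups}
    for (c, l), per_acc in scores.items():
        for accession, s in per_acc.items():
            cols[f"{c}_{l}"][accession] = s.nontryptic_sc
    df = pd.DataFrame(cols).fillna(0).astype(int)
    df = df[[f"{c}_{l}" for (c, l) in groups]]
    df = df[df.sum(axis=1) > 0]
    df = df.loc[
        sorted(df.index, key=lambda a: (-df.loc[a].sum(), a))
    ]
    df.index.name = "accession"
    return df


def map_cleavage_sites(classified, design: list[SampleDesign]) -> pd.DataFrame:
    """Aggregate inferred endogenous cleavage sites with observation counts.

    Each non-tryptic terminus marks a scission: a peptide starting at protein
    position p with a non-tryptic N terminus implies a cut after residue p-1;
    a non-tryptic C terminus at position q implies a cut after q.  One row per
    (protein, cut position, terminus side, group); ``n_obs`` counts
    contributing PSMs, so repeat observations of the same peptide accumulate.
    """
    by_sample = {d.sample_id: d for d in design}
    rows: dict[tuple, int] = {}
    for cp in classified:
        d = by_sample.get(cp.psm.sample_id)
        if d is None:
            continue
        for site in _sites_for(cp):
            key = (site.accession, site.position, site.terminus, *d.group)
            rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [(a, p, t, c, l, n) for (a, p, t, c, l), n in sorted(rows.items())],
        columns=["accession", "position", "terminus", "condition", "layer", "n_obs"],
    )
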