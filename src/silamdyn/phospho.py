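"""Phosphosite aggregation and disease-specific site calls.

Peptide-level phospho modifications are translated to protein coordinates,
filtered on localization confidence (Ascore >= 1000 by default, the search
engine's maximal value), merged across observations, and classified as
disease-specific when a site is seen only under LPS within a layer — the
readout for sepsis-induced signaling on the endothelium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .digestion import UNMAPPED
from .io import FormatError, ProteinRecord, SampleDesign

PHOSPHO_NAME = "phospho"
DEFAULT_MIN_SCORE = 1000.0
PHOSPHO_RESIDUES = set("STY")


@dataclass
class PhosphoSite:
    """A localized phosphosite on a protein.

    Keyed by (accession, position, residue); ``groups_detected`` collects the
    (condition, layer) groups with >= 1 observation, ``samples_detected`` the
    sample ids.  ``disease_specific`` means detected under LPS and never in a
    Control sample of the same layer; ``control_specific`` is the mirror.
    """

    accession: str
    residue: str
    position: int  # 1-based protein coordinate
    localization_score: float
    groups_detected: set = field(default_factory=set)
    samples_detected: set = field(default_factory=set)
    n_obs: int = 0
    disease_specific: bool = False
    control_specific: bool = False

    @property
    def site_label(self) -> str:
        return f"{self.residue}{self.position}"


def collect_sites(
    classified,
    proteins: list[ProteinRecord],
    design: list[SampleDesign],
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[PhosphoSite]:
    """Aggregate phosphosites from classified PSMs.

    Peptide positions are translated to protein coordinates via the
    specificity call's mapping; observations below ``min_score`` are
    discarded; duplicates merge keeping the maximal score.  Shared peptides
    resolve to their first-listed accession.  A phospho on a residue other
    than S/T/Y is a validation error.
    """
    seqs = {p.accession: p.sequence for p in proteins}
    by_sample = {d.sample_id: d for d in design}
    sites: dict[tuple[str, int, str], PhosphoSite] = {}
    for cp in classified:
        phos = [m for m in cp.psm.modifications if m.name == PHOSPHO_NAME]
        if not phos:
            continue
        accession = cp.accession
        if accession is None:
            # shared peptide: fall back to the first listed known accession
            known = [a for a in cp.psm.protein_accessions if a in seqs]
            if not known:
                continue
            accession = known[0]
        if cp.specificity.specificity == UNMAPPED or cp.specificity.start == 0:
            continue
        d = by_sample.get(cp.psm.sample_id)
        if d is None:
            continue
        for mod in phos:
            if mod.residue not in PHOSPHO_RESIDUES:
                raise FormatError(
                    f"phospho on residue {mod.residue} in {cp.psm.peptide!r}"
                )
            score = mod.localization_score
            if score is None or score < min_score:
                continue
            pos = cp.specificity.start + mod.position - 1
            if seqs[accession][pos - 1] != mod.residue:
                raise FormatError(
                    f"site {mod.residue}{pos} does not match protein "
                    f"{accession} sequence"
                )
            key = (accession, pos, mod.residue)
            site = sites.get(key)
            if site is None:
                site = PhosphoSite(accession, mod.residue, pos, score)
                sites[key] = site
            site.localization_score = max(site.localization_score, score)
            site.groups_detected.add(d.group)
            site.samples_detected.add(d.sample_id)
            site.n_obs += cp.psm.spectral_count
    out = [sites[k] for k in sorted(sites)]
    _flag_specific(out)
    return out


def _flag_specific(sites: list[PhosphoSite]) -> None:
    """Set disease/control specificity per layer (mutually exclusive).

    A site is disease-specific when some layer has LPS observations and no
    Control observation in that same layer; cross-layer evidence does not
    veto.  Control-specific is the symmetric flag.
    """
    for s in sites:
        lps_layers = {l for (c, l) in s.groups_detected if c == "LPS"}
        control_layers = {l for (c, l) in s.groups_detected if c == "Control"}
        lps_only = lps_layers - control_layers
        control_only = control_layers - lps_layers
        disjoint = lps_layers.isdisjoint(control_layers)
        # Conservative on cross-layer splits: any Control evidence in a layer
        # shared with (or opposing) the LPS evidence blocks the call, so the
        # two flags can never both be true.
        s.disease_specific = bool(lps_only) and not control_only and disjoint
        s.control_specific = bool(control_only) and not lps_only and disjoint


def count_sites_per_group(
    sites: list[PhosphoSite], design: list[SampleDesign]
) -> pd.DataFrame:
    """Distinct-site counts per animal and group, with the group comparison.

    Returns a tidy frame (condition, layer, animal_id, n_sites).  Use
    :func:`compare_site_counts` for the LPS-vs-Control t-test per layer.
    """
    by_sample = {d.sample_id: d for d in design}
    per_animal: dict[tuple[str, str, str], set] = {
        (d.condition, d.layer, d.animal_id): set() for d in design
    }
    for s in sites:
        for sid in s.samples_detected:
            d = by_sample[sid]
            per_animal[(d.condition, d.layer, d.animal_id)].add(
                (s.accession, s.position, s.residue)
            )
    rows = [
        (c, l, a, len(v)) for (c, l, a), v in sorted(per_animal.items())
    ]
    return pd.DataFrame(rows, columns=["condition", "layer", "animal_id", "n_sites"])


def compare_site_counts(counts: pd.DataFrame, layer: str) -> dict:
    """Student's t-test on per-animal site counts, LPS vs Control, one layer."""
    from .dynamics import test_protein

    sub = counts[counts.layer == layer]
    lps = sub[sub.condition == "LPS"].n_sites.tolist()
    control = sub[sub.condition == "Control"].n_sites.tolist()
    return {
        "layer": layer,
        "mean_lps": float(pd.Series(lps).mean()) if lps else 0.0,
        "mean_control": float(pd.Series(control).mean()) if control else 0.0,
        "p_value": test_protein(lps, control),
    }


def call_disease_specific(
    sites: list[PhosphoSite],
    gene_map: dict[str, str] | None = None,
    annotation_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Disease-specific site table (gene, protein, modified residues).

    ``gene_map``/``annotation_map`` are optional user-supplied accession ->
    gene symbol / annotation lookups; accession is used when absent.  Sites
    on the same protein are collapsed into one comma-separated residue list.
    """
    gene_map = gene_map or {}
    annotation_map = annotation_map or {}
    by_protein: dict[str, list[PhosphoSite]] = {}
    for s in sites:
        if s.disease_specific:
            by_protein.setdefault(s.accession, []).append(s)
    rows = []
    for accession in sorted(by_protein):
        ss = sorted(by_protein[accession], key=lambda s: s.position)
        rows.append(
            (
                gene_map.get(accession, accession),
                accession,
                ", ".join(s.site_label for s in ss),
                annotation_map.get(accession, ""),
            )
        )
    return pd.DataFrame(
        rows, columns=["gene", "accession", "modified_residues", "annotation"]
    )


def sites_to_frame(sites: list[PhosphoSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.accession,
                s.site_label,
                s.residue,
                s.position,
                s.localization_score,
                ";".join(sorted(f"{c}_{l}" for (c, l) in s.groups_detected)),
                s.n_obs,
                s.disease_specific,
                s.control_specific,
            )
            for s in sites
        ],
        columns=[
            "accession",
            "site",
            "residue",
            "position",
            "localization_score",
            "groups",
            "n_obs",
            "disease_specific",
            "control_specific",
        ],
    )
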