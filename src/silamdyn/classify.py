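"""Join PSMs against the protein database: label status + terminal specificity.

This is the bridge between raw PSM tables and the quantitative modules.  Each
PSM is resolved to a protein (unique-peptides-only by default: peptides whose
accession list, after dropping accessions absent from the FASTA, names more
than one protein are kept but flagged shared and excluded from per-protein
aggregation), classified for Lys(6) labeling and for terminal specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .digestion import SpecificityCall, UNMAPPED, classify_specificity
from .io import ProteinRecord, PsmRecord, SampleDesign
from .labeling import LabelCall, call_label

SHARED_POLICY_UNIQUE = "unique_only"
SHARED_POLICY_ALL = "all_mapped"


@dataclass(frozen=True)
class ClassifiedPeptide:
    """A PSM enriched with label and specificity calls.

    ``accession`` is the single protein the PSM is attributed to, or ``None``
    for shared peptides under the unique-only policy (they still appear in
    peptidome-level tallies).
    """

    psm: PsmRecord
    label: LabelCall
    specificity: SpecificityCall
    accession: str | None
    shared: bool


def classify_psms(
    psms: list[PsmRecord],
    proteins: list[ProteinRecord],
    shared_policy: str = SHARED_POLICY_UNIQUE,
) -> list[ClassifiedPeptide]:
    """Classify every PSM for labeling and terminal specificity.

    Under ``all_mapped`` a shared peptide is duplicated, once per mapped
    accession.  Unknown accessions are ignored; a PSM mapping to no known
    protein gets specificity ``unmapped`` and no attribution.
    """
    if shared_policy not in (SHARED_POLICY_UNIQUE, SHARED_POLICY_ALL):
        raise ValueError(f"unknown shared-peptide policy {shared_policy!r}")
    seqs = {p.accession: p.sequence for p in proteins}

    @lru_cache(maxsize=None)
    def spec_call(peptide: str, accession: str) -> SpecificityCall:
        return classify_specificity(peptide, seqs[accession])

    out: list[ClassifiedPeptide] = []
    for psm in psms:
        label = call_label(psm)
        mapped = [a for a in psm.protein_accessions if a in seqs]
        # prefer an accession where the peptide actually occurs
        calls = {a: spec_call(psm.peptide, a) for a in mapped}
        hit_accs = [a for a in mapped if calls[a].specificity != UNMAPPED]
        targets = hit_accs or mapped
        if not targets:
            out.append(
                ClassifiedPeptide(psm, label, classify_specificity(psm.peptide, ""), None, False)
            )
            continue
        shared = len(targets) > 1
        if shared and shared_policy == SHARED_POLICY_UNIQUE:
            # keep the call (for peptidome-level stats) but attribute to no protein
            out.append(ClassifiedPeptide(psm, label, calls[targets[0]], None, True))
        else:
            for acc in targets if shared else targets[:1]:
                out.append(ClassifiedPeptide(psm, label, calls[acc], acc, shared))
    return out


def index_by_sample(
    design: list[SampleDesign],
) -> dict[str, SampleDesign]:
    return {d.sample_id: d for d in design}
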