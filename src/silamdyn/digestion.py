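"""In-silico trypsin digestion and peptide terminal-specificity calls.

Trypsin cleaves C-terminal to K or R unless the next residue is P
(sequencing-grade rule).  A peptide observed in a trypsin-digested sample
whose termini do not both sit at cleavage sites (or protein termini) is
evidence of endogenous proteolysis and feeds the turnover analysis.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

FULLY_TRYPTIC = "fully_tryptic"
SEMI_TRYPTIC = "semi_tryptic"
NON_TRYPTIC = "non_tryptic"
UNMAPPED = "unmapped"


def cleavage_sites(sequence: str) -> list[int]:
    """1-based positions i such that trypsin cleaves between i and i+1."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    start: int  # 1-based in protein
    end: int  # 1-based inclusive
    missed_cleavages: int


def digest(sequence: str, max_missed_cleavages: int = 0) -> list[DigestPeptide]:
    """Tryptic peptides of ``sequence`` with 0..max missed cleavages.

    Ordered by start position, then length.  Empty sequence yields [].
    """
    if not sequence:
        return []
    sites = cleavage_sites(sequence)
    bounds = [0] + sites + [len(sequence)]  # fragment boundaries (0-based end-exclusive)
    peptides: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for mc in range(max_missed_cleavages + 1):
            j = i + 1 + mc
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            peptides.append(DigestPeptide(sequence[start:end], start + 1, end, mc))
    peptides.sort(key=lambda p: (p.start, p.end - p.start))
    return peptides


@dataclass(frozen=True)
class SpecificityCall:
    """Terminal specificity of an observed peptide against one protein.

    ``multi_mapped`` is set when the peptide occurs at more than one position
    in the protein; the reported call is then the occurrence maximizing
    specificity (fully > semi > non).
    """

    specificity: str
    n_term_tryptic: bool
    c_term_tryptic: bool
    missed_cleavages: int
    start: int
    end: int
    multi_mapped: bool = False


_RANK = {FULLY_TRYPTIC: 2, SEMI_TRYPTIC: 1, NON_TRYPTIC: 0}

_UNMAPPED_CALL = SpecificityCall(UNMAPPED, False, False, 0, 0, 0)


def _call_at(peptide: str, protein: str, start0: int) -> SpecificityCall:
    """Specificity call for peptide occurring at 0-based offset start0."""
    end0 = start0 + len(peptide)  # exclusive
    # N terminus: protein start, after a K/R (not before P), or Met-excision
    # allowance (peptide starting at position 2 of a Met-initiated protein).
    n_ok = (
        start0 == 0
        or (protein[start0 - 1] in "KR" and peptide[0] != "P")
        or (start0 == 1 and protein[0] == "M")
    )
    # C terminus: protein end or K/R not followed by P.
    c_ok = end0 == len(protein) or (
        peptide[-1] in "KR" and protein[end0] != "P"
    )
    mc = sum(
        1
        for i in range(len(peptide) - 1)
        if peptide[i] in "KR" and peptide[i + 1] != "P"
    )
    spec = (
        FULLY_TRYPTIC if (n_ok and c_ok) else SEMI_TRYPTIC if (n_ok or c_ok) else NON_TRYPTIC
    )
    return SpecificityCall(spec, n_ok, c_ok, mc, start0 + 1, end0)


def classify_specificity(peptide: str, protein_sequence: str) -> SpecificityCall:
    """Classify a peptide's termini against its parent protein.

    Returns a call with ``specificity="unmapped"`` when the peptide is not a
    substring of the protein.  For multiply occurring peptides the most
    specific occurrence wins (tie: leftmost) and ``multi_mapped`` is set.
    """
    if not peptide:
        return _UNMAPPED_CALL
    hits: list[SpecificityCall] = []
    pos = protein_sequence.find(peptide)
    while pos >= 0:
        hits.append(_call_at(peptide, protein_sequence, pos))
        pos = protein_sequence.find(peptide, pos + 1)
    if not hits:
        return _UNMAPPED_CALL
    best = max(hits, key=lambda c: (_RANK[c.specificity], -c.start))
    if len(hits) > 1:
        best = SpecificityCall(
            best.specificity,
            best.n_term_tryptic,
            best.c_term_tryptic,
            best.missed_cleavages,
            best.start,
            best.end,
            multi_mapped=True,
        )
    return best


def is_nontryptic_evidence(call: SpecificityCall) -> bool:
    """Turnover evidence: at least one non-tryptic terminus.

    Endogenous proteolysis in a trypsin-digested sample manifests mostly as
    one non-tryptic terminus, so semi-tryptic peptides count too.
    """
    return call.specificity in (SEMI_TRYPTIC, NON_TRYPTIC)
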