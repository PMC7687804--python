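"""Independent brute-force oracles for digestion logic.

Deliberately written as exhaustive substring enumeration, a different shape
from the implementation's boundary walk, so agreement is meaningful.
"""

from __future__ import annotations


def oracle_sites(seq: str) -> set[int]:
    """0-based cut offsets: trypsin cleaves between i and i+1."""
    return {
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    }


def oracle_digest(seq: str, max_mc: int) -> set[tuple[str, int, int, int]]:
    """All tryptic peptides as (sequence, start1, end1, mc) via substring scan."""
    cuts = oracle_sites(seq)
    boundaries = {-1} | cuts | {len(seq) - 1}  # cut after these 0-based offsets
    out = set()
    for i in range(len(seq)):
        for j in range(i, len(seq)):
            if (i - 1) in boundaries and j in boundaries:
                internal = sum(1 for k in cuts if i <= k < j)
                if internal <= max_mc:
                    out.add((seq[i : j + 1], i + 1, j + 1, internal))
    return out


def oracle_specificity(pep: str, prot: str):
    """(specificity, n_ok, c_ok, mc, start1, end1, multi) or 'unmapped'."""
    cuts = oracle_sites(prot)
    occs = []
    for i in range(len(prot) - len(pep) + 1):
        if prot[i : i + len(pep)] != pep:
            continue
        j = i + len(pep) - 1
        n_ok = i == 0 or (i - 1) in cuts or (i == 1 and prot[0] == "M")
        c_ok = j == len(prot) - 1 or j in cuts
        mc = sum(1 for k in cuts if i <= k < j)
        spec = {2: "fully_tryptic", 1: "semi_tryptic", 0: "non_tryptic"}[
            int(n_ok) + int(c_ok)
        ]
        occs.append((spec, n_ok, c_ok, mc, i + 1, j + 1))
    if not occs:
        return "unmapped"
    rank = {"fully_tryptic": 2, "semi_tryptic": 1, "non_tryptic": 0}
    best = max(occs, key=lambda o: (rank[o[0]], -o[4]))
    return (*best, len(occs) > 1)
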