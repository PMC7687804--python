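"""File formats and shared domain types.

The pipeline consumes three plain-text inputs — a protein FASTA, tab-separated
PSM (peptide-spectrum-match) tables as exported downstream of a database
search, and a sample-design table mapping each MS run to its experimental
group — and writes tab-separated result tables plus a JSON run summary.

All tables are UTF-8, tab-separated; lines starting with ``#`` are comments.
Decimal points only (locale-independent parsing).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Controlled modification vocabulary: name -> (monoisotopic delta mass, allowed residues)
MOD_VOCAB: dict[str, tuple[float, str]] = {
    "label-K6": (6.0201, "K"),
    "phospho": (79.9663, "STY"),
    "carbamidomethyl": (57.0215, "C"),
}

#: Tolerance for matching a printed rounded delta mass to the vocabulary.
MOD_MASS_TOL = 0.01

CONDITIONS = ("Control", "LPS")
LAYERS = ("GC", "EC", "SMC")


class FormatError(ValueError):
    """Malformed input file (bad header, illegal residue, unknown value)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One entry of the protein search space."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise FormatError(
                f"{self.accession}: non-canonical residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class Modification:
    """A localized peptide modification.

    ``position`` is 1-based into the peptide; ``residue`` is the amino acid
    at that position.  ``localization_score`` (e.g. Ascore) is ``None`` when
    the search engine reported none.
    """

    name: str
    delta_mass: float
    position: int
    residue: str
    localization_score: float | None = None

    def validate(self, peptide: str) -> None:
        if not 1 <= self.position <= len(peptide):
            raise FormatError(
                f"modification position {self.position} outside peptide {peptide!r}"
            )
        if peptide[self.position - 1] != self.residue:
            raise FormatError(
                f"modification residue {self.residue} does not match "
                f"{peptide[self.position - 1]} at position {self.position} of {peptide!r}"
            )
        if self.name in MOD_VOCAB and self.residue not in MOD_VOCAB[self.name][1]:
            raise FormatError(
                f"{self.name} not allowed on residue {self.residue} "
                f"(peptide {peptide!r}, position {self.position})"
            )


@dataclass(frozen=True)
class PsmRecord:
    """One peptide identification with its spectral count and provenance."""

    peptide: str
    modifications: tuple[Modification, ...]
    protein_accessions: tuple[str, ...]
    spectral_count: int
    sample_id: str

    def __post_init__(self) -> None:
        if not self.peptide:
            raise FormatError("empty peptide")
        if self.spectral_count < 0:
            raise FormatError(f"negative spectral count for {self.peptide!r}")
        for mod in self.modifications:
            mod.validate(self.peptide)


@dataclass(frozen=True)
class SampleDesign:
    """Maps one MS run to condition x layer x animal."""

    sample_id: str
    condition: str
    layer: str
    animal_id: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(f"unknown condition {self.condition!r}")
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}")

    @property
    def group(self) -> tuple[str, str]:
        return (self.condition, self.layer)


def match_modification(delta: float, residue: str) -> tuple[str, float]:
    """Resolve a printed delta mass to the controlled vocabulary.

    PEAKS-style exports print rounded deltas ("+6.02"); the match is made
    within ±0.01 Da and the exact vocabulary mass is stored.
    """
    for name, (mass, residues) in MOD_VOCAB.items():
        if abs(delta - mass) <= MOD_MASS_TOL and residue in residues:
            return name, mass
    raise FormatError(f"unrecognized modification +{delta} on {residue}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records.

    Sequences are uppercased; duplicate accessions are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate accession {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, desc, str(rec.seq).upper()))
    return records


def write_fasta(records: list[ProteinRecord], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.accession}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Inline / columnar modification notation

def _parse_delta(text: str, context: str) -> float:
    text = text.strip()
    if "," in text:
        raise FormatError(f"{context}: decimal commas are not accepted ({text!r})")
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"{context}: unparseable mass delta {text!r}") from exc


def parse_inline_peptide(annotated: str) -> tuple[str, tuple[Modification, ...]]:
    """Parse PEAKS-style inline notation, e.g. ``ASK(+6.02)LR``.

    Returns the bare peptide and the resolved modifications.
    """
    bare: list[str] = []
    mods: list[Modification] = []
    i = 0
    while i < len(annotated):
        ch = annotated[i]
        if ch == "(":
            j = annotated.find(")", i)
            if j < 0:
                raise FormatError(f"unclosed modification in {annotated!r}")
            if not bare:
                raise FormatError(f"modification before first residue in {annotated!r}")
            delta = _parse_delta(annotated[i + 1 : j].lstrip("+"), annotated)
            residue = bare[-1]
            name, mass = match_modification(delta, residue)
            mods.append(Modification(name, mass, len(bare), residue))
            i = j + 1
        else:
            bare.append(ch)
            i += 1
    return "".join(bare), tuple(mods)


def parse_mod_field(text: str, peptide: str) -> tuple[Modification, ...]:
    """Parse the ``modifications`` column: semicolon-separated ``pos:RES(+delta)``.

    An optional ``@score`` suffix carries the localization score,
    e.g. ``4:S(+79.97)@1000``.
    """
    text = text.strip()
    if not text:
        return ()
    mods = []
    for tok in text.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        score: float | None = None
        if "@" in tok:
            tok, score_s = tok.rsplit("@", 1)
            score = _parse_delta(score_s, tok)
        try:
            pos_s, rest = tok.split(":", 1)
            pos = int(pos_s)
            residue = rest[0]
            if rest[1] != "(" or not rest.endswith(")"):
                raise ValueError
            delta = _parse_delta(rest[2:-1].lstrip("+"), tok)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"unparseable modification token {tok!r}") from exc
        if not 1 <= pos <= len(peptide) or peptide[pos - 1] != residue:
            raise FormatError(
                f"modification {tok!r} inconsistent with peptide {peptide!r}"
            )
        name, mass = match_modification(delta, residue)
        mods.append(Modification(name, mass, pos, residue, score))
    return tuple(mods)


def format_mod_field(mods: tuple[Modification, ...]) -> str:
    toks = []
    for m in sorted(mods, key=lambda m: m.position):
        tok = f"{m.position}:{m.residue}(+{m.delta_mass:.4f})"
        if m.localization_score is not None:
            tok += f"@{m.localization_score:g}"
        toks.append(tok)
    return ";".join(toks)


# ---------------------------------------------------------------------------
# TSV tables

PSM_COLUMNS = ["sample_id", "peptide", "modifications", "proteins", "spectral_count"]
DESIGN_COLUMNS = ["sample_id", "condition", "layer", "animal_id"]


def _read_tsv(path: str | os.PathLike, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_design(path: str | os.PathLike) -> list[SampleDesign]:
    df = _read_tsv(path, DESIGN_COLUMNS)
    rows = [
        SampleDesign(r.sample_id, r.condition, r.layer, r.animal_id)
        for r in df.itertuples()
    ]
    keys = [(d.condition, d.layer, d.animal_id) for d in rows]
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (condition, layer, animal_id) rows")
    ids = [d.sample_id for d in rows]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample_id")
    return rows


def write_design(design: list[SampleDesign], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(d.sample_id, d.condition, d.layer, d.animal_id) for d in design],
        columns=DESIGN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_psm_table(
    path: str | os.PathLike, design: list[SampleDesign] | None = None
) -> list[PsmRecord]:
    """Read a PSM TSV (columns: sample_id, peptide, modifications, proteins,
    spectral_count).

    The peptide column may carry inline PEAKS-style annotations
    (``ASK(+6.02)LR``); those are merged with the ``modifications`` column.
    With a ``design`` given, every sample_id must resolve to a design row.
    """
    df = _read_tsv(path, PSM_COLUMNS)
    known = {d.sample_id for d in design} if design is not None else None
    records: list[PsmRecord] = []
    for r in df.itertuples():
        if known is not None and r.sample_id not in known:
            raise FormatError(f"{path}: unknown sample_id {r.sample_id!r}")
        peptide, inline_mods = parse_inline_peptide(r.peptide)
        col_mods = parse_mod_field(r.modifications, peptide)
        mods = tuple(
            sorted(set(inline_mods) | set(col_mods), key=lambda m: (m.position, m.name))
        )
        try:
            count = int(r.spectral_count)
        except ValueError as exc:
            raise FormatError(
                f"{path}: unparseable spectral_count {r.spectral_count!r}"
            ) from exc
        if count < 0:
            raise FormatError(f"{path}: negative spectral_count for {peptide!r}")
        proteins = tuple(p for p in r.proteins.split(";") if p)
        records.append(PsmRecord(peptide, mods, proteins, count, r.sample_id))
    return records


def write_psm_table(psms: list[PsmRecord], path: str | os.PathLike) -> None:
    rows = [
        (
            p.sample_id,
            p.peptide,
            format_mod_field(p.modifications),
            ";".join(p.protein_accessions),
            p.spectral_count,
        )
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    summary: dict | None = None,
) -> dict[str, str]:
    """Write result tables as TSV plus a JSON run summary.

    Column order is taken from each DataFrame (deterministic as built by the
    analysis modules).  Returns name -> written path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    if summary is not None:
        path = os.path.join(out_dir, "run_summary.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["run_summary"] = path
    return paths


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
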