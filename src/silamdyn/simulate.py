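"""Synthetic post-search PSM data with known ground truth.

Emulates what a database search exports for a pulsed-SILAM spectral-counting
experiment: a random proteome, a condition x layer x animal design, and
per-animal PSM tables in which

* a per-group fraction of proteins belongs to the newly-synthesized pool and
  their lysine-containing peptides carry K6 labels with a per-peptide
  probability;
* spectral counts are overdispersed (negative binomial; a detected peptide
  always has count >= 1);
* endogenous proteolysis is injected as semi-tryptic truncations of tryptic
  peptides at a configurable per-group rate;
* a subset of proteins in the LPS condition has its labeled-peptide counts
  suppressed/amplified by a fold change (binomial thinning, so the expected
  count scales exactly);
* candidate phosphosites are detected with condition-specific probabilities,
  a configurable fraction being LPS-only.

Everything needed to score the pipeline against the generator (true pool
membership, modulated proteins, true phosphosites) is returned as a ground
truth dictionary and can be written as JSON.  A fixed seed reproduces the
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as sio
from .digestion import classify_specificity, digest, is_nontryptic_evidence

#: Residue sampling weights; K+R ~ 12% keeps tryptic peptides usably short.
_RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")
_WEIGHTS = {
    "A": 8.0, "C": 1.5, "D": 5.5, "E": 6.5, "F": 4.0, "G": 7.0, "H": 2.5,
    "I": 5.5, "K": 7.0, "L": 9.5, "M": 2.5, "N": 4.0, "P": 4.5, "Q": 4.0,
    "R": 5.0, "S": 7.0, "T": 5.5, "V": 6.5, "W": 1.5, "Y": 3.0,
}

_GROUPS_ALL = tuple(
    (c, l) for c in ("Control", "LPS") for l in ("GC", "EC", "SMC")
)

#: Named scenario presets (data, not code).  "fig1_fractions" carries the
#: published per-layer newly-synthesized proteome fractions as labeling
#: probabilities; "null" gives both conditions identical parameters.
PRESETS: dict[str, dict] = {
    "fig1_fractions": {
        "protein_label_prob": {
            ("Control", "GC"): 0.31,
            ("Control", "EC"): 0.29,
            ("Control", "SMC"): 0.34,
            ("LPS", "GC"): 0.16,
            ("LPS", "EC"): 0.18,
            ("LPS", "SMC"): 0.16,
        },
    },
    "null": {
        "protein_label_prob": 0.30,
        "frac_modulated": 0.0,
        "nsp_fold_change": 1.0,
    },
}


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Defaults describe a mid-size pulsed-SILAM study: ~30% of proteins newly
    synthesized, overdispersed spectral counts around 3, three animals per
    group.  ``protein_label_prob`` and ``endogenous_cleavage_prob`` accept a
    single float or a {(condition, layer): value} mapping.
    """

    n_proteins: int = 500
    protein_length: tuple[int, int] = (250, 450)
    n_animals: int = 3
    groups: tuple[tuple[str, str], ...] = (("Control", "EC"), ("LPS", "EC"))
    protein_label_prob: float | dict = 0.30
    peptide_label_prob: float = 0.6
    peptidome_label_prob: float | None = None
    sc_mean: float = 3.0
    sc_dispersion: float = 0.5
    detect_prob: float = 0.8
    min_peptide_len: int = 6
    max_peptide_len: int = 30
    max_missed_cleavages: int = 2
    missed_cleavage_rate: float = 0.15
    endogenous_cleavage_prob: float | dict = 0.05
    frac_modulated: float = 0.0
    nsp_fold_change: float = 1.0
    phospho_sites_per_protein: float = 0.0
    phospho_detect_prob: dict = field(
        default_factory=lambda: {"Control": 0.05, "LPS": 0.3}
    )
    lps_only_site_frac: float = 0.0
    phospho_low_score_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        def probs(x):
            return list(x.values()) if isinstance(x, dict) else [x]

        for name in (
            "peptide_label_prob",
            "detect_prob",
            "missed_cleavage_rate",
            "frac_modulated",
            "lps_only_site_frac",
            "phospho_low_score_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("protein_label_prob", "endogenous_cleavage_prob"):
            for v in probs(getattr(self, name)):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} value {v} outside [0, 1]")
        for v in self.phospho_detect_prob.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("phospho_detect_prob outside [0, 1]")
        if self.peptidome_label_prob is not None and not (
            0.0 <= self.peptidome_label_prob <= 1.0
        ):
            raise ValueError("peptidome_label_prob outside [0, 1]")
        if self.sc_mean < 1.0:
            raise ValueError("sc_mean must be >= 1 (a detected peptide has count >= 1)")
        if self.n_proteins < 1 or self.n_animals < 1:
            raise ValueError("n_proteins and n_animals must be positive")
        if self.protein_length[0] < 30 or self.protein_length[1] < self.protein_length[0]:
            raise ValueError("bad protein_length range")

    def group_value(self, attr: str, group: tuple[str, str]) -> float:
        v = getattr(self, attr)
        if isinstance(v, dict):
            try:
                return v[group]
            except KeyError as exc:
                raise KeyError(f"{attr} has no value for group {group}") from exc
        return v

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SyntheticConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        params = {**PRESETS[name], **overrides}
        if "groups" not in params:
            params["groups"] = _GROUPS_ALL if name == "fig1_fractions" else cls.groups
        return cls(**params)


def _draw_sequence(rng: np.random.Generator, length: int) -> str:
    w = np.array([_WEIGHTS[r] for r in _RESIDUES])
    return "".join(rng.choice(_RESIDUES, size=length, p=w / w.sum()))


def generate_proteome(config: SyntheticConfig) -> list[sio.ProteinRecord]:
    """Random protein database with tryptic-friendly composition.

    Each sequence is resampled until it yields >= 2 tryptic peptides of
    usable length (6-30 by default) at the configured missed-cleavage cap.
    Deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length
    records = []
    for i in range(config.n_proteins):
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, length)
            usable = [
                p
                for p in digest(seq, config.max_missed_cleavages)
                if config.min_peptide_len <= len(p.sequence) <= config.max_peptide_len
            ]
            if len(usable) >= 2:
                break
        records.append(sio.ProteinRecord(f"SYN{i:04d}", "synthetic protein", seq))
    return records


def _nb_count(rng: np.random.Generator, mean: float, alpha: float) -> int:
    """1 + NB(mean-1, alpha) with var = mu + alpha*mu^2 on the NB part."""
    mu = mean - 1.0
    if mu <= 0:
        return 1
    if alpha <= 0:
        return 1 + int(rng.poisson(mu))
    r = 1.0 / alpha
    p = r / (r + mu)
    return 1 + int(rng.negative_binomial(r, p))


def _truncate_semi(
    rng: np.random.Generator, pep, protein_seq: str
) -> str | None:
    """Semi-tryptic truncation of a tryptic peptide; None if no valid cut."""
    seq = pep.sequence
    if len(seq) < 7:
        return None
    for _ in range(5):
        keep_n = bool(rng.integers(0, 2))
        cut = int(rng.integers(3, len(seq) - 2))  # keep >= 3 residues each side
        cand = seq[:cut] if keep_n else seq[cut:]
        if len(cand) < 5:
            continue
        call = classify_specificity(cand, protein_seq)
        if is_nontryptic_evidence(call):
            return cand
    return None


def _eligible_peptides(config: SyntheticConfig, seq: str, rng: np.random.Generator):
    """Observable tryptic peptide universe for one protein.

    All mc=0 peptides of usable length, plus a random subset of
    missed-cleavage peptides at ``missed_cleavage_rate``.
    """
    out = []
    for p in digest(seq, config.max_missed_cleavages):
        if not config.min_peptide_len <= len(p.sequence) <= config.max_peptide_len:
            continue
        if p.missed_cleavages == 0 or rng.random() < config.missed_cleavage_rate:
            out.append(p)
    return out


def generate_psm_tables(
    config: SyntheticConfig, proteome: list[sio.ProteinRecord] | None = None
) -> tuple[list[sio.PsmRecord], list[sio.SampleDesign], dict]:
    """Simulate the full experiment: PSMs, design, and ground truth.

    Returns (psms, design, truth).  The truth dictionary is sufficient to
    compute every generator-level quantity the pipeline estimates: per-group
    newly-synthesized proteins, labeled peptide sets, modulated proteins,
    injected semi-tryptic peptides, and true phosphosites with their
    condition specificity.
    """
    config.validate()
    if proteome is None:
        proteome = generate_proteome(config)
    rng = np.random.default_rng((config.seed, 0x5EED))

    design: list[sio.SampleDesign] = []
    for (cond, layer) in config.groups:
        for a in range(1, config.n_animals + 1):
            design.append(
                sio.SampleDesign(
                    f"{cond}_{layer}_a{a}", cond, layer, f"{cond}_{layer}_animal{a}"
                )
            )

    # Per-protein peptide universe (shared across groups/animals).
    universe = {p.accession: _eligible_peptides(config, p.sequence, rng) for p in proteome}
    seqs = {p.accession: p.sequence for p in proteome}

    # Peptidome-level labeling mode: marginal Bernoulli over distinct
    # peptides, realized on the K-containing ones at a rescaled rate so the
    # marginal over ALL distinct peptides equals peptidome_label_prob.
    peptidome_labels: dict[str, bool] | None = None
    if config.peptidome_label_prob is not None:
        distinct = sorted({p.sequence for peps in universe.values() for p in peps})
        with_k = [s for s in distinct if "K" in s]
        if not with_k:
            raise ValueError("no lysine-containing peptides to label")
        p_eff = config.peptidome_label_prob * len(distinct) / len(with_k)
        if p_eff > 1.0:
            raise ValueError(
                "peptidome_label_prob too high for the lysine-containing share"
            )
        flags = rng.random(len(with_k)) < p_eff
        labeled_set = {s for s, f in zip(with_k, flags) if f}
        peptidome_labels = {s: (s in labeled_set) for s in distinct}

    # Ground-truth containers
    truth: dict = {
        "config": _config_dict(config),
        "groups": {},
        "modulated_proteins": [],
        "phospho_sites": [],
    }

    # LPS effect-model proteins (shared across layers)
    accs = [p.accession for p in proteome]
    n_mod = int(round(config.frac_modulated * len(accs)))
    modulated = set(rng.choice(accs, size=n_mod, replace=False)) if n_mod else set()
    truth["modulated_proteins"] = sorted(modulated)
    truth["nsp_fold_change"] = config.nsp_fold_change

    # Candidate phosphosites: positions on S/T/Y covered by an eligible peptide.
    phospho_sites = []
    if config.phospho_sites_per_protein > 0:
        for acc in accs:
            covered = {}
            for pep in universe[acc]:
                for off, res in enumerate(pep.sequence):
                    if res in "STY":
                        covered.setdefault(pep.start + off, (res, pep))
            if not covered:
                continue
            n_sites = int(rng.poisson(config.phospho_sites_per_protein))
            n_sites = min(n_sites, len(covered))
            if n_sites == 0:
                continue
            positions = sorted(covered)
            chosen = rng.choice(len(positions), size=n_sites, replace=False)
            for ci in sorted(chosen):
                pos = positions[ci]
                res, pep = covered[pos]
                lps_only = rng.random() < config.lps_only_site_frac
                phospho_sites.append(
                    {"accession": acc, "position": int(pos), "residue": res,
                     "peptide": pep, "lps_only": bool(lps_only)}
                )
    truth["phospho_sites"] = [
        {k: v for k, v in s.items() if k != "peptide"}
        | {"peptide": s["peptide"].sequence, "peptide_start": s["peptide"].start}
        for s in phospho_sites
    ]

    # Synthesis state is correlated across conditions: one latent uniform per
    # protein (and per peptide) realizes the group-specific labeling
    # probabilities comonotonically, so pools nest when probabilities shrink
    # (marginals are exact; a protein synthesized under Control keeps being
    # synthesized under LPS whenever the LPS probability allows).
    u_protein = dict(zip(accs, rng.random(len(accs))))
    u_peptide = {
        (acc, pep.sequence): rng.random()
        for acc in accs
        for pep in universe[acc]
    }

    psms: list[sio.PsmRecord] = []
    for group in config.groups:
        cond, layer = group
        gkey = f"{cond}_{layer}"
        p_label = config.group_value("protein_label_prob", group)
        p_cleave = config.group_value("endogenous_cleavage_prob", group)

        nsp_proteins = {a for a in accs if u_protein[a] < p_label}
        group_labels: dict[tuple[str, str], bool] = {}
        for acc in accs:
            for pep in universe[acc]:
                if peptidome_labels is not None:
                    flag = peptidome_labels[pep.sequence]
                else:
                    flag = (
                        acc in nsp_proteins
                        and "K" in pep.sequence
                        and u_peptide[(acc, pep.sequence)] < config.peptide_label_prob
                    )
                group_labels[(acc, pep.sequence)] = flag
        truth["groups"][gkey] = {
            "condition": cond,
            "layer": layer,
            "protein_label_prob": p_label,
            "endogenous_cleavage_prob": p_cleave,
            "nsp_proteins": sorted(nsp_proteins),
            "n_labeled_peptides": int(sum(group_labels.values())),
            "n_peptides": len(group_labels),
        }

        suppress = cond == "LPS" and config.nsp_fold_change != 1.0
        for d in [x for x in design if x.group == group]:
            for acc in accs:
                for pep in universe[acc]:
                    if rng.random() >= config.detect_prob:
                        continue
                    count = _nb_count(rng, config.sc_mean, config.sc_dispersion)
                    labeled = group_labels[(acc, pep.sequence)]
                    if labeled and suppress and acc in modulated:
                        count = int(rng.binomial(count, config.nsp_fold_change))
                        if count == 0:
                            continue
                    mods = ()
                    if labeled:
                        mods = tuple(
                            sio.Modification("label-K6", 6.0201, i + 1, "K")
                            for i, r in enumerate(pep.sequence)
                            if r == "K"
                        )
                    psms.append(
                        sio.PsmRecord(pep.sequence, mods, (acc,), count, d.sample_id)
                    )
                    # endogenous proteolysis: semi-tryptic truncation
                    if rng.random() < p_cleave:
                        cand = _truncate_semi(rng, pep, seqs[acc])
                        if cand is not None:
                            psms.append(
                                sio.PsmRecord(
                                    cand,
                                    (),
                                    (acc,),
                                    _nb_count(rng, config.sc_mean, config.sc_dispersion),
                                    d.sample_id,
                                )
                            )
            # phosphosite observations
            for site in phospho_sites:
                p_det = config.phospho_detect_prob.get(cond, 0.0)
                if site["lps_only"] and cond != "LPS":
                    p_det = 0.0
                if rng.random() >= p_det:
                    continue
                pep = site["peptide"]
                offset = site["position"] - pep.start + 1
                score = 1000.0
                if (
                    config.phospho_low_score_frac > 0
                    and rng.random() < config.phospho_low_score_frac
                ):
                    score = 500.0
                mod = sio.Modification(
                    "phospho", 79.9663, offset, site["residue"], score
                )
                psms.append(
                    sio.PsmRecord(
                        pep.sequence,
                        (mod,),
                        (site["accession"],),
                        _nb_count(rng, config.sc_mean, config.sc_dispersion),
                        d.sample_id,
                    )
                )
    return psms, design, truth


def _config_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("protein_label_prob", "endogenous_cleavage_prob"):
        if isinstance(d[key], dict):
            d[key] = {f"{c}_{l}": v for (c, l), v in d[key].items()}
    d["groups"] = [f"{c}_{l}" for (c, l) in d["groups"]]
    d["phospho_detect_prob"] = dict(d["phospho_detect_prob"])
    return d


def write_dataset(
    config: SyntheticConfig, out_dir: str | os.PathLike
) -> dict[str, str]:
    """Generate and write FASTA + PSM TSV + design TSV + truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    proteome = generate_proteome(config)
    psms, design, truth = generate_psm_tables(config, proteome)
    paths = {
        "fasta": os.path.join(out_dir, "proteome.fasta"),
        "psms": os.path.join(out_dir, "psms.tsv"),
        "design": os.path.join(out_dir, "design.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    sio.write_fasta(proteome, paths["fasta"])
    sio.write_psm_table(psms, paths["psms"])
    sio.write_design(design, paths["design"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
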