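"""End-to-end orchestration: ingest -> classify -> labeling -> dynamics ->
turnover -> phospho, with a machine-readable run report.

Identical inputs and configuration produce byte-identical outputs; every
stage logs record counts into the report so PSMs can be accounted for
(classified = attributed + shared + unmapped).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .classify import SHARED_POLICY_UNIQUE, classify_psms
from .digestion import UNMAPPED
from .dynamics import call_regulation, regulation_table, results_to_frame
from .io import (
    FormatError,
    read_design,
    read_fasta,
    read_psm_table,
    write_results,
)
from .labeling import (
    incorporation_profiles,
    labeled_peptidome_fraction,
    labeled_proteome_fraction,
)
from .phospho import (
    call_disease_specific,
    collect_sites,
    count_sites_per_group,
    sites_to_frame,
)
from .turnover import map_cleavage_sites, score_turnover, turnover_matrix

log = logging.getLogger("silamdyn")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds, and policy switches for a full run."""

    fasta: str
    psm_tables: list[str]
    design: str
    out_dir: str
    p_threshold: float = 0.05
    fold_threshold: float = 1.5
    min_ascore: float = 1000.0
    min_animals: int = 2
    max_missed_cleavages: int = 2
    shared_policy: str = SHARED_POLICY_UNIQUE
    welch: bool = False
    include_lysine_free: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("p_threshold", "fold_threshold", "min_ascore"):
            if getattr(self, name) <= 0:
                raise PipelineError("config", f"{name} must be positive")
        if self.min_animals < 1:
            raise PipelineError("config", "min_animals must be >= 1")
        for path in [self.fasta, self.design, *self.psm_tables]:
            if not os.path.exists(path):
                raise PipelineError("config", f"input path not found: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        if extra:
            kwargs["extra"] = extra
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise PipelineError("config", str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all result tables plus a report JSON.

    Returns the report dictionary.  Any stage error aborts with a
    stage-named :class:`PipelineError`.
    """
    config.validate()
    t0 = time.time()
    report: dict = {
        "version": __version__,
        "config": {
            k: v for k, v in config.__dict__.items() if not isinstance(v, dict)
        },
        "stages": {},
        "warnings": [],
        "notes": [
            "phosphosite filtering uses the localization-score threshold as an "
            "automated surrogate for manual validation"
        ],
    }

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": round(time.time() - t0, 3)}
        return report["stages"][name]

    # ingest -------------------------------------------------------------
    s = stage("ingest")
    try:
        proteins = read_fasta(config.fasta)
        design = read_design(config.design)
        psms = []
        for path in config.psm_tables:
            psms.extend(read_psm_table(path, design))
    except FormatError as exc:
        raise PipelineError("ingest", str(exc)) from exc
    s.update(n_proteins=len(proteins), n_samples=len(design), n_psms=len(psms))

    # classify -----------------------------------------------------------
    s = stage("classify")
    classified = classify_psms(psms, proteins, config.shared_policy)
    n_attr = sum(1 for c in classified if c.accession is not None)
    n_shared = sum(1 for c in classified if c.shared)
    n_unmapped = sum(1 for c in classified if c.specificity.specificity == UNMAPPED)
    s.update(
        n_classified=len(classified),
        n_attributed=n_attr,
        n_shared=n_shared,
        n_unmapped=n_unmapped,
        drop_reasons={
            "shared_peptides": sum(
                1 for c in classified if c.shared and c.accession is None
            ),
            "unmapped": n_unmapped,
        },
    )
    if n_unmapped:
        report["warnings"].append(f"{n_unmapped} PSMs did not map to any protein")

    groups = sorted({d.group for d in design})
    layers = sorted({l for (_c, l) in groups})

    # labeling -----------------------------------------------------------
    s = stage("labeling")
    incorporation_rows = []
    fractions = {}
    for group in groups:
        gname = f"{group[0]}_{group[1]}"
        pf = labeled_proteome_fraction(
            classified, design, group, min_animals=config.min_animals
        )
        ppf = labeled_peptidome_fraction(
            classified, design, group, include_lysine_free=config.include_lysine_free
        )
        fractions[gname] = {
            "labeled_proteins": pf.n_labeled,
            "detected_proteins": pf.n_detected,
            "proteome_fraction": pf.fraction,
            "proteome_fraction_per_animal_mean": pf.mean,
            "proteome_fraction_per_animal_sd": pf.sd,
            "peptidome_fraction": ppf.fraction,
            "peptidome_fraction_sc_weighted": ppf.fraction_sc_weighted,
        }
        for p in incorporation_profiles(classified, design, group):
            incorporation_rows.append(
                (
                    p.accession,
                    gname,
                    p.labeled_sc,
                    p.total_sc,
                    p.incorporation_fraction,
                    p.labeled_peptides,
                    p.total_peptides,
                    p.incorporation_fraction_peptides,
                )
            )
    incorporation_df = pd.DataFrame(
        incorporation_rows,
        columns=[
            "accession",
            "group",
            "labeled_sc",
            "total_sc",
            "incorporation_fraction",
            "labeled_peptides",
            "total_peptides",
            "incorporation_fraction_peptides",
        ],
    )
    s.update(fractions=fractions, n_profiles=len(incorporation_df))

    # dynamics -----------------------------------------------------------
    s = stage("dynamics")
    from .dynamics import aggregate_counts

    counts = aggregate_counts(classified, design)
    all_results = []
    for layer in layers:
        if ("LPS", layer) in counts or ("Control", layer) in counts:
            all_results.extend(
                regulation_table(
                    counts, layer, min_animals=config.min_animals, welch=config.welch
                )
            )
    regulation_df = results_to_frame(all_results)
    regulated_df = call_regulation(all_results)
    s.update(n_tested=len(regulation_df), n_regulated=len(regulated_df))

    # turnover -----------------------------------------------------------
    s = stage("turnover")
    scores = score_turnover(classified, design)
    matrix = turnover_matrix(scores).reset_index()
    sites_df = map_cleavage_sites(classified, design)
    s.update(n_turnover_proteins=len(matrix), n_cleavage_sites=len(sites_df))

    # phospho ------------------------------------------------------------
    s = stage("phospho")
    psites = collect_sites(classified, proteins, design, min_score=config.min_ascore)
    phospho_df = sites_to_frame(psites)
    site_counts = count_sites_per_group(psites, design)
    disease_df = call_disease_specific(psites)
    s.update(
        n_sites=len(psites),
        n_disease_specific=int(sum(s_.disease_specific for s_ in psites)),
    )

    # write --------------------------------------------------------------
    stage("write")
    tables = {
        "incorporation": incorporation_df,
        "regulation": regulation_df,
        "regulated": regulated_df,
        "turnover_matrix": matrix,
        "cleavage_sites": sites_df,
        "phosphosites": phospho_df,
        "phosphosite_counts": site_counts,
        "disease_specific_sites": disease_df,
    }
    report["elapsed_s"] = round(time.time() - t0, 3)
    paths = write_results(tables, config.out_dir, summary=report)
    report["outputs"] = paths
    with open(
        os.path.join(config.out_dir, "run_summary.json"), "w", encoding="utf-8"
    ) as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
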