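"""End-to-end orchestration of the analysis stages with one config.

Stage order: simulate (optional) → filter → cna (optional) → adjust →
cluster → pairs + chclass + outcomes.  Every stage writes TSVs through
:func:`clonehier.cohort_model.write_results`; the run manifest records the
seed, per-stage row counts and file checksums, so a re-run with the same
config and seed is verifiable as byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from clonehier import ch_class, cooccur, outcomes
from clonehier.clonal_dp import DPConfig, cohort_summary, fit_cohort
from clonehier.cohort_model import (
    CohortTable,
    ValidationError,
    attach_cn_states,
    filter_variants,
    read_clinical_table,
    read_mutation_table,
    read_seg,
    write_results,
)
from clonehier.synthetic_cohort import SimulationConfig, simulate_cohort
from clonehier.tcf_adjust import adjust_table


@dataclass
class RunConfig:
    out_dir: str = "clonehier_out"
    mutations_path: str | None = None
    seg_path: str | None = None
    clinical_path: str | None = None
    simulate: bool = True
    n_patients: int = 300
    seed: int = 0
    min_depth: int = 20
    min_alt: int = 5
    dp: DPConfig = field(default_factory=lambda: DPConfig(iterations=2000, burn_in=200))
    min_pair_freq: float = 0.01
    q_co: float = 0.01
    q_ex: float = 0.25
    vaf_cut: float = 0.4
    survival_gene: str = "TP53"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        dp_raw = raw.pop("dp", {})
        cfg = cls(**raw)
        if dp_raw:
            cfg.dp = DPConfig(**{**dataclasses.asdict(cfg.dp), **dp_raw})
        return cfg


def _validate(config: RunConfig) -> None:
    if not config.simulate:
        for name in ("mutations_path", "clinical_path"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise ValidationError(f"{name} missing or does not exist: {p}")


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to out_dir)."""
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    if config.simulate:
        sim_cfg = SimulationConfig(n_patients=config.n_patients, seed=config.seed)
        cohort, truth = simulate_cohort(sim_cfg)
        stages["simulate"] = write_results(
            {"mutations": cohort.mutations, "clinical": cohort.clinical,
             "segments": cohort.cn_segments, "ground_truth": truth.mutations},
            out / "simulate", config={"seed": config.seed, "n": config.n_patients},
        )
    else:
        mutations = read_mutation_table(config.mutations_path)
        clinical = read_clinical_table(config.clinical_path)
        segments = (read_seg(config.seg_path) if config.seg_path
                    else pd.DataFrame(columns=["sample", "chrom", "start", "end",
                                               "region_class", "tcn", "ascn"]))
        cohort = CohortTable(mutations=mutations, clinical=clinical, cn_segments=segments)

    filtered = filter_variants(cohort.mutations, config.min_depth, config.min_alt)
    stages["filter"] = write_results({"filtered": filtered}, out / "filter")

    annotated = attach_cn_states(filtered, cohort.cn_segments)
    adjusted = adjust_table(annotated)
    stages["adjust"] = write_results({"adjusted": adjusted}, out / "adjust")

    dp = dataclasses.replace(config.dp, seed=config.seed)
    labels = fit_cohort(adjusted, dp)
    summary = cohort_summary(labels)
    stages["cluster"] = write_results(
        {"labels": labels, "clone_histogram": summary["clone_histogram"],
         "gene_ranks": summary["gene_ranks"]},
        out / "cluster", config={"dp_seed": dp.seed},
    )

    pairs = cooccur.pair_tables(labels, config.min_pair_freq,
                                q_co=config.q_co, q_ex=config.q_co)
    pheno = cooccur.phenotype_or(labels, cohort.clinical)
    try:
        hma = cooccur.hma_association(cohort.clinical, labels)
    except ValidationError:
        hma = pd.DataFrame()
    stages["pairs"] = write_results({"pairs": pairs, "phenotype_or": pheno, "hma": hma},
                                    out / "pairs")

    classes = ch_class.classify_cohort(labels)
    profile = ch_class.ch_profile(classes, labels, cohort.clinical)
    stages["chclass"] = write_results(
        {"ch_classes": classes, "ch_sizes": profile["sizes"],
         "ch_secondary": profile["secondary_freq"]},
        out / "chclass",
    )

    surv = outcomes.survival_by_rank(cohort.clinical, labels, config.survival_gene,
                                     vaf_cut=config.vaf_cut)
    km_tables = {f"km_{name}": est["table"] for name, est in surv.get("km", {}).items()}
    comparison = pd.DataFrame(
        [{"contrast": k, **v} for k, v in surv["pairwise_cox"].items()]
    )
    ch_groups = [outcomes.group_from_clinical(cohort.clinical, pats, cls)
                 for cls, pats in profile["survival_groups"].items() if pats]
    ch_lr = outcomes.logrank(ch_groups) if len(ch_groups) >= 2 else {}
    stages["outcomes"] = write_results(
        {**km_tables, "cox_comparison": comparison,
         "ch_logrank": pd.DataFrame([ch_lr]) if ch_lr else pd.DataFrame()},
        out / "outcomes",
    )

    manifest = {"seed": config.seed, "stages": stages}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
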