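"""Ground-truth cohort generator.

Emulates the data structure of a large myeloid cohort sequenced with a
deep targeted panel: each patient carries 1–7 nested clones (mode 2); each
clone holds one or more mutations drawn from a 36-gene panel with
gene-specific dominant/secondary propensities; read counts are sampled
binomially at a negative-binomial depth (mean 796, truncated at the
read-support filter floor of 20); recurrent arm-level lesions (del(5q),
−7/del(7q), a 4q UPD) modify the expected VAF of overlapping mutations
through the TCF branch formulas; dichotomous phenotypes (MDS vs. MDS/MPN,
lower vs. higher risk) follow logistic models with configurable
dominant→secondary pair effects; survival is exponential with group-level
hazards under independent uniform censoring; hypomethylating-agent (HMA)
response is Bernoulli with per-gene effects.

Everything is driven by one :class:`numpy.random.Generator`, so identical
seed and config give a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from clonehier.cohort_model import CohortTable, ValidationError
from clonehier.tcf_adjust import vaf_expected
from clonehier.cohort_model import CopyNumberState
from clonehier import ch_class

#: fraction of patients with 1..7 clones; mode at 2 among multi-clone cases,
#: roughly half the cohort single-clone.
DEFAULT_CLONE_COUNT_WEIGHTS = (0.525, 0.300, 0.100, 0.045, 0.018, 0.008, 0.004)

#: arm-level lesions: (chrom, start, end, region_class, tcn, ascn, frequency)
DEFAULT_CNA_LESIONS = {
    "del5q": ("5", 48_800_000, 181_538_259, "deletion", 1.0, 0.0, 0.16),
    "minus7_del7q": ("7", 1, 159_138_663, "deletion", 1.0, 0.0, 0.10),
    "upd4q": ("4", 87_000_000, 191_154_276, "UPD", 2.0, 0.0, 0.04),
}

VARIANT_CLASS_PROBS = {
    "missense": 0.55, "truncating": 0.25, "splice": 0.08,
    "canonical_hotspot": 0.07, "other": 0.05,
}


def load_gene_propensities() -> pd.DataFrame:
    """Packaged per-gene panel: locus plus dominant/secondary draw weights."""
    with resources.files("clonehier.data").joinpath("gene_propensities.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_patients: int = 300
    clone_count_weights: tuple = DEFAULT_CLONE_COUNT_WEIGHTS
    mean_depth: float = 796.0
    depth_dispersion: float = 8.0          # NB size; CV ≈ sqrt(1/m + 1/size)
    min_depth: int = 20                    # truncation floor (matches the filter)
    gene_propensities: pd.DataFrame | None = None
    cna_lesions: dict = field(default_factory=lambda: dict(DEFAULT_CNA_LESIONS))
    extra_muts_per_clone: float = 0.3      # Poisson mean beyond the obligatory one
    branching: bool = False                # one branching event instead of a pure chain
    # phenotype logistic models: base log-odds + per-(dominant, secondary) pair effects
    mdsmpn_base_logit: float = -1.95       # ≈ logit(226/1809)
    high_risk_base_logit: float = -0.31    # ≈ logit(766/1809)
    phenotype_effects: dict = field(
        default_factory=lambda: {("TET2", "SRSF2"): {"mdsmpn": 1.5, "high_risk": 0.8}}
    )
    # survival: exponential with multiplicative group hazards, uniform censoring
    survival_base_rate: float = 0.026      # events/month; median ≈ 27 months
    hazard_ratios: dict = field(
        default_factory=lambda: {
            "dominant:TP53": 2.9, "ch:CH_U": 1.43, "high_risk": 1.8,
        }
    )
    censor_max_months: float = 120.0
    # HMA therapy
    hma_treated_frac: float = 0.10
    hma_base_logit: float = -0.75          # ≈ logit(0.32), the wild-type response rate
    hma_effects: dict = field(default_factory=lambda: {"TET2": 0.88, "ASXL1": -0.70})
    error_rate: float = 0.001
    unidirectional_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.clone_count_weights, float)
        if len(w) != 7 or (w < 0).any() or w.sum() <= 0:
            raise ValidationError("clone_count_weights must be 7 non-negative weights")
        self.clone_count_weights = tuple(w / w.sum())
        if self.gene_propensities is None:
            self.gene_propensities = load_gene_propensities()
        gp = self.gene_propensities
        if (gp[["dominant_weight", "secondary_weight"]].to_numpy() < 0).any():
            raise ValidationError("gene weights must be non-negative")
        if gp["dominant_weight"].sum() <= 0 or gp["secondary_weight"].sum() <= 0:
            raise ValidationError("degenerate all-zero gene weights")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    clones: pd.DataFrame      # patient_id, clone_idx, prevalence
    mutations: pd.DataFrame   # patient_id, mut_id, gene, clone_idx, label
    patients: pd.DataFrame    # patient_id, n_clones, phenotype flags, ch_class


def _draw_prevalences(rng: np.random.Generator, k: int, branching: bool) -> np.ndarray:
    """Nested clone prevalences, descending; chain topology by default."""
    p = np.empty(k)
    p[0] = rng.beta(5.0, 2.0)
    for i in range(1, k):
        if branching and i == 2:
            # second child of the founder: siblings must fit inside the parent
            hi = min(p[1], p[0] - p[1])
            p[i] = rng.uniform(0.0, max(hi, 1e-3))
        else:
            p[i] = p[i - 1] * rng.uniform(0.30, 0.85)
    return np.sort(p)[::-1]


def _truncated_nb(rng: np.random.Generator, mean: float, size_param: float,
                  floor: int, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    out = rng.negative_binomial(size_param, p, size=n)
    for _ in range(100):
        low = out < floor
        if not low.any():
            break
        out[low] = rng.negative_binomial(size_param, p, size=int(low.sum()))
    return np.maximum(out, floor)


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, GroundTruth]:
    """Generate a cohort and its ground truth from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    gp = config.gene_propensities
    genes = gp["gene"].to_numpy()
    gene_chrom = dict(zip(gp["gene"], gp["chrom"].astype(str)))
    gene_pos = dict(zip(gp["gene"], gp["pos"].astype(int)))
    w_dom = gp["dominant_weight"].to_numpy(float)
    w_sec = gp["secondary_weight"].to_numpy(float)
    w_dom = w_dom / w_dom.sum()
    w_sec = w_sec / w_sec.sum()
    vclasses = list(VARIANT_CLASS_PROBS)
    vprobs = np.array(list(VARIANT_CLASS_PROBS.values()))

    mut_rows, seg_rows, clin_rows = [], [], []
    truth_clone_rows, truth_mut_rows, truth_pat_rows = [], [], []

    for ip in range(config.n_patients):
        pid = f"P{ip:05d}"
        k = int(rng.choice(np.arange(1, 8), p=config.clone_count_weights))
        prev = _draw_prevalences(rng, k, config.branching)
        for ic, p in enumerate(prev):
            truth_clone_rows.append((pid, ic, float(p)))

        # copy-number lesions
        lesions: list[tuple[str, tuple]] = []
        for name, (chrom, start, end, rc, tcn, ascn, freq) in config.cna_lesions.items():
            if rng.random() < freq:
                lesions.append((name, (chrom, start, end, rc, tcn, ascn)))
                seg_rows.append((pid, chrom, start, end, rc, tcn, ascn))

        # mutations per clone
        n_per_clone = 1 + rng.poisson(config.extra_muts_per_clone, size=k)
        dominant_genes: list[str] = []
        secondary_genes: list[str] = []
        pat_mut_genes: list[str] = []
        for ic in range(k):
            weights = w_dom if ic == 0 else w_sec
            m = int(n_per_clone[ic])
            chosen = rng.choice(genes, size=min(m, len(genes)), replace=False, p=weights)
            for gene in chosen:
                chrom, pos0 = gene_chrom[gene], gene_pos[gene]
                pos = int(pos0 + rng.integers(0, 2000))
                rc, tcn, ascn = "neutral", 2.0, 1.0
                for _, (lchrom, lstart, lend, lrc, ltcn, lascn) in lesions:
                    if lchrom == chrom and lstart <= pos <= lend:
                        rc, tcn, ascn = lrc, float(ltcn), float(lascn)
                        break
                phi = float(prev[ic])
                if rc == "UPD":
                    # founder-clone mutations predate the UPD (duplicated allele)
                    branch = "upd_late" if ic == 0 else "upd_early"
                elif rc == "deletion":
                    branch = "deletion"
                elif rc == "gain":
                    branch = "gain"
                else:
                    branch = "neutral"
                cn = CopyNumberState(region_class=rc, tcn=tcn, ascn=ascn)
                evaf = vaf_expected(phi, cn, branch)
                p_read = float(np.clip(evaf, config.error_rate, 1.0 - config.error_rate))
                depth = int(_truncated_nb(rng, config.mean_depth,
                                          config.depth_dispersion, config.min_depth, 1)[0])
                alt = int(rng.binomial(depth, p_read))
                bidir = bool(rng.random() >= config.unidirectional_rate)
                vclass = str(rng.choice(vclasses, p=vprobs))
                mut_rows.append((pid, gene, vclass, chrom, pos, "A", "G",
                                 alt, depth, bidir))
                label = "dominant" if ic == 0 else "secondary"
                truth_mut_rows.append((pid, f"{pid}:{chrom}:{pos}", gene, ic, label,
                                       phi, branch, evaf))
                pat_mut_genes.append(gene)
                (dominant_genes if ic == 0 else secondary_genes).append(gene)

        # phenotypes from logistic models with pair effects
        lz_mpn = config.mdsmpn_base_logit
        lz_hr = config.high_risk_base_logit
        for (dg, sg), eff in config.phenotype_effects.items():
            if dg in dominant_genes and sg in secondary_genes:
                lz_mpn += eff.get("mdsmpn", 0.0)
                lz_hr += eff.get("high_risk", 0.0)
        is_mpn = rng.random() < 1.0 / (1.0 + np.exp(-lz_mpn))
        is_hr = rng.random() < 1.0 / (1.0 + np.exp(-lz_hr))
        diagnosis = "MDS_MPN" if is_mpn else "MDS"
        ipssr = float(rng.uniform(3.6, 10.0) if is_hr else rng.uniform(0.0, 3.5))

        ch = ch_class.classify_genes(set(dominant_genes))

        hazard = config.survival_base_rate
        for key, hr in config.hazard_ratios.items():
            if key == "high_risk":
                applies = is_hr
            elif key.startswith("dominant:"):
                applies = key.split(":", 1)[1] in dominant_genes
            elif key.startswith("secondary:"):
                applies = key.split(":", 1)[1] in secondary_genes
            elif key.startswith("ch:"):
                applies = ch == key.split(":", 1)[1]
            elif key.startswith("pair:"):
                dg, sg = key.split(":", 1)[1].split(">")
                applies = dg in dominant_genes and sg in secondary_genes
            else:
                raise ValidationError(f"unknown hazard group {key!r}")
            if applies:
                hazard *= hr
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0.0, config.censor_max_months)
        os_months = float(min(t_event, t_cens))
        os_event = bool(t_event <= t_cens)

        treated = bool(rng.random() < config.hma_treated_frac)
        response = "NA"
        if treated:
            lz = config.hma_base_logit + sum(
                eff for g, eff in config.hma_effects.items() if g in pat_mut_genes
            )
            if rng.random() < 1.0 / (1.0 + np.exp(-lz)):
                response = str(rng.choice(["CR", "PR", "HI"], p=[0.5, 0.25, 0.25]))
            else:
                response = "none"

        clin_rows.append((pid, diagnosis, ipssr, os_months, os_event, treated, response))
        truth_pat_rows.append((pid, k, bool(is_mpn), bool(is_hr), ch))

    mutations = pd.DataFrame(
        mut_rows,
        columns=["patient_id", "gene", "variant_class", "chrom", "pos", "ref", "alt",
                 "alt_reads", "depth", "bidirectional"],
    )
    mutations["vaf_obs"] = mutations["alt_reads"] / mutations["depth"]
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "region_class", "tcn", "ascn"]
    )
    clinical = pd.DataFrame(
        clin_rows,
        columns=["patient_id", "diagnosis", "ipssr_score", "os_months", "os_event",
                 "hma_treated", "hma_response"],
    )
    clinical["risk_group"] = np.where(clinical["ipssr_score"] <= 3.5, "low", "high")
    cohort = CohortTable(mutations=mutations, clinical=clinical, cn_segments=segments)
    truth = GroundTruth(
        clones=pd.DataFrame(truth_clone_rows,
                            columns=["patient_id", "clone_idx", "prevalence"]),
        mutations=pd.DataFrame(
            truth_mut_rows,
            columns=["patient_id", "mut_id", "gene", "clone_idx", "label",
                     "prevalence", "branch", "expected_vaf"],
        ),
        patients=pd.DataFrame(
            truth_pat_rows,
            columns=["patient_id", "n_clones", "mdsmpn", "high_risk", "ch_class"],
        ),
    )
    return cohort, truth


def expected_vaf_sanity(truth: GroundTruth, cohort: CohortTable,
                        tol: float = 0.05) -> pd.DataFrame:
    """Per-clone check that mean observed VAF tracks the expected VAF.

    Returns one row per (patient, clone) with the deviation and an ``ok``
    flag; raises if the two tables do not describe the same cohort.
    """
    tm = truth.mutations
    if set(tm["patient_id"]) - set(cohort.mutations["patient_id"]):
        raise ValidationError("ground truth references patients absent from cohort")
    muts = cohort.mutations.copy()
    muts["mut_id"] = (
        muts["patient_id"] + ":" + muts["chrom"].astype(str) + ":" + muts["pos"].astype(str)
    )
    merged = tm.merge(muts[["mut_id", "vaf_obs"]], on="mut_id", validate="one_to_one")
    rows = []
    for (pid, ic), grp in merged.groupby(["patient_id", "clone_idx"]):
        dev = float(abs(grp["vaf_obs"].mean() - grp["expected_vaf"].mean()))
        rows.append((pid, ic, len(grp), grp["expected_vaf"].mean(),
                     grp["vaf_obs"].mean(), dev, dev <= tol))
    return pd.DataFrame(rows, columns=["patient_id", "clone_idx", "n_mutations",
                                       "expected_vaf", "mean_vaf_obs", "deviation", "ok"])


def write_cohort(cohort: CohortTable, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write the three cohort TSVs plus ground_truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    cohort.cn_segments.to_csv(out / "segments.seg", sep="\t", index=False)
    truth.mutations.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
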