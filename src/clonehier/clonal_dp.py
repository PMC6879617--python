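"""Dirichlet-process Beta-Binomial clustering of mutations into clones.

Model
-----
For one patient, each mutation ``n`` has alt-read count ``a_n`` out of
depth ``d_n``.  Mutations are assigned to clusters by a Dirichlet process
(concentration 1) whose base measure is Beta(1, 1) over cellular
prevalence φ.  The emission is an overdispersed binomial::

    a_n ~ BetaBinomial(d_n, mean ξ_n, precision s)
    ξ_n = clip(vaf_expected(φ_{z_n}, cn_n, branch_n), ε, 1 − ε)
    s   ~ Gamma(shape 1.0, rate 0.001)

where ``vaf_expected`` maps a prevalence to the VAF implied by the
mutation's copy-number branch (φ/2 for neutral loci) and ε is the
sequencing error rate (0.001).  Inference is MCMC: collapsed assignment
updates with auxiliary components (Neal's algorithm 8), random-walk
Metropolis for each cluster's φ, and a log-scale Metropolis step for s.
Defaults are 10,000 iterations with a burn-in of 1,000.

Consensus and labels
--------------------
Post-burn-in assignment samples form a posterior co-assignment matrix;
average-linkage hierarchical clustering on its complement is cut at the
number of clusters maximizing the posterior expected adjusted Rand (PEAR)
criterion.  The cluster with the highest posterior mean prevalence is the
dominant (ancestral) clone; all other clusters are secondary.  Mutations
withheld from the sampler (indels, repetitive regions) are labeled post
hoc by nearest prevalence.

The public surface follows the Model/Results convention:
``ClonalModel(data).fit(config)`` returns a :class:`ClonalResults` with the
trace, the consensus architecture, and a ``summary()`` table.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

from clonehier.cohort_model import ValidationError

_BRANCH_AFFINE = {
    # ξ(φ) = c0 + c1·φ per copy-number branch (see tcf_adjust.vaf_expected)
    "neutral": (0.0, 0.5),
    "upd_early": (0.0, 0.5),
    "gain": (0.0, 1.0 / 3.0),
}


@dataclass(frozen=True)
class DPConfig:
    """Sampler configuration; defaults match the reference pipeline run."""

    iterations: int = 10_000
    burn_in: int = 1_000
    concentration: float = 1.0
    base_alpha: float = 1.0
    base_beta: float = 1.0
    precision_shape: float = 1.0
    precision_rate: float = 0.001
    error_rate: float = 0.001
    thin: int = 1
    seed: int = 0
    aux_components: int = 3
    phi_step: float = 0.05
    s_step: float = 0.4
    largest_by: str = "prevalence"   # or "members"

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValidationError("burn_in must be smaller than iterations")
        for name in ("concentration", "base_alpha", "base_beta",
                     "precision_shape", "precision_rate", "error_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.largest_by not in ("prevalence", "members"):
            raise ValidationError("largest_by must be 'prevalence' or 'members'")


@dataclass
class ClusterInfo:
    index: int
    phi_mean: float
    phi_sd: float
    members: list[int]           # positions in canonical mutation order


@dataclass
class ClonalArchitecture:
    """Hard clustering of one patient's mutations with rank labels."""

    patient_id: str
    clusters: list[ClusterInfo]
    dominant_cluster: int
    labels: pd.DataFrame         # canonical order: mut columns + cluster, phi_mean, label
    phi_tied: bool = False       # top-prevalence tie observed (candidate co-dominance)

    @property
    def n_clones(self) -> int:
        return len(self.clusters)

    def iter_labeled(self):
        for row in self.labels.itertuples():
            yield row, row.label


def _canonical_order(df: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("chrom", "pos", "ref", "alt") if c in df.columns]
    if cols:
        df = df.sort_values(cols, kind="mergesort")
    return df.reset_index(drop=True)


class _Sampler:
    """MCMC state for one patient (canonical mutation order)."""

    def __init__(self, a, d, c0, c1, config: DPConfig):
        self.a = np.asarray(a, float)
        self.d = np.asarray(d, float)
        self.c0 = np.asarray(c0, float)
        self.c1 = np.asarray(c1, float)
        self.n = len(self.a)
        self.cfg = config
        self.eps = config.error_rate

    def _ll_all(self, phi: float, s: float) -> np.ndarray:
        """Beta-binomial log-likelihood of every mutation at prevalence phi."""
        xi = np.clip(self.c0 + self.c1 * phi, self.eps, 1.0 - self.eps)
        al = xi * s
        be = s - al
        return (gammaln(self.a + al) + gammaln(self.d - self.a + be)
                - gammaln(self.d + s) - gammaln(al) - gammaln(be) + gammaln(s))

    def _ll_one(self, n: int, phi, s: float):
        phi = np.atleast_1d(np.asarray(phi, float))
        xi = np.clip(self.c0[n] + self.c1[n] * phi, self.eps, 1.0 - self.eps)
        al = xi * s
        be = s - al
        return (gammaln(self.a[n] + al) + gammaln(self.d[n] - self.a[n] + be)
                - gammaln(self.d[n] + s) - gammaln(al) - gammaln(be) + gammaln(s))

    def _log_base(self, phi: float) -> float:
        cfg = self.cfg
        if cfg.base_alpha == 1.0 and cfg.base_beta == 1.0:
            return 0.0
        return float((cfg.base_alpha - 1) * np.log(phi) + (cfg.base_beta - 1) * np.log1p(-phi))

    def run(self) -> dict:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        n = self.n
        # init: one cluster per distinct rounded prevalence guess
        z = np.zeros(n, dtype=int)
        init_phi = np.clip(2.0 * self.a / self.d * 0.0 + self._init_phi(), 1e-4, 1 - 1e-4)
        phis: dict[int, float] = {}
        for i in range(n):
            z[i] = i
            phis[i] = float(init_phi[i])
        s = cfg.precision_shape / cfg.precision_rate   # prior mean
        ll_cache = {k: self._ll_all(p, s) for k, p in phis.items()}

        keep = max(1, (cfg.iterations - cfg.burn_in) // cfg.thin)
        z_trace = np.empty((keep, n), dtype=np.int32)
        phi_trace = np.empty((keep, n), dtype=np.float64)
        s_trace = np.empty(keep, dtype=np.float64)
        kept = 0

        m_aux = cfg.aux_components
        log_alpha_m = np.log(cfg.concentration / m_aux)
        for it in range(cfg.iterations):
            # --- assignments (Neal algorithm 8) ---
            for i in range(n):
                ki = z[i]
                members = np.flatnonzero(z == ki)
                singleton = members.size == 1
                counts = {}
                for k in set(z.tolist()):
                    c = int(np.sum(z == k)) - (1 if k == ki else 0)
                    if c > 0:
                        counts[k] = c
                aux_phi = rng.beta(cfg.base_alpha, cfg.base_beta, size=m_aux)
                if singleton:
                    aux_phi[0] = phis[ki]
                cand_k = list(counts)
                logw = [np.log(counts[k]) + ll_cache[k][i] for k in cand_k]
                ll_aux = self._ll_one(i, aux_phi, s)
                for j in range(m_aux):
                    logw.append(log_alpha_m + ll_aux[j])
                logw = np.asarray(logw)
                w = np.exp(logw - logw.max())
                w /= w.sum()
                pick = int(rng.choice(len(w), p=w))
                if singleton:
                    del phis[ki], ll_cache[ki]
                if pick < len(cand_k):
                    z[i] = cand_k[pick]
                else:
                    new_k = max(phis, default=-1) + 1
                    phis[new_k] = float(aux_phi[pick - len(cand_k)])
                    ll_cache[new_k] = self._ll_all(phis[new_k], s)
                    z[i] = new_k
            # --- phi updates (random-walk Metropolis) ---
            for k in list(phis):
                members = np.flatnonzero(z == k)
                if members.size == 0:       # defensive; emptied clusters were pruned
                    del phis[k], ll_cache[k]
                    continue
                phi_old = phis[k]
                phi_new = phi_old + rng.normal(0.0, cfg.phi_step)
                if not 0.0 < phi_new < 1.0:
                    continue
                ll_new = self._ll_all(phi_new, s)
                delta = (ll_new[members].sum() - ll_cache[k][members].sum()
                         + self._log_base(phi_new) - self._log_base(phi_old))
                if np.log(rng.random()) < delta:
                    phis[k] = float(phi_new)
                    ll_cache[k] = ll_new
            # --- precision update (log-scale Metropolis) ---
            s_new = float(np.exp(np.log(s) + rng.normal(0.0, cfg.s_step)))
            cur = new = 0.0
            new_cache = {}
            for k, p in phis.items():
                members = np.flatnonzero(z == k)
                cur += ll_cache[k][members].sum()
                new_cache[k] = self._ll_all(p, s_new)
                new += new_cache[k][members].sum()
            shp, rate = cfg.precision_shape, cfg.precision_rate
            delta = (new - cur
                     + (shp - 1) * (np.log(s_new) - np.log(s)) - rate * (s_new - s)
                     + np.log(s_new) - np.log(s))    # Jacobian of the log transform
            if np.log(rng.random()) < delta:
                s = s_new
                ll_cache = new_cache

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < keep:
                relabel = {}
                for i in range(n):
                    if z[i] not in relabel:
                        relabel[z[i]] = len(relabel)
                z_trace[kept] = [relabel[k] for k in z]
                phi_trace[kept] = [phis[k] for k in z]
                s_trace[kept] = s
                kept += 1
        return {
            "assignments": z_trace[:kept],
            "phi": phi_trace[:kept],
            "s": s_trace[:kept],
        }

    def _init_phi(self) -> np.ndarray:
        # invert the affine emission mean at the observed VAF
        vaf = self.a / self.d
        return np.clip((vaf - self.c0) / np.maximum(self.c1, 1e-9), 1e-4, 1 - 1e-4)


def fit_patient(adjusted: pd.DataFrame, config: DPConfig | None = None) -> dict:
    """Run the sampler for one patient's adjusted mutations; return the trace.

    ``adjusted`` needs columns ``alt_reads``, ``depth``, ``branch_used`` and
    the copy-number columns ``tcn``/``ascn``.  Rows are re-sorted into the
    canonical (chrom, pos, ref, alt) order internally; the trace columns
    follow that order.
    """
    config = config or DPConfig()
    df = _canonical_order(adjusted)
    if df.empty:
        raise ValidationError("fit_patient requires at least one mutation")
    c0 = np.empty(len(df))
    c1 = np.empty(len(df))
    for i, row in enumerate(df.itertuples()):
        branch = getattr(row, "branch_used", "neutral")
        if branch in _BRANCH_AFFINE:
            c0[i], c1[i] = _BRANCH_AFFINE[branch]
        elif branch == "deletion":
            tcn = float(getattr(row, "tcn", 1.0))
            if tcn <= 0:
                raise ValidationError("deletion branch with non-positive tcn")
            c0[i], c1[i] = 0.0, 1.0 / tcn
        elif branch == "upd_late":
            ascn = float(getattr(row, "ascn", 0.0))
            c0[i], c1[i] = (1.0 - ascn) / 2.0, 0.5
        else:
            raise ValidationError(f"unknown branch {branch!r}")
    sampler = _Sampler(df["alt_reads"].to_numpy(), df["depth"].to_numpy(), c0, c1, config)
    return sampler.run()


def _pear(indicator: np.ndarray, pi_sum: float, pi: np.ndarray) -> float:
    t = indicator.size
    sum_i = float(indicator.sum())
    sum_ip = float((indicator * pi).sum())
    expected = sum_i * pi_sum / t
    denom = 0.5 * (sum_i + pi_sum) - expected
    num = sum_ip - expected
    if abs(denom) < 1e-12:
        return 1.0 if abs(num) < 1e-12 else 0.0
    return num / denom


def consensus_clusters(trace: dict) -> tuple[np.ndarray, pd.DataFrame]:
    """Consensus partition from the posterior co-assignment matrix.

    Average-linkage clustering on 1 − similarity, cut at the cluster count
    maximizing the PEAR criterion.  Returns the hard assignment vector (in
    canonical mutation order) and a per-cluster table with posterior mean
    and SD of prevalence.
    """
    zs = trace["assignments"]
    if zs.size == 0:
        raise ValidationError("empty trace")
    n = zs.shape[1]
    phi_post = trace["phi"].mean(axis=0)
    phi_sd = trace["phi"].std(axis=0)
    if n == 1:
        assign = np.zeros(1, dtype=int)
    else:
        co = np.zeros((n, n))
        for zrow in zs:
            co += zrow[:, None] == zrow[None, :]
        co /= len(zs)
        dist = squareform(1.0 - co, checks=False)
        lk = linkage(dist, method="average")
        iu = np.triu_indices(n, 1)
        pi = co[iu]
        pi_sum = float(pi.sum())
        best, assign = -np.inf, np.zeros(n, dtype=int)
        for k in range(1, n + 1):
            cand = fcluster(lk, t=k, criterion="maxclust") - 1
            score = _pear((cand[:, None] == cand[None, :])[iu].astype(float), pi_sum, pi)
            if score > best + 1e-12:
                best, assign = score, cand
    rows = []
    for k in sorted(set(assign.tolist())):
        members = np.flatnonzero(assign == k)
        rows.append((k, float(phi_post[members].mean()),
                     float(phi_sd[members].mean()), len(members)))
    table = pd.DataFrame(rows, columns=["cluster", "phi_mean", "phi_sd", "n_members"])
    return assign, table


def _merge_floor(assign: np.ndarray, table: pd.DataFrame, floor: float):
    """Merge clusters with prevalence below the floor into their nearest cluster."""
    if len(table) <= 1:
        return assign, table
    low = table[table["phi_mean"] < floor]
    if low.empty:
        return assign, table
    keep = table[table["phi_mean"] >= floor]
    if keep.empty:
        return assign, table
    assign = assign.copy()
    for row in low.itertuples():
        target = keep.iloc[(keep["phi_mean"] - row.phi_mean).abs().argmin()]["cluster"]
        assign[assign == row.cluster] = int(target)
    rows = []
    for new_idx, k in enumerate(sorted(set(assign.tolist()))):
        members = np.flatnonzero(assign == k)
        sub = table[table["cluster"] == k]
        rows.append((new_idx, float(sub["phi_mean"].iloc[0]),
                     float(sub["phi_sd"].iloc[0]), len(members)))
        assign[members] = new_idx
    return assign, pd.DataFrame(rows, columns=table.columns)


def label_dominant(
    assign: np.ndarray,
    table: pd.DataFrame,
    mutations: pd.DataFrame,
    excluded: pd.DataFrame | None = None,
    config: DPConfig | None = None,
    patient_id: str = "",
) -> ClonalArchitecture:
    """Reduce clusters to dominant/secondary labels.

    The cluster with the highest posterior mean prevalence is dominant
    (ties: more members, then smallest canonical mutation position).
    Excluded mutations are attached to the nearest cluster in TCF distance
    and inherit its label.
    """
    config = config or DPConfig()
    if table.empty:
        raise ValidationError("label_dominant requires at least one cluster")
    tb = table.copy()
    tb["first_member"] = [int(np.flatnonzero(assign == k).min()) for k in tb["cluster"]]
    if config.largest_by == "members":
        order = tb.sort_values(["n_members", "phi_mean", "first_member"],
                               ascending=[False, False, True], kind="mergesort")
    else:
        order = tb.sort_values(["phi_mean", "n_members", "first_member"],
                               ascending=[False, False, True], kind="mergesort")
    dominant = int(order.iloc[0]["cluster"])
    key = config.largest_by == "members" and "n_members" or "phi_mean"
    top = order.iloc[0][key]
    phi_tied = bool((np.abs(tb[key] - top) < 1e-9).sum() > 1)

    lab = mutations.copy()
    lab["cluster"] = assign
    lab = lab.merge(tb[["cluster", "phi_mean"]], on="cluster", how="left")
    lab["label"] = np.where(lab["cluster"] == dominant, "dominant", "secondary")
    lab["excluded_from_fit"] = False

    if excluded is not None and len(excluded):
        exc = excluded.copy()
        phis = tb["phi_mean"].to_numpy()
        nearest = [int(tb.iloc[int(np.argmin(np.abs(phis - t)))]["cluster"])
                   for t in exc["tcf"].to_numpy(float)]
        exc["cluster"] = nearest
        exc = exc.merge(tb[["cluster", "phi_mean"]], on="cluster", how="left")
        exc["label"] = np.where(exc["cluster"] == dominant, "dominant", "secondary")
        exc["excluded_from_fit"] = True
        lab = pd.concat([lab, exc], ignore_index=True)

    clusters = [
        ClusterInfo(index=int(r.cluster), phi_mean=float(r.phi_mean),
                    phi_sd=float(r.phi_sd),
                    members=np.flatnonzero(assign == r.cluster).tolist())
        for r in tb.itertuples()
    ]
    return ClonalArchitecture(
        patient_id=patient_id, clusters=clusters, dominant_cluster=dominant,
        labels=lab, phi_tied=phi_tied,
    )


class ClonalModel:
    """Per-patient clonal mixture model over adjusted mutation calls.

    Parameters
    ----------
    data : DataFrame
        One patient's mutations with ``alt_reads``, ``depth``, ``tcf``,
        ``branch_used`` (output of :func:`clonehier.tcf_adjust.adjust_table`);
        an optional boolean ``excluded`` column withholds rows (indels,
        repetitive regions) from the sampler while keeping them labeled.
    """

    def __init__(self, data: pd.DataFrame, patient_id: str | None = None):
        if data.empty:
            raise ValidationError("ClonalModel requires at least one mutation")
        self.data = _canonical_order(data)
        if patient_id is None:
            pids = self.data.get("patient_id")
            patient_id = str(pids.iloc[0]) if pids is not None else ""
        self.patient_id = patient_id

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, patient: str) -> "ClonalModel":
        sub = df[df["patient_id"] == patient]
        return cls(sub, patient_id=patient)

    def fit(self, config: DPConfig | None = None, **overrides) -> "ClonalResults":
        config = replace(config or DPConfig(), **overrides) if overrides else (config or DPConfig())
        excl_mask = (self.data["excluded"].astype(bool)
                     if "excluded" in self.data.columns
                     else pd.Series(False, index=self.data.index))
        fit_df = self.data[~excl_mask]
        excluded = self.data[excl_mask]
        if fit_df.empty:
            raise ValidationError("all mutations excluded from clustering")
        trace = fit_patient(fit_df, config)
        assign, table = consensus_clusters(trace)
        assign, table = _merge_floor(assign, table, config.error_rate)
        arch = label_dominant(assign, table, _canonical_order(fit_df), excluded,
                              config, self.patient_id)
        return ClonalResults(model=self, config=config, trace=trace,
                             architecture=arch)


@dataclass
class ClonalResults:
    """Posterior trace plus the consensus clonal architecture."""

    model: ClonalModel
    config: DPConfig
    trace: dict
    architecture: ClonalArchitecture

    @property
    def labels(self) -> pd.DataFrame:
        return self.architecture.labels

    @property
    def n_clones(self) -> int:
        return self.architecture.n_clones

    def summary(self) -> str:
        arch = self.architecture
        lines = [
            f"Clonal architecture: patient {arch.patient_id or '<unnamed>'}",
            f"  mutations: {len(arch.labels)}   clones: {arch.n_clones}"
            f"   posterior samples: {len(self.trace['s'])}",
            "  cluster   phi_mean   phi_sd   members   rank",
        ]
        for c in sorted(arch.clusters, key=lambda c: -c.phi_mean):
            rank = "dominant" if c.index == arch.dominant_cluster else "secondary"
            lines.append(f"  {c.index:7d}   {c.phi_mean:8.3f}   {c.phi_sd:6.3f}"
                         f"   {len(c.members):7d}   {rank}")
        if arch.phi_tied:
            lines.append("  note: top-prevalence tie (candidate co-dominance)")
        return "\n".join(lines)


def fit_cohort(adjusted: pd.DataFrame, config: DPConfig | None = None) -> pd.DataFrame:
    """Fit every patient in an adjusted mutation table; concatenated labels.

    Per-patient seeds are derived deterministically from ``config.seed`` and
    the patient identifier, so results do not depend on patient order.
    """
    config = config or DPConfig()
    out = []
    for pid in sorted(adjusted["patient_id"].unique()):
        sub_seed = (config.seed * 1_000_003 + zlib.crc32(str(pid).encode())) % (2**31)
        res = ClonalModel.from_dataframe(adjusted, pid).fit(replace(config, seed=sub_seed))
        out.append(res.labels.assign(n_clones=res.n_clones))
    return pd.concat(out, ignore_index=True)


def cohort_summary(labels: pd.DataFrame) -> dict:
    """Cohort-level reduction of per-patient architectures.

    Returns ``clone_histogram`` (count/fraction of patients by clone
    number), ``gene_ranks`` (per-gene dominant/secondary counts and
    fractions) and ``avaf_test`` (Mann–Whitney U comparison of adjusted
    VAF between dominant and secondary mutations).
    """
    per_patient = labels.groupby("patient_id")["n_clones"].first()
    hist = per_patient.value_counts().sort_index().rename("n_patients").reset_index()
    hist.columns = ["n_clones", "n_patients"]
    hist["fraction"] = hist["n_patients"] / len(per_patient)

    gr = (labels.groupby(["gene", "label"]).size().unstack(fill_value=0)
          .reindex(columns=["dominant", "secondary"], fill_value=0))
    gr["dominant_fraction"] = gr["dominant"] / (gr["dominant"] + gr["secondary"])
    gr = gr.reset_index()

    dom = labels.loc[labels["label"] == "dominant", "tcf"].dropna()
    sec = labels.loc[labels["label"] == "secondary", "tcf"].dropna()
    if len(dom) and len(sec):
        stat, p = mannwhitneyu(dom, sec, alternative="two-sided")
        test = {"u_statistic": float(stat), "p": float(p),
                "median_dominant": float(dom.median()),
                "median_secondary": float(sec.median())}
    else:
        test = {"u_statistic": np.nan, "p": np.nan,
                "median_dominant": float(dom.median()) if len(dom) else np.nan,
                "median_secondary": float(sec.median()) if len(sec) else np.nan}
    return {"clone_histogram": hist, "gene_ranks": gr, "avaf_test": test}
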