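"""Digital copy-number estimation from per-exon sequencing depth.

The per-exon depth of each sample is standardized to sum to a fixed
constant k0 (= 1), a panel of the m0 = 12 most correlated normal samples
supplies a per-exon reference, and the copy ratio Cn = D / D̂ is computed
on exons whose raw mean depth exceeds 500.  The ratio profile is
segmented with circular binary segmentation (CBS) and exons whose
segmented ratio deviates from the cohort per-exon mean by strictly more
than 4 standard deviations are called losses or gains.

The CBS here is a self-contained recursive implementation: the best
circular arc split maximizes the two-sample t statistic, a permutation
test (default 1,000 permutations, α = 0.01) decides whether to keep the
split, and segments narrower than 2 exons are not produced.  UPD is
invisible to depth and must come from SEG input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonehier.cohort_model import ValidationError

META_COLUMNS = ["chrom", "start", "end", "exon_id"]


@dataclass
class CBSConfig:
    alpha: float = 0.01
    n_permutations: int = 1000
    min_width: int = 2
    seed: int = 0


def standardize_depth(matrix: pd.DataFrame, k0: float = 1.0) -> pd.DataFrame:
    """Scale each sample's per-exon depth sums to total ``k0``.

    ``matrix`` has exons as rows and samples as columns (metadata columns
    excluded).  Idempotent: standardizing a standardized matrix is a
    no-op.
    """
    data = matrix[[c for c in matrix.columns if c not in META_COLUMNS]]
    sums = data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"all-zero depth for sample(s): {list(zero.index)}")
    out = data / sums * k0
    return out


def select_panel(sample: pd.Series, normals: pd.DataFrame, m0: int = 12) -> list[str]:
    """The ``m0`` normals most Pearson-correlated with ``sample``.

    Ties break deterministically by column order.
    """
    if normals.shape[1] < m0:
        raise ValidationError(f"need at least m0={m0} normals, got {normals.shape[1]}")
    s = sample.to_numpy(float)
    corrs = np.array([np.corrcoef(s, normals[c].to_numpy(float))[0, 1]
                      for c in normals.columns])
    order = np.lexsort((np.arange(len(corrs)), -corrs))
    return [normals.columns[i] for i in order[:m0]]


def copy_ratio(sample: pd.Series, panel: pd.DataFrame, raw_means: pd.Series,
               min_mean_depth: float = 500.0, recenter: bool = True) -> pd.Series:
    """Per-exon copy ratio against the panel-of-normals mean.

    Defined only on exons whose raw mean depth strictly exceeds
    ``min_mean_depth``; exons where the panel mean is zero are returned as
    NaN (flagged missing) rather than raising.

    Because every sample's standardized depths sum to the same constant, a
    real copy-number change at some exons shifts the ratio of *all* other
    exons in that sample; with ``recenter`` (default) the profile is
    divided by its median so that the copy-neutral majority sits at 1.
    """
    if panel.shape[1] == 0:
        raise ValidationError("empty panel")
    ref = panel.mean(axis=1)
    passing = raw_means > min_mean_depth
    cn = pd.Series(np.nan, index=sample.index)
    ok = passing & (ref > 0)
    cn[ok] = sample[ok] / ref[ok]
    cn = cn[passing]
    if recenter and cn.notna().any():
        med = float(cn.median())
        if med > 0:
            cn = cn / med
    return cn


def _best_circular_split(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Max two-sample t statistic over circular arcs [i, j); O(n^2)."""
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    best_t, best_i, best_j = 0.0, 0, n
    var = np.var(x)
    if var <= 0 or n < 2 * min_width:
        return 0.0, 0, n
    sd = np.sqrt(var)
    for i in range(n):
        # arc lengths m from min_width to n - min_width
        m = np.arange(min_width, n - min_width + 1)
        j = i + m
        wrap = j > n
        arc_sum = np.where(wrap, (total - cs[i]) + cs[j - n], cs[np.minimum(j, n)] - cs[i])
        mean_in = arc_sum / m
        mean_out = (total - arc_sum) / (n - m)
        t = np.abs(mean_in - mean_out) / (sd * np.sqrt(1.0 / m + 1.0 / (n - m)))
        k = int(np.argmax(t))
        if t[k] > best_t:
            best_t, best_i, best_j = float(t[k]), i, int(j[k])
    return best_t, best_i, best_j


def _segment_recursive(x: np.ndarray, offset: int, cfg: CBSConfig,
                       rng: np.random.Generator, breaks: set[int]) -> None:
    n = len(x)
    if n < 2 * cfg.min_width:
        return
    t_obs, i, j = _best_circular_split(x, cfg.min_width)
    if t_obs <= 0:
        return
    exceed = 0
    for _ in range(cfg.n_permutations):
        t_perm, _, _ = _best_circular_split(rng.permutation(x), cfg.min_width)
        if t_perm >= t_obs:
            exceed += 1
            if exceed > cfg.alpha * cfg.n_permutations:   # early stop: cannot be significant
                break
    p = exceed / cfg.n_permutations
    if p > cfg.alpha:
        return
    # arc [i, j): j may wrap past n
    if j <= n:
        cuts = [i, j]
    else:
        cuts = [j - n, i]
    cuts = [c for c in cuts if 0 < c < n]
    if not cuts:
        return
    for c in cuts:
        breaks.add(offset + c)
    pieces = np.split(x, sorted(cuts))
    starts = [0] + sorted(cuts)
    for start, piece in zip(starts, pieces):
        _segment_recursive(piece, offset + start, cfg, rng, breaks)


def segment_ratio(cn: pd.Series, config: CBSConfig | None = None) -> pd.DataFrame:
    """CBS segmentation of an ordered copy-ratio profile.

    Returns a frame indexed like ``cn`` with columns ``segment`` (integer
    id) and ``segmented`` (segment mean assigned to each exon).  NaN exons
    are dropped.  Deterministic given ``config.seed``.
    """
    config = config or CBSConfig()
    values = cn.dropna()
    if values.empty:
        raise ValidationError("empty copy-ratio profile")
    x = values.to_numpy(float)
    rng = np.random.default_rng(config.seed)
    breaks: set[int] = set()
    _segment_recursive(x, 0, config, rng, breaks)
    bounds = [0] + sorted(breaks) + [len(x)]
    seg_id = np.empty(len(x), dtype=int)
    seg_mean = np.empty(len(x))
    for k, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        seg_id[lo:hi] = k
        seg_mean[lo:hi] = x[lo:hi].mean()
    return pd.DataFrame({"segment": seg_id, "segmented": seg_mean}, index=values.index)


def call_lesions(segmented: pd.DataFrame, n_sd: float = 4.0,
                 trim: float = 0.0) -> pd.DataFrame:
    """Per-exon loss/gain calls from the cohort distribution of segmented Cn.

    ``segmented`` is exons × samples of segmented copy ratios.  For each
    exon the mean E and SD across samples are computed (optionally with
    symmetric trimming); a sample is called loss when its value is
    strictly below E − n_sd·SD, gain when strictly above E + n_sd·SD, else
    neutral.  Zero-SD exons are neutral unless a value differs from E, in
    which case it is flagged ``degenerate``.
    """
    if segmented.shape[1] < 3:
        raise ValidationError("need at least 3 samples to estimate the SD")
    vals = segmented.to_numpy(float)
    if trim > 0:
        lo = np.nanquantile(vals, trim, axis=1, keepdims=True)
        hi = np.nanquantile(vals, 1 - trim, axis=1, keepdims=True)
        clipped = np.clip(vals, lo, hi)
        e = np.nanmean(clipped, axis=1)
        sd = np.nanstd(clipped, axis=1)
    else:
        e = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1)
    calls = pd.DataFrame("neutral", index=segmented.index, columns=segmented.columns)
    dev = vals - e[:, None]
    with np.errstate(invalid="ignore"):
        loss = dev < -n_sd * sd[:, None]
        gain = dev > n_sd * sd[:, None]
    zero_sd = sd == 0
    degenerate = zero_sd[:, None] & (dev != 0)
    loss[zero_sd] = False
    gain[zero_sd] = False
    calls = calls.mask(loss, "loss").mask(gain, "gain").mask(degenerate, "degenerate")
    calls[np.isnan(vals)] = "missing"
    return calls


def calls_to_seg(calls: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Translate per-exon calls into SEG rows (merging adjacent same-call exons).

    loss → deletion (tcn 1, ascn 0); gain → tcn 3, ascn 1.  UPD cannot be
    detected from depth and never appears here.
    """
    state = {"loss": ("deletion", 1.0, 0.0), "gain": ("gain", 3.0, 1.0)}
    rows = []
    for sample in calls.columns:
        col = calls[sample]
        run_call, run_start, prev = None, None, None
        for exon_id in calls.index:
            call = col[exon_id]
            m = meta.loc[exon_id]
            if call in state:
                if run_call == call and prev is not None and m["chrom"] == prev["chrom"]:
                    prev = m
                    continue
                if run_call in state:
                    rc, tcn, ascn = state[run_call]
                    rows.append((sample, run_start["chrom"], int(run_start["start"]),
                                 int(prev["end"]), rc, tcn, ascn))
                run_call, run_start, prev = call, m, m
            else:
                if run_call in state:
                    rc, tcn, ascn = state[run_call]
                    rows.append((sample, run_start["chrom"], int(run_start["start"]),
                                 int(prev["end"]), rc, tcn, ascn))
                run_call, run_start, prev = None, None, None
        if run_call in state:
            rc, tcn, ascn = state[run_call]
            rows.append((sample, run_start["chrom"], int(run_start["start"]),
                         int(prev["end"]), rc, tcn, ascn))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "region_class", "tcn", "ascn"])


def run_depth_pipeline(matrix: pd.DataFrame, normal_ids: list[str],
                       m0: int = 12, min_mean_depth: float = 500.0,
                       cbs: CBSConfig | None = None, n_sd: float = 4.0) -> dict:
    """Full digital copy-number pipeline over a depth matrix.

    ``matrix`` carries the metadata columns plus one column per sample;
    ``normal_ids`` names the panel-of-normals candidates.  Returns the
    standardized matrix, per-sample segmented profiles, per-exon calls,
    and SEG rows.
    """
    cbs = cbs or CBSConfig()
    meta = matrix[META_COLUMNS].copy()
    meta.index = matrix.index
    std = standardize_depth(matrix)
    sample_ids = [c for c in std.columns]
    raw_means = matrix[sample_ids].mean(axis=1)
    normals = std[normal_ids]
    segmented = {}
    for s in sample_ids:
        pool = normals[[c for c in normal_ids if c != s]]
        panel_ids = select_panel(std[s], pool, m0)
        cn = copy_ratio(std[s], std[panel_ids], raw_means, min_mean_depth)
        seg = segment_ratio(cn, CBSConfig(alpha=cbs.alpha, n_permutations=cbs.n_permutations,
                                          min_width=cbs.min_width,
                                          seed=cbs.seed + hash_sample(s)))
        segmented[s] = seg["segmented"]
    seg_df = pd.DataFrame(segmented)
    calls = call_lesions(seg_df, n_sd=n_sd)
    seg_rows = calls_to_seg(calls, meta)
    return {"standardized": std, "segmented": seg_df, "calls": calls, "seg": seg_rows}


def hash_sample(name: str) -> int:
    import zlib
    return zlib.crc32(str(name).encode()) % 100_000
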