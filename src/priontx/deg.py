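"""Differential-expression calling and the DEG pattern taxonomy.

The DEG decision rule is the classical bulk RNA-seq one: a gene is
differentially expressed in a contrast when its Benjamini-Hochberg
adjusted p-value falls below ``alpha_adj`` (default 0.001) and
|log2 fold change| exceeds ``lfc_cut`` (default 1, i.e. two-fold).

The test engine is a self-contained negative-binomial likelihood-ratio
test: per-gene means are fitted by maximum likelihood with sample size
factors as offsets, under a null model (one common mean) and an
alternative (one mean per condition), using a moderated per-gene
dispersion (method-of-moments estimates shrunk 70% toward their mean,
floored at 1e-4). The deviance is referred to chi-square with 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, DEGCall, GeneRecord, CONTRASTS

PATTERNS = [
    ("up", "up"),
    ("down", "down"),
    ("up", "unchanged"),
    ("down", "unchanged"),
    ("unchanged", "up"),
    ("unchanged", "down"),
    ("up", "down"),
    ("down", "up"),
]

_CONTRAST_GROUPS = {
    "prion_vs_wt": ("prion", "wt"),
    "deletion_vs_wt": ("deletion", "wt"),
    "prion_vs_deletion": ("prion", "deletion"),
}


@dataclass(frozen=True)
class ThresholdConfig:
    """DEG cutoffs: adjusted p < alpha_adj and |log2FC| > lfc_cut."""

    alpha_adj: float = 0.001
    lfc_cut: float = 1.0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha_adj < 1:
            raise ValueError("alpha_adj must be in (0, 1)")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be >= 0")


def estimate_depth(n_reads: float, read_length: float, genome_length: float) -> float:
    """Fold genome coverage of a sequencing run: N x L / G."""
    if n_reads <= 0 or read_length <= 0 or genome_length <= 0:
        raise ValueError("n_reads, read_length and genome_length must be positive")
    return n_reads * read_length / genome_length


def normalize_counts(cm: CountMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-gene geometric mean over genes with positive
    counts in every sample; each sample's size factor is the median ratio
    of its counts to that reference. If no gene is positive everywhere the
    estimator is undefined and we fall back to total-count scaling.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        log_ref = np.log(counts[all_positive]).mean(axis=1)
        log_ratios = np.log(counts[all_positive]) - log_ref[:, None]
        factors = np.exp(np.median(log_ratios, axis=0))
    else:
        warnings.warn(
            "no gene with positive counts in every sample; "
            "falling back to total-count size factors"
        )
        totals = counts.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    sf = pd.Series(factors, index=cm.samples, name="size_factor")
    normed = cm.counts / sf
    return sf, normed


def _fit_group_mean(y: np.ndarray, s: np.ndarray, r: np.ndarray, n_iter: int = 40) -> np.ndarray:
    """Vectorized per-gene MLE of the NB mean parameter q (mu_i = s_i * q)
    with fixed NB size r = 1/phi, by damped Newton on log q.

    y: genes x samples counts, s: samples size factors, r: per-gene size.
    """
    q = y.sum(axis=1) / s.sum()
    q = np.maximum(q, 1e-8)
    t = np.log(q)
    for _ in range(n_iter):
        q = np.exp(t)
        mu = s[None, :] * q[:, None]
        denom = r[:, None] + mu
        # d loglik / d t  (t = log q)
        grad = (y - (y + r[:, None]) * mu / denom).sum(axis=1)
        # expected negative second derivative (Fisher information in t)
        info = (r[:, None] * mu / denom).sum(axis=1)
        step = grad / np.maximum(info, 1e-12)
        t = t + np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.maximum(np.exp(t), 1e-12)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    rr = r[:, None]
    from scipy.special import gammaln

    ll = (
        gammaln(y + rr)
        - gammaln(rr)
        - gammaln(y + 1)
        + rr * np.log(rr / (rr + mu))
        + y * np.log(mu / (rr + mu))
    )
    return ll.sum(axis=1)


def moderated_dispersion(
    normed: pd.DataFrame, groups: Sequence[Sequence[str]], shrink: float = 0.7, floor: float = 1e-4
) -> np.ndarray:
    """Per-gene NB dispersion phi: method-of-moments on normalized counts
    pooled across groups, shrunk ``shrink`` of the way toward the mean
    estimate and floored."""
    num = np.zeros(len(normed))
    den = np.zeros(len(normed))
    for cols in groups:
        x = normed[list(cols)].to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        ok = m > 0
        num[ok] += v[ok] - m[ok]
        den[ok] += m[ok] ** 2
    phi_hat = np.where(den > 0, np.maximum(num, 0.0) / np.maximum(den, 1e-12), 0.0)
    phi_bar = phi_hat.mean() if len(phi_hat) else 0.0
    phi = (1.0 - shrink) * phi_hat + shrink * phi_bar
    return np.maximum(phi, floor)


def call_degs(
    cm: CountMatrix,
    contrast: str,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> list[DEGCall]:
    """Call DEGs for one contrast with the NB likelihood-ratio test.

    Genes with all-zero counts in both groups are excluded from testing
    and returned with direction "unchanged" and NaN p-values.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    cond_a, cond_b = _CONTRAST_GROUPS[contrast]
    samples_a = cm.samples_for(cond_a)
    samples_b = cm.samples_for(cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"contrast {contrast} needs >=2 replicates per condition "
            f"(got {len(samples_a)} {cond_a}, {len(samples_b)} {cond_b})"
        )
    sub = cm.subset_samples(samples_a + samples_b)
    sf, normed = normalize_counts(sub)

    y = sub.counts.to_numpy(dtype=float)
    tested = y.sum(axis=1) > 0
    phi = moderated_dispersion(normed, [samples_a, samples_b])
    r = 1.0 / phi

    idx_a = [sub.samples.index(s) for s in samples_a]
    idx_b = [sub.samples.index(s) for s in samples_b]
    s_all = sf.to_numpy()
    s_a, s_b = s_all[idx_a], s_all[idx_b]
    y_a, y_b = y[:, idx_a], y[:, idx_b]

    yt, rt = y[tested], r[tested]
    q_null = _fit_group_mean(yt, s_all, rt)
    q_a = _fit_group_mean(y_a[tested], s_a, rt)
    q_b = _fit_group_mean(y_b[tested], s_b, rt)
    ll_null = _nb_loglik(yt, s_all[None, :] * q_null[:, None], rt)
    ll_alt = _nb_loglik(y_a[tested], s_a[None, :] * q_a[:, None], rt) + _nb_loglik(
        y_b[tested], s_b[None, :] * q_b[:, None], rt
    )
    dev = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p_raw = stats.chi2.sf(dev, df=1)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    mean_a = normed[samples_a].mean(axis=1).to_numpy()
    mean_b = normed[samples_b].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_a + cfg.pseudocount) / (mean_b + cfg.pseudocount))

    calls: list[DEGCall] = []
    pos = {gi: ti for ti, gi in enumerate(np.flatnonzero(tested))}
    for gi, gene in enumerate(sub.genes):
        if gi not in pos:
            calls.append(DEGCall(gene, contrast, 0.0, float("nan"), float("nan"), "unchanged"))
            continue
        ti = pos[gi]
        pr, pa, lfc = float(p_raw[ti]), float(p_adj[ti]), float(log2fc[gi])
        if pa < cfg.alpha_adj and lfc > cfg.lfc_cut:
            direction = "up"
        elif pa < cfg.alpha_adj and lfc < -cfg.lfc_cut:
            direction = "down"
        else:
            direction = "unchanged"
        calls.append(DEGCall(gene, contrast, lfc, pr, pa, direction))
    return calls


def calls_to_frame(calls: Sequence[DEGCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "contrast": [c.contrast for c in calls],
            "log2fc": [c.log2fc for c in calls],
            "p_raw": [c.p_raw for c in calls],
            "p_adj": [c.p_adj for c in calls],
            "direction": [c.direction for c in calls],
        }
    ).set_index("gene_id")


def direction_map(calls: Sequence[DEGCall]) -> dict[str, str]:
    return {c.gene_id: c.direction for c in calls}


def deg_sets(calls: Sequence[DEGCall]) -> dict[str, set[str]]:
    """Up / down / all DEG id sets from a call list."""
    up = {c.gene_id for c in calls if c.direction == "up"}
    down = {c.gene_id for c in calls if c.direction == "down"}
    return {"up": up, "down": down, "all": up | down}


# ---------------------------------------------------------------------------
# replicate-outlier screening

def sample_outlier_screen(
    cm: CountMatrix, n_top: int = 500, threshold: float = 2.0
) -> tuple[dict[str, bool], pd.DataFrame]:
    """Flag replicate outliers by distance in log-expression space.

    Computes log2(normalized + 0.5) over the ``n_top`` most variable
    genes, embeds samples by classical multidimensional scaling of
    Euclidean distances (returned for inspection), and flags a replicate
    when its distance to its condition centroid exceeds ``threshold``
    times the median within-condition replicate distance. At most one
    replicate per condition is flagged; if the rule would flag more, only
    the farthest stays flagged and a warning is issued.

    Returns (keep flags per sample, 2-D embedding DataFrame).
    """
    if len(cm.samples) < 3:
        raise ValueError("outlier screening needs at least 3 samples")
    conditions = {c for c in cm.condition_of.values()}
    for cond in conditions:
        if len(cm.samples_for(cond)) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
    _, normed = normalize_counts(cm)
    logx = np.log2(normed.to_numpy(dtype=float) + 0.5)
    variances = logx.var(axis=1)
    top = np.argsort(variances)[::-1][: min(n_top, len(variances))]
    x = logx[top].T  # samples x genes

    # classical MDS (principal coordinates) on Euclidean distances
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    embedding = pd.DataFrame(coords, index=cm.samples, columns=["MDS1", "MDS2"])

    dist_to_centroid: dict[str, float] = {}
    for cond in conditions:
        cols = [cm.samples.index(s) for s in cm.samples_for(cond)]
        centroid = x[cols].mean(axis=0)
        for ci in cols:
            dist_to_centroid[cm.samples[ci]] = float(
                np.linalg.norm(x[ci] - centroid)
            )
    med = float(np.median(list(dist_to_centroid.values())))
    flagged = {s for s, d in dist_to_centroid.items() if d > threshold * med}
    for cond in conditions:
        cond_flagged = [s for s in cm.samples_for(cond) if s in flagged]
        if len(cond_flagged) > 1:
            cond_flagged.sort(key=lambda s: dist_to_centroid[s])
            keep_anyway = cond_flagged[:-1]
            warnings.warn(
                f"condition {cond!r}: rule flagged {len(cond_flagged)} replicates; "
                f"keeping all but the farthest ({cond_flagged[-1]})"
            )
            flagged -= set(keep_anyway)
    keep = {s: s not in flagged for s in cm.samples}
    return keep, embedding


# ---------------------------------------------------------------------------
# pattern taxonomy and overlap arithmetic

def classify_patterns(
    prion_calls: Sequence[DEGCall], deletion_calls: Sequence[DEGCall]
) -> tuple[dict[str, tuple[str, str]], dict[tuple[str, str], int]]:
    """Assign each gene that is a DEG in at least one of the two contrasts
    to one of the 8 joint (prion, deletion) direction patterns."""
    dp = direction_map(prion_calls)
    dd = direction_map(deletion_calls)
    if set(dp) != set(dd):
        only = set(dp) ^ set(dd)
        raise ValueError(f"gene universes differ between call lists: {sorted(only)[:5]}")
    assignments: dict[str, tuple[str, str]] = {}
    counts = {p: 0 for p in PATTERNS}
    for gene in dp:
        pattern = (dp[gene], dd[gene])
        if pattern == ("unchanged", "unchanged"):
            continue
        assignments[gene] = pattern
        counts[pattern] += 1
    return assignments, counts


def summarize_overlap(deg_set_a: set[str], deg_set_b: set[str]) -> dict[str, float]:
    """Set arithmetic between two DEG lists: sizes, intersection, union
    (inclusion-exclusion), and the shared fraction of each list in
    percent (one decimal for display)."""
    inter = deg_set_a & deg_set_b
    union = len(deg_set_a) + len(deg_set_b) - len(inter)
    out = {
        "n_a": len(deg_set_a),
        "n_b": len(deg_set_b),
        "n_intersection": len(inter),
        "n_union": union,
        "pct_of_b": round(100.0 * len(inter) / len(deg_set_b), 1) if deg_set_b else 0.0,
        "pct_of_a": round(100.0 * len(inter) / len(deg_set_a), 1) if deg_set_a else 0.0,
    }
    return out


def feature_breakdown(
    assignments: dict[str, tuple[str, str]], annotation: Sequence[GeneRecord]
) -> pd.DataFrame:
    """Contingency table of pattern x feature_class counts."""
    fclass = {r.gene_id: r.feature_class for r in annotation}
    missing = [g for g in assignments if g not in fclass]
    if missing:
        raise ValueError(f"unannotated genes: {sorted(missing)[:10]}")
    rows = pd.DataFrame(
        {
            "pattern": [f"{p[0]}/{p[1]}" for p in assignments.values()],
            "feature_class": [fclass[g] for g in assignments],
        }
    )
    table = pd.crosstab(rows["pattern"], rows["feature_class"])
    return table
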