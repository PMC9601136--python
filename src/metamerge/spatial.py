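"""Covariation analysis incorporating bivariate spatial relevance.

Gene clusters get one expression profile per (individual, site) sample;
pairs of profiles are scored with Lee's bivariate spatial association
statistic L over a site-adjacency weight matrix that is block-diagonal
across individuals.  Known clusters (COG-grouped, with KEGG reaction
labels) provide an ROC benchmark — positives are cluster pairs sharing a
reaction — from which an L threshold is chosen to keep the empirical false
positive rate under a target.  Unknown clusters linked to known ones above
that threshold inherit the known clusters' function labels, and label
enrichment is tested with Fisher's exact test under Benjamini-Hochberg
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import logger
from .types import ParameterError


@dataclass
class SpatialWeights:
    samples: list[tuple[str, str]]
    V: np.ndarray  # n x n row-standardized, block-diagonal across individuals

    @property
    def n(self) -> int:
        return len(self.samples)


def build_weights(
    site_order: dict[str, tuple[str, ...]], include_self: bool = True
) -> SpatialWeights:
    """Chain-adjacency weights over ordered sites, per individual.

    Within an individual, v_ij = 1 for chain-adjacent sites (and for i == j
    when ``include_self``); weights are zero across individuals; rows are
    standardized to sum to 1.
    """
    samples = [
        (ind, s) for ind in sorted(site_order) for s in site_order[ind]
    ]
    n = len(samples)
    V = np.zeros((n, n))
    pos = {s: i for i, s in enumerate(samples)}
    for ind in sorted(site_order):
        sites = site_order[ind]
        for i, site in enumerate(sites):
            row = pos[(ind, site)]
            if include_self:
                V[row, row] = 1.0
            if i > 0:
                V[row, pos[(ind, sites[i - 1])]] = 1.0
            if i < len(sites) - 1:
                V[row, pos[(ind, sites[i + 1])]] = 1.0
    sums = V.sum(axis=1)
    if (sums == 0).any():
        raise ParameterError("weight matrix has an all-zero row")
    V = V / sums[:, None]
    return SpatialWeights(samples=samples, V=V)


def lee_L(x: np.ndarray, y: np.ndarray, W: SpatialWeights | np.ndarray) -> float:
    """Lee's bivariate spatial association statistic.

    L = [n / sum_i (sum_j v_ij)^2] *
        sum_i (sum_j v_ij (x_j - xbar)) (sum_j v_ij (y_j - ybar))
        / (||x - xbar|| * ||y - ybar||)

    With V = I this reduces to the Pearson correlation of x and y.  L is
    symmetric in (x, y) and invariant to positive affine transforms of
    either argument.  Constant vectors are undefined (ValueError).
    """
    V = W.V if isinstance(W, SpatialWeights) else np.asarray(W, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if V.shape != (n, n) or len(y) != n:
        raise ParameterError("dimension mismatch between x, y and V")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("Lee's L undefined for a constant vector")
    row_sums = V.sum(axis=1)
    pref = n / float((row_sums**2).sum())
    return float(pref * ((V @ xc) * (V @ yc)).sum() / (nx * ny))


# ---------------------------------------------------------------------------
# cluster profiles


def cluster_profiles(
    clusters,
    expression: pd.DataFrame,
    weights: SpatialWeights,
    agg: str = "sum",
    log_transform: bool = True,
) -> dict[str, np.ndarray]:
    """One expression vector per cluster, ordered by the weights' samples.

    Member-gene expression is summed (or averaged) per sample, then
    log2(1 + value) transformed.  Clusters with masked (NaN) or constant
    profiles are excluded and logged.
    """
    out: dict[str, np.ndarray] = {}
    cols = [c for c in weights.samples]
    for cl in clusters:
        members = [g for g in cl.members if g in expression.index]
        if not members:
            continue
        sub = expression.loc[members, cols]
        vec = sub.sum(axis=0) if agg == "sum" else sub.mean(axis=0)
        vec = vec.to_numpy(dtype=float)
        if np.isnan(vec).any():
            logger.info("cluster %s excluded: masked entries", cl.cluster_id)
            continue
        if log_transform:
            vec = np.log2(1.0 + vec)
        if np.allclose(vec, vec[0]):
            logger.info("cluster %s excluded: constant profile", cl.cluster_id)
            continue
        out[cl.cluster_id] = vec
    return out


# ---------------------------------------------------------------------------
# ROC benchmark and threshold selection


@dataclass
class BenchmarkResult:
    roc: list[tuple[float, float, float]]  # (threshold, FPR, sensitivity)
    auc: float
    theta: float
    achieved_fpr: float
    achieved_sensitivity: float
    n_positive_pairs: int = 0
    n_negative_pairs: int = 0


def roc_curve_from_scores(
    scores: np.ndarray, labels: np.ndarray
) -> list[tuple[float, float, float]]:
    """ROC points (threshold, FPR, sensitivity), prediction: score >= t."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    P = int(lab.sum())
    N = len(lab) - P
    points = []
    tp = fp = 0
    i = 0
    while i < len(s):
        t = s[i]
        while i < len(s) and s[i] == t:
            tp += int(lab[i])
            fp += int(not lab[i])
            i += 1
        points.append((float(t), fp / N, tp / P))
    return points


def auc_trapezoid(roc: list[tuple[float, float, float]]) -> float:
    fprs = [0.0] + [p[1] for p in roc]
    sens = [0.0] + [p[2] for p in roc]
    if fprs[-1] != 1.0 or sens[-1] != 1.0:
        fprs.append(1.0)
        sens.append(1.0)
    return float(np.trapezoid(sens, fprs))


def select_threshold(
    roc: list[tuple[float, float, float]], target_fpr: float
) -> tuple[float, float, float]:
    """Smallest threshold whose empirical FPR <= target (ties -> larger L)."""
    best = None
    for t, fpr, sens in roc:  # thresholds descend; FPR ascends
        if fpr <= target_fpr:
            best = (t, fpr, sens)
        else:
            break
    if best is None:
        return (np.inf, 0.0, 0.0)
    return best


def benchmark_known(
    known_profiles: dict[str, np.ndarray],
    cluster_reactions: dict[str, frozenset[str] | set[str]],
    W: SpatialWeights,
    target_fpr: float = 0.05,
) -> BenchmarkResult:
    """ROC of Lee's L over known-cluster pairs; truth = shared reaction.

    Pairs are unordered and exclude self-pairs; clusters without reaction
    labels are excluded from the truth set entirely (not treated as
    negatives).  AUC is the trapezoid over (FPR, sensitivity); the selected
    threshold is the smallest L whose empirical FPR is <= ``target_fpr``.
    """
    ids = sorted(
        c for c in known_profiles if cluster_reactions.get(c)
    )
    scores, labels = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            scores.append(lee_L(known_profiles[a], known_profiles[b], W))
            labels.append(bool(cluster_reactions[a] & cluster_reactions[b]))
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("benchmark undefined: need both positive and negative pairs")
    roc = roc_curve_from_scores(scores, labels)
    auc = auc_trapezoid(roc)
    theta, fpr, sens = select_threshold(roc, target_fpr)
    return BenchmarkResult(
        roc=roc,
        auc=auc,
        theta=theta,
        achieved_fpr=fpr,
        achieved_sensitivity=sens,
        n_positive_pairs=n_pos,
        n_negative_pairs=n_neg,
    )


# ---------------------------------------------------------------------------
# label transfer and enrichment


@dataclass
class TransferResult:
    links: list[tuple[str, str, float]]  # (unknown, known, L)
    predicted_labels: dict[str, set[str]]  # unknown cluster -> labels
    gene_predictions: dict[str, set[str]] = field(default_factory=dict)
    theta: float = np.nan

    @property
    def n_annotated_genes(self) -> int:
        return sum(1 for labels in self.gene_predictions.values() if labels)


def transfer_functions(
    unknown_profiles: dict[str, np.ndarray],
    known_profiles: dict[str, np.ndarray],
    known_labels: dict[str, set[str]],
    W: SpatialWeights,
    theta: float,
    unknown_members: dict[str, list[str]] | None = None,
) -> TransferResult:
    """Link unknown clusters to known clusters with L >= theta.

    Each linked unknown cluster's predicted function set is the union of its
    linked known clusters' labels; member genes inherit the cluster's set.
    """
    links = []
    predicted: dict[str, set[str]] = {}
    for u in sorted(unknown_profiles):
        for kcl in sorted(known_profiles):
            L = lee_L(unknown_profiles[u], known_profiles[kcl], W)
            if L >= theta:
                links.append((u, kcl, L))
                predicted.setdefault(u, set()).update(known_labels.get(kcl, set()))
    gene_predictions: dict[str, set[str]] = {}
    if unknown_members:
        for u, labels in predicted.items():
            for g in unknown_members.get(u, []):
                gene_predictions[g] = set(labels)
    return TransferResult(
        links=links,
        predicted_labels=predicted,
        gene_predictions=gene_predictions,
        theta=theta,
    )


@dataclass
class EnrichmentRow:
    category: str
    unknown_with: int
    unknown_without: int
    known_with: int
    known_without: int
    odds_ratio: float
    p_value: float
    p_adjusted: float = np.nan
    enriched: bool = False


def enrich_functions(
    transfer: TransferResult,
    known_labels: dict[str, set[str]],
    alpha: float = 0.01,
) -> list[EnrichmentRow]:
    """Per-category Fisher's exact test, unknown-linked vs known clusters.

    Two-sided p values are Benjamini-Hochberg adjusted across categories;
    a category is enriched iff its adjusted p < ``alpha``.  Categories
    absent from both groups are skipped.
    """
    unknown_sets = list(transfer.predicted_labels.values())
    known_sets = [known_labels[k] for k in sorted(known_labels)]
    cats = sorted(set().union(*unknown_sets, *known_sets) if (unknown_sets or known_sets) else set())
    rows = []
    for cat in cats:
        a = sum(1 for s in unknown_sets if cat in s)
        c = len(unknown_sets) - a
        b = sum(1 for s in known_sets if cat in s)
        d = len(known_sets) - b
        if a + b == 0:
            continue
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            EnrichmentRow(
                category=cat,
                unknown_with=a,
                unknown_without=c,
                known_with=b,
                known_without=d,
                odds_ratio=float(odds),
                p_value=float(p),
            )
        )
    if rows:
        _rej, padj, _a, _b2 = multipletests(
            [r.p_value for r in rows], alpha=alpha, method="fdr_bh"
        )
        for r, pa in zip(rows, padj):
            r.p_adjusted = float(pa)
            r.enriched = pa < alpha
    return rows
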