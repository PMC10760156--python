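"""Pathway activity scoring, pre-ranked GSEA and pathway-overlap networks.

Three complementary readouts of pathway engagement:

* :func:`mlm_activity` — footprint-style activities: each nucleus's
  expression vector is regressed jointly on all pathway weight columns
  (signed gene weights, PROGENy-style) plus an intercept; the activity of a
  pathway is the t-value of its coefficient.
* :func:`gsea_preranked` — the classic weighted Kolmogorov-Smirnov running
  sum on a ranked gene list, with gene-label permutation for normalized
  enrichment scores (NES), p-values and the permutation-pool FDR.
* :func:`weight_lfc_concordance` — per-gene concordance between pathway
  weights and differential-expression log fold changes (the weight-vs-logFC
  scatter classification).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

CONSISTENT_UP = "consistent_up"
CONSISTENT_DOWN = "consistent_down"
DISCORDANT = "discordant"
NEUTRAL = "discordant_neutral"


def mlm_activity(
    expression: np.ndarray | pd.DataFrame,
    weights: pd.DataFrame,
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Multivariate linear-model pathway activities (t-values).

    ``expression`` is nuclei x genes (a single row is accepted); ``weights``
    is genes x pathways with signed real weights. Genes are aligned by the
    weight table's index when ``expression`` is a DataFrame; otherwise
    columns are assumed aligned. Collinear weight columns fall back to a
    ridge-regularized fit with a logged penalty.
    """
    W = weights.to_numpy(dtype=float)
    if not np.any(W != 0, axis=0).all():
        raise ValueError("every pathway needs at least one nonzero weight")
    if isinstance(expression, pd.DataFrame):
        Y = expression.reindex(columns=weights.index).to_numpy(dtype=float)
        obs_index = expression.index
    else:
        Y = np.atleast_2d(np.asarray(expression, dtype=float))
        obs_index = pd.RangeIndex(len(Y))
    g, p = W.shape
    if Y.shape[1] != g:
        raise ValueError("expression columns do not match weight-table genes")
    X = np.column_stack([np.ones(g), W])
    XtX = X.T @ X
    cond = np.linalg.cond(XtX)
    if cond > 1e10:
        warnings.warn(f"collinear weight columns; ridge fallback lambda={ridge}")
        XtX = XtX + ridge * np.eye(p + 1)
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X.T @ Y.T  # (p+1) x n_obs
    resid = Y.T - X @ beta
    dof = g - (p + 1)
    if dof <= 0:
        raise ValueError("need more genes than pathways + intercept")
    sigma2 = (resid**2).sum(axis=0) / dof
    # exact fits leave numerically-zero residuals; floor the variance so
    # t-values of genuinely-zero coefficients stay at zero instead of 0/0
    floor = (1e-8 * max(float(np.abs(Y).max()), 1.0)) ** 2
    sigma2 = np.maximum(sigma2, floor)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return pd.DataFrame(t[1:].T, index=obs_index, columns=weights.columns)


def weight_lfc_concordance(
    de: pd.DataFrame, weights: pd.Series
) -> pd.DataFrame:
    """Classify genes by agreement between pathway weight and DE logFC.

    ``consistent_up``: weight and logFC both positive (the gene moved with
    pathway activation); ``consistent_down``: both negative; ``discordant``:
    opposite signs; zero weight or zero logFC is ``discordant_neutral``.
    Genes absent from the weight table are omitted.
    """
    common = de.index.intersection(weights.index)
    w = weights.loc[common].to_numpy(dtype=float)
    lfc = de.loc[common, "lfc"].to_numpy(dtype=float)
    cls = np.full(len(common), DISCORDANT, dtype=object)
    cls[(w > 0) & (lfc > 0)] = CONSISTENT_UP
    cls[(w < 0) & (lfc < 0)] = CONSISTENT_DOWN
    cls[(w == 0) | (lfc == 0)] = NEUTRAL
    return pd.DataFrame(
        {"weight": w, "lfc": lfc, "concordance": cls}, index=common
    )


# ---------------------------------------------------------------------------
# pre-ranked GSEA


def enrichment_score(
    scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score for one set on one ranked list.

    ``scores`` must already be sorted in ranking order (descending);
    ``hit_mask`` marks set members at their rank positions. Hits increment
    the running sum by ``|score|^p`` (normalized by the set total), misses
    decrement by ``1/(N - n_set)``. Returns the signed extremum and the full
    running sum.
    """
    scores = np.asarray(scores, dtype=float)
    hit = np.asarray(hit_mask, dtype=bool)
    N = len(scores)
    n_set = int(hit.sum())
    if n_set == 0 or n_set == N:
        raise ValueError("gene set must be a proper nonempty subset of the ranking")
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores are 0: fall back to equal weights
        hit_w = hit.astype(float)
        total = float(n_set)
    running = np.cumsum(hit_w / total - (~hit) / (N - n_set))
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _es_many(scores_sorted: np.ndarray, positions: np.ndarray,
             weight_exponent: float) -> np.ndarray:
    """ES for many sets given their (perm x n_set) rank positions."""
    N = len(scores_sorted)
    w = np.abs(scores_sorted) ** weight_exponent
    pos = np.sort(positions, axis=1)
    n_set = pos.shape[1]
    miss = 1.0 / (N - n_set)
    hw = w[pos]
    totals = hw.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        hw[zero] = 1.0
        totals[zero] = n_set
    cum = np.cumsum(hw, axis=1) / totals[:, None]
    k = np.arange(1, n_set + 1)
    # running sum just after hit k, and just before hit k
    after = cum - (pos + 1 - k) * miss
    before = np.concatenate(
        [np.zeros((len(pos), 1)), cum[:, :-1]], axis=1
    ) - (pos - (k - 1)) * miss
    cand = np.concatenate([after, before], axis=1)
    return np.take_along_axis(
        cand, np.argmax(np.abs(cand), axis=1)[:, None], axis=1
    ).ravel()


@dataclass
class GseaResult:
    table: pd.DataFrame  # per set: es, nes, pval, fdr, size
    null_nes: np.ndarray


def gsea_preranked(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a collection of gene sets.

    ``ranking`` maps gene -> score (e.g. a signed DE t-statistic); genes are
    ranked by descending score. Null distributions come from gene-label
    permutation: for each set size, random same-size sets drawn from the
    ranking. NES = ES divided by the mean |ES| of same-sign permutations;
    p is the same-sign permutation tail; FDR follows the permutation-pool
    procedure (pooled null NES vs observed NES). Returns a frame with
    columns ``es, nes, pval, fdr, size``.
    """
    if not np.isfinite(ranking.to_numpy(dtype=float)).all():
        raise ValueError("ranking scores must be finite")
    order = np.argsort(-ranking.to_numpy(dtype=float), kind="stable")
    genes = ranking.index.to_numpy()[order]
    scores = ranking.to_numpy(dtype=float)[order]
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    rng = np.random.default_rng(seed)

    rows = {}
    null_by_set = {}
    for name, members in gene_sets.items():
        pos = np.array(sorted({gene_pos[g] for g in members if g in gene_pos}))
        if len(pos) == 0 or len(pos) >= N:
            raise ValueError(f"gene set {name!r} empty or spans the whole ranking")
        hit = np.zeros(N, dtype=bool)
        hit[pos] = True
        es, _ = enrichment_score(scores, hit, weight_exponent)
        perm_pos = np.argsort(
            rng.random((n_perm, N)), axis=1
        )[:, : len(pos)]
        null = _es_many(scores, perm_pos, weight_exponent)
        same = null >= 0 if es >= 0 else null < 0
        n_same = max(int(same.sum()), 1)
        pval = float((np.abs(null[same]) >= abs(es)).sum()) / n_same
        denom = float(np.abs(null[same]).mean()) if same.any() else np.nan
        nes = es / denom if denom and denom > 0 else 0.0
        null_nes = np.zeros_like(null)
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else 1.0
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else 1.0
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        rows[name] = {"es": es, "nes": nes, "pval": pval, "size": len(pos)}
        null_by_set[name] = null_nes

    table = pd.DataFrame.from_dict(rows, orient="index")
    pooled = np.concatenate(list(null_by_set.values()))
    obs = table["nes"].to_numpy()
    fdr = np.ones(len(obs))
    for i, nes in enumerate(obs):
        if nes >= 0:
            num_pool = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            num_obs = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
        else:
            num_pool = (pooled <= nes).sum() / max((pooled < 0).sum(), 1)
            num_obs = (obs <= nes).sum() / max((obs < 0).sum(), 1)
        fdr[i] = min(num_pool / num_obs, 1.0) if num_obs > 0 else 1.0
    table["fdr"] = fdr
    return table


def bh_fdr_from_permutation(table: pd.DataFrame) -> pd.Series:
    """Alternative FDR: Benjamini-Hochberg over the permutation p-values."""
    from statsmodels.stats.multitest import multipletests

    return pd.Series(
        multipletests(table["pval"].to_numpy(), method="fdr_bh")[1],
        index=table.index,
        name="fdr_bh",
    )


def nes_heatmap_table(
    results: dict[str, pd.DataFrame],
    fdr_threshold: float = 0.01,
    min_contrasts: int = 2,
) -> pd.DataFrame:
    """Pathway x contrast NES matrix, filtered to reproducible pathways.

    A pathway is retained when its FDR is below ``fdr_threshold`` in at
    least ``min_contrasts`` of the contrasts.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 contrasts")
    nes = pd.DataFrame({c: t["nes"] for c, t in results.items()})
    fdr = pd.DataFrame({c: t["fdr"] for c, t in results.items()})
    keep = (fdr < fdr_threshold).sum(axis=1) >= min_contrasts
    return nes[keep]


def pathway_overlap_network(
    gene_sets: dict[str, list[str]],
    edge_threshold: float = 0.0,
) -> tuple[nx.Graph, dict[str, int]]:
    """Graph of pathways weighted by Jaccard overlap of member genes.

    Edges at or below ``edge_threshold`` are dropped; communities come from
    greedy modularity maximization. Returns the graph and a pathway ->
    community-id map.
    """
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 gene sets")
    names = list(gene_sets)
    members = {n: set(gene_sets[n]) for n in names}
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            union = members[a] | members[b]
            if not union:
                continue
            j = len(members[a] & members[b]) / len(union)
            if j > edge_threshold:
                g.add_edge(a, b, weight=j)
    comms = nx.algorithms.community.greedy_modularity_communities(g, weight="weight")
    labels = {n: i for i, c in enumerate(comms) for n in c}
    return g, labels
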