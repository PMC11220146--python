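"""Preranked gene-set enrichment against the pathomics score.

Genes are ranked by their Spearman correlation with the per-patient
pathomics score.  The enrichment score (ES) of a gene set is the signed
extremum of the weighted Kolmogorov-Smirnov running sum over the ranked
list: hits increment by |metric|^p normalized over the set's hits, misses
decrement by 1/(N - N_hit).  Significance comes from gene-set (tag)
permutation: random same-size sets drawn from the ranked universe give the
null ES distribution; NES divides ES by the mean |null ES| of matching
sign, the nominal p is the same-sign tail fraction, and the FDR q follows
the sign-stratified pooled-null NES convention.  A phenotype-permutation
mode (re-ranking against permuted scores) is available at higher cost.

Also provided: Spearman correlations (with BH adjustment) of curated gene
lists against the score, and rank-sum comparison of externally supplied
immune-cell fraction tables between high- and low-score groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
SIGNIFICANCE_P = 0.05
SIGNIFICANCE_FDR = 0.25


@dataclass
class GeneSet:
    name: str
    description: str
    members: list

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def read_gmt(path) -> list:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], parts[2:]))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def _spearman_vs_score(expr: pd.DataFrame, ps: pd.Series) -> pd.Series:
    """Vectorized per-gene Spearman rho against the score."""
    shared = expr.columns.intersection(ps.index)
    X = expr[shared].to_numpy(dtype=float)
    rx = np.apply_along_axis(stats.rankdata, 1, X)
    ry = stats.rankdata(ps[shared].to_numpy(dtype=float))
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
    const = ~np.isfinite(rho)
    if const.any():
        logger.info("%d constant gene rows: rho set to 0", const.sum())
        rho[const] = 0.0
    return pd.Series(rho, index=expr.index)


def rank_genes(expression: pd.DataFrame, ps: pd.Series,
               method: str = "spearman") -> pd.DataFrame:
    """Rank genes by Spearman correlation with the pathomics score.

    ``expression`` is genes x patients; ``ps`` indexed by patient id.
    Duplicate gene symbols keep the highest-variance row.  Returns a
    DataFrame (gene, metric), metric descending, ties by gene symbol.
    """
    if method != "spearman":
        raise ValueError("only the spearman ranking metric is implemented")
    expr = pd.DataFrame(expression)
    ps = pd.Series(ps)
    shared = expr.columns.intersection(ps.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 patients shared between expression and scores")
    if expr.index.duplicated().any():
        variances = expr[shared].var(axis=1)
        order = np.argsort(-variances.to_numpy(), kind="mergesort")
        dedup = expr.iloc[order]
        dup = dedup.index.duplicated()
        logger.info("dropping %d duplicate gene symbols (kept highest variance)",
                    int(dup.sum()))
        expr = dedup[~dup]
    rho = _spearman_vs_score(expr[shared], ps[shared])
    out = pd.DataFrame({"gene": rho.index, "metric": rho.to_numpy()})
    out = out.sort_values(["metric", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return out


def gsea_es(ranked: pd.DataFrame, gene_set: GeneSet, p: float = 1.0) -> tuple:
    """Weighted KS enrichment score of one set against a ranked list.

    Returns (ES, running-sum vector over list positions).  ES is the
    running-sum value of largest absolute magnitude (signed).
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set.members))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the list")
    n = len(genes)
    weights = np.abs(metric) ** p
    w_hit = np.where(hit, weights, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        w_hit = hit.astype(float)
        denom = n_hit
    if n_hit == n:
        running = np.cumsum(w_hit / denom)
        return float(running.max()), running
    step = w_hit / denom - (~hit) / (n - n_hit)
    running = np.cumsum(step)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int) -> float:
    """ES from sorted hit positions only (fast path for permutations).

    The running sum rises at hit positions and falls linearly between, so
    its signed extremum is attained either just after a hit or just before
    one.
    """
    k = len(pos)
    w = weights[pos]
    total = w.sum()
    cw = np.cumsum(w) / total if total > 0 else np.arange(1, k + 1) / k
    miss = 1.0 / (n - k)
    misses_before = (pos - np.arange(k)) * miss   # misses strictly before hit i
    at_hit = cw - misses_before                    # just after hit i
    before_hit = np.concatenate(([0.0], cw[:-1])) - misses_before
    cands = np.concatenate([at_hit, before_hit])
    return float(cands[np.argmax(np.abs(cands))])


@dataclass
class GSEAResult:
    set_name: str
    size: int
    es: float
    nes: float
    p: float
    fdr: float
    n_perm: int
    seed: int


def gsea_permutation(ranked: pd.DataFrame, sets, n_perm: int = DEFAULT_N_PERM,
                     seed: int = 0, p: float = 1.0,
                     expression: pd.DataFrame | None = None,
                     ps: pd.Series | None = None,
                     scheme: str = "geneset") -> pd.DataFrame:
    """Permutation significance for preranked GSEA.

    scheme="geneset" (default): null ES from random same-size gene sets
    drawn from the ranked universe.  scheme="phenotype": null ES from
    re-ranking genes against permuted scores (requires ``expression`` and
    ``ps``; slower).

    NES = ES / mean |null ES| of matching sign; nominal p = fraction of
    same-sign null with |ES_null| >= |ES|; FDR q by the sign-stratified
    pooled-null NES procedure.  Returns a tidy DataFrame
    (set, size, ES, NES, p, q, significant).
    """
    rng = np.random.default_rng(seed)
    sets = sorted(sets, key=lambda s: s.name)  # order-invariant output
    genes = ranked["gene"].to_numpy()
    n = len(genes)
    usable, results = [], []
    for s in sets:
        overlap = int(np.isin(genes, list(s.members)).sum())
        if overlap == 0:
            logger.info("set %s skipped: no overlap", s.name)
            continue
        usable.append((s, overlap))

    null_es: dict = {}
    if scheme == "geneset":
        weights = np.abs(ranked["metric"].to_numpy(dtype=float)) ** p
        sizes = sorted({k for _, k in usable})
        for k in sizes:
            if k == n:
                null_es[k] = np.ones(n_perm)
                continue
            es_null = np.empty(n_perm)
            for b in range(n_perm):
                pos = np.sort(rng.choice(n, size=k, replace=False))
                es_null[b] = _es_from_positions(pos, weights, n)
            null_es[k] = es_null
    elif scheme == "phenotype":
        if expression is None or ps is None:
            raise ValueError("phenotype permutation needs expression and ps")
        perm_ranked = []
        for b in range(n_perm):
            perm = pd.Series(rng.permutation(ps.to_numpy()), index=ps.index)
            perm_ranked.append(rank_genes(expression, perm))
        for s, k in usable:
            null_es[s.name] = np.array(
                [gsea_es(r, s, p=p)[0] for r in perm_ranked])
    else:
        raise ValueError("scheme must be 'geneset' or 'phenotype'")

    obs = []
    pooled_null_nes = []
    for s, k in usable:
        es, _ = gsea_es(ranked, s, p=p)
        nulls = null_es[k if scheme == "geneset" else s.name]
        pos_null = nulls[nulls > 0]
        neg_null = nulls[nulls < 0]
        mean_pos = np.abs(pos_null).mean() if len(pos_null) else np.nan
        mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan
        # normalized null NES of this set, pooled across sets for the FDR
        normed = []
        if len(pos_null):
            normed.append(pos_null / mean_pos)
        if len(neg_null):
            normed.append(neg_null / mean_neg)
        if normed:
            pooled_null_nes.append(np.concatenate(normed))
        if es >= 0:
            same = pos_null
            nes = es / mean_pos if np.isfinite(mean_pos) else 0.0
        else:
            same = neg_null
            nes = es / mean_neg if np.isfinite(mean_neg) else 0.0
        pval = float(np.mean(np.abs(same) >= abs(es))) if len(same) else 1.0
        obs.append({"set": s.name, "size": k, "ES": es, "NES": float(nes),
                    "p": pval})

    # sign-stratified pooled-null FDR on NES
    pooled = (np.concatenate(pooled_null_nes)
              if pooled_null_nes else np.array([]))
    obs_nes = np.array([o["NES"] for o in obs])
    for o in obs:
        nes = o["NES"]
        if len(pooled) == 0:
            o["q"] = 1.0
            continue
        if nes >= 0:
            n_side = max(np.sum(pooled >= 0), 1)
            tail_null = np.sum(pooled >= nes) / n_side
            o_side = max(np.sum(obs_nes >= 0), 1)
            tail_obs = np.sum(obs_nes >= nes) / o_side
        else:
            n_side = max(np.sum(pooled <= 0), 1)
            tail_null = np.sum(pooled <= nes) / n_side
            o_side = max(np.sum(obs_nes <= 0), 1)
            tail_obs = np.sum(obs_nes <= nes) / o_side
        o["q"] = float(min(1.0, tail_null / max(tail_obs, 1e-300)))
    for o in obs:
        o["significant"] = (o["p"] < SIGNIFICANCE_P) and (o["q"] < SIGNIFICANCE_FDR)
    return pd.DataFrame(obs)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple:
    """Spearman rho with exact permutation p for tiny samples."""
    from itertools import permutations

    rho_obs = stats.spearmanr(x, y).statistic
    ry = stats.rankdata(y)
    count, total = 0, 0
    for perm in permutations(stats.rankdata(x)):
        r = np.corrcoef(perm, ry)[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return float(rho_obs), count / total


def genelist_correlations(ps: pd.Series, expression: pd.DataFrame,
                          genes: list) -> pd.DataFrame:
    """Spearman rho of each listed gene with the score, BH-adjusted.

    Genes missing from the expression matrix are logged and skipped.
    Exact permutation p-values are used when n <= 8 patients.
    """
    ps = pd.Series(ps)
    expr = pd.DataFrame(expression)
    shared = expr.columns.intersection(ps.index)
    rows = []
    for g in genes:
        if g not in expr.index:
            logger.info("gene %s missing from expression matrix; skipped", g)
            continue
        x = expr.loc[g, shared].to_numpy(dtype=float)
        y = ps[shared].to_numpy(dtype=float)
        if len(shared) <= 8:
            rho, pval = _spearman_exact_p(x, y)
        else:
            res = stats.spearmanr(x, y)
            rho, pval = float(res.statistic), float(res.pvalue)
        rows.append({"gene": g, "rho": rho, "p": pval})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def compare_fractions(fractions: pd.DataFrame, groups,
                      atol: float = 1e-6) -> pd.DataFrame:
    """Rank-sum comparison of immune-cell fractions between score groups.

    ``fractions`` is patients x cell types with rows summing to 1 (the
    deconvolution itself is supplied externally); ``groups`` is a binary
    high/low label per patient.  All-zero cell types are skipped.  Returns
    per-cell-type (statistic, p, BH-adjusted p).
    """
    frac = pd.DataFrame(fractions)
    if ((frac < 0) | (frac > 1)).any().any():
        raise ValueError("fractions must lie in [0, 1]")
    sums = frac.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValueError("fraction rows must sum to 1")
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("groups must be binary high/low")
    rows = []
    for ct in frac.columns:
        v = frac[ct].to_numpy(dtype=float)
        if np.all(v == 0):
            logger.info("cell type %s all zeros; skipped", ct)
            continue
        a, b = v[g == levels[1]], v[g == levels[0]]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, pval = float(len(a) * len(b) / 2), 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, pval = float(res.statistic), float(res.pvalue)
        rows.append({"cell_type": ct, "statistic": stat, "p": pval})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
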