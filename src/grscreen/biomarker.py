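"""Correlation-based transcriptome biomarker discovery.

Given baseline expression (genes x lines, log2 CPM or TPM) and a per-line
drug-response metric (normalized AOC), this module provides:

* genewise Pearson correlation with the response, p-values from the exact
  t transform with n - 2 degrees of freedom;
* positive / negative correlated gene signatures (PCGS / NCGS) at a raw
  p-value cutoff (default 0.01; a Benjamini-Hochberg column is emitted for
  transparency but does not gate membership);
* preranked gene-set enrichment via the weighted Kolmogorov-Smirnov running
  sum with gene-permutation NES and p;
* single-marker ROC classification (rank-based AUC, Mann-Whitney p, Youden
  cutoff);
* an exhaustive depth-<=2 Gini decision tree over (gene, threshold) splits;
* first-order partial correlation networks around a seed gene;
* per-patient fraction-of-positive-cells Spearman correlation for
  single-cell validation of a marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "genewise_correlation",
    "CorrelationSignature",
    "build_signatures",
    "EnrichmentResult",
    "preranked_enrichment",
    "RocResult",
    "roc_single_marker",
    "DecisionNode",
    "decision_tree_biomarker",
    "partial_correlation",
    "fraction_positive_correlation",
]


# ---------------------------------------------------------------------------
# genewise correlation and signatures
# ---------------------------------------------------------------------------

def genewise_correlation(expr: pd.DataFrame, aoc_by_line: dict) -> pd.DataFrame:
    """Pearson correlation of every gene's expression with the response.

    ``expr`` is genes x samples; sample ids are matched against
    ``aoc_by_line`` keys and at least 4 shared samples are required.
    Returns a DataFrame indexed by gene with columns ``r``, ``p``,
    ``p_bh`` (Benjamini-Hochberg adjusted, informational) and
    ``zero_variance``.  Zero-variance genes carry NaN r/p and the flag.
    """
    shared = [s for s in expr.columns if s in aoc_by_line]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, found {len(shared)}")
    x = expr[shared].to_numpy(dtype=float)
    y = np.array([aoc_by_line[s] for s in shared], dtype=float)
    n = y.size

    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    sx = np.sqrt((xm**2).sum(axis=1))
    sy = np.sqrt((ym**2).sum())
    zero_var = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xm @ ym) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[zero_var] = np.nan

    # exact t transform: t = r * sqrt((n-2) / (1 - r^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[zero_var] = np.nan

    p_bh = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        p_bh[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"r": r, "p": p, "p_bh": p_bh, "zero_variance": zero_var},
        index=expr.index,
    )


@dataclass
class CorrelationSignature:
    """Positive / negative correlated gene signatures at a p cutoff."""

    pcgs: list
    ncgs: list
    cutoff: float
    table: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_positive(self) -> int:
        return len(self.pcgs)

    @property
    def n_negative(self) -> int:
        return len(self.ncgs)


def build_signatures(cors: pd.DataFrame, cutoff: float = 0.01) -> CorrelationSignature:
    """Split significantly correlated genes into PCGS (r > 0) and NCGS (r < 0)."""
    ok = cors["p"].notna() & (cors["p"] < cutoff)
    pcgs = sorted(cors.index[ok & (cors["r"] > 0)])
    ncgs = sorted(cors.index[ok & (cors["r"] < 0)])
    return CorrelationSignature(pcgs=pcgs, ncgs=ncgs, cutoff=cutoff, table=cors)


# ---------------------------------------------------------------------------
# preranked enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    p: float
    n_perm: int
    seed: int


def _running_sum_es(order_stats: np.ndarray, member: np.ndarray) -> float:
    """Weighted KS enrichment score for one membership vector.

    ``order_stats`` are the ranking statistics sorted descending; ``member``
    marks set membership in the same order.  Hit increments are weighted by
    |stat| (weight exponent 1); the ES is the running-sum extremum.
    """
    w = np.abs(order_stats) * member
    denom_hit = w.sum()
    if denom_hit == 0:  # all-zero weights inside the set: fall back to equal
        w = member.astype(float)
        denom_hit = w.sum()
    n_miss = (~member.astype(bool)).sum()
    if n_miss == 0:
        return 0.0
    step = w / denom_hit - (~member.astype(bool)) / n_miss
    run = np.cumsum(step)
    return float(run[np.argmax(np.abs(run))])


def preranked_enrichment(
    ranked_stats: pd.Series, gene_set, n_perm: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Preranked GSEA with gene-permutation normalization.

    ``ranked_stats`` maps gene -> ranking statistic (any real value; genes
    are sorted by it descending).  The null distribution permutes set
    membership over genes; NES = ES / mean |ES| of same-sign null scores and
    p is the same-sign permutation fraction with a +1 continuity floor.
    """
    genes = ranked_stats.index.to_numpy()
    gene_set = list(gene_set)
    if len(gene_set) < 3:
        raise ValueError("gene set must contain at least 3 genes")
    missing = set(gene_set) - set(genes)
    if missing:
        raise ValueError(f"gene set members absent from ranking: {sorted(missing)[:5]}")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")

    order = np.argsort(-ranked_stats.to_numpy(), kind="mergesort")
    sorted_stats = ranked_stats.to_numpy()[order]
    sorted_genes = genes[order]
    member = np.isin(sorted_genes, gene_set)
    es = _running_sum_es(sorted_stats, member)

    rng = np.random.default_rng(seed)
    k = member.sum()
    null = np.empty(n_perm)
    idx = np.arange(sorted_genes.size)
    for i in range(n_perm):
        perm = np.zeros(sorted_genes.size, dtype=bool)
        perm[rng.choice(idx, size=k, replace=False)] = True
        null[i] = _running_sum_es(sorted_stats, perm)

    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size == 0:
        nes = 0.0
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same))
        p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
    return EnrichmentResult(es=es, nes=float(nes), p=float(p), n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# single-marker ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    p: float
    cutoff: float
    sensitivity: float  # percent, at the reported cutoff
    specificity: float  # percent


def roc_single_marker(values, labels) -> RocResult:
    """ROC analysis of one continuous marker against a binary response.

    AUC uses the rank (Mann-Whitney) construction with the convention that
    higher marker values indicate the positive class (label 1).  The p-value
    is the two-sided Mann-Whitney test (exact when both classes have <= 10
    samples, normal approximation otherwise).  The reported cutoff maximizes
    Youden's J over midpoints between consecutive sorted values, predicting
    positive when value >= cutoff; ties go to the cutoff with higher
    specificity.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(values)
    u = ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2.0
    auc = u / (pos.size * neg.size)

    method = "exact" if (pos.size <= 10 and neg.size <= 10) else "asymptotic"
    p = float(
        stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method).pvalue
    )

    svals = np.sort(np.unique(values))
    mids = (svals[:-1] + svals[1:]) / 2.0
    candidates = np.concatenate(([svals[0] - 1.0], mids, [svals[-1] + 1.0]))
    best = None
    for c in candidates:
        pred = values >= c
        sens = (pred & (labels == 1)).sum() / pos.size
        spec = (~pred & (labels == 0)).sum() / neg.size
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (j, sens, spec, c)
    _, sens, spec, cutoff = best
    return RocResult(
        auc=float(auc),
        p=p,
        cutoff=float(cutoff),
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
    )


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

@dataclass
class DecisionNode:
    """One node of the threshold tree; leaves carry a label only."""

    label: str | None = None
    gene: str | None = None
    threshold: float | None = None
    left: "DecisionNode | None" = None  # gene value <= threshold
    right: "DecisionNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.gene is None

    def predict_one(self, sample: pd.Series) -> str:
        node = self
        while not node.is_leaf:
            node = node.left if sample[node.gene] <= node.threshold else node.right
        return node.label


def _gini(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return 1.0 - (p**2).sum()


def _majority(labels: np.ndarray) -> str:
    vals, counts = np.unique(labels, return_counts=True)
    return str(vals[np.argmax(counts)])  # np.unique sorts -> deterministic tie-break


def _best_split(x: pd.DataFrame, labels: np.ndarray, genes):
    """Exhaustive (gene, midpoint-threshold) search minimizing weighted Gini."""
    best = None
    n = labels.size
    for gene in genes:
        vals = x.loc[gene].to_numpy(dtype=float)
        svals = np.sort(np.unique(vals))
        if svals.size < 2:
            continue
        for thr in (svals[:-1] + svals[1:]) / 2.0:
            left = vals <= thr
            imp = (
                left.sum() / n * _gini(labels[left])
                + (~left).sum() / n * _gini(labels[~left])
            )
            if best is None or imp < best[0] - 1e-12:
                best = (imp, gene, float(thr), left)
    return best


def _grow(x, labels, genes, depth, max_depth):
    if np.unique(labels).size == 1 or depth >= max_depth:
        return DecisionNode(label=_majority(labels))
    split = _best_split(x, labels, genes)
    if split is None or split[0] >= _gini(labels) - 1e-12:
        return DecisionNode(label=_majority(labels))
    _, gene, thr, left = split
    return DecisionNode(
        gene=gene,
        threshold=thr,
        left=_grow(x.loc[:, left], labels[left], genes, depth + 1, max_depth),
        right=_grow(x.loc[:, ~left], labels[~left], genes, depth + 1, max_depth),
    )


def decision_tree_biomarker(
    expr: pd.DataFrame, groups: pd.DataFrame, candidate_genes=None, max_depth: int = 2
):
    """Shallow threshold tree separating the response groups.

    ``groups`` is the classification table (``line_id``, ``group``).  Splits
    are searched exhaustively over genes and midpoints between consecutive
    observed expression values, minimizing weighted Gini impurity.  Returns
    (root node, training confusion matrix as DataFrame).
    """
    labels_by_line = groups.set_index("line_id")["group"]
    samples = [s for s in expr.columns if s in labels_by_line.index]
    if len(np.unique(labels_by_line[samples])) < 2:
        raise ValueError("need at least 2 response groups")
    x = expr[samples]
    labels = labels_by_line[samples].to_numpy()
    genes = list(candidate_genes) if candidate_genes is not None else list(expr.index)
    root = _grow(x, labels, genes, 0, max_depth)

    pred = np.array([root.predict_one(x[s]) for s in samples])
    cats = sorted(np.unique(np.concatenate([labels, pred])))
    conf = pd.DataFrame(0, index=cats, columns=cats)
    for t, pr in zip(labels, pred):
        conf.loc[t, pr] += 1
    return root, conf


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def partial_correlation(expr: pd.DataFrame, seed_gene: str, partners) -> pd.DataFrame:
    """First-order partial correlation network around a seed gene.

    For every partner y, computes r_xy.z for each control gene z among the
    remaining partners via

        r_xy.z = (r_xy - r_xz * r_zy) / sqrt((1 - r_xz^2) (1 - r_zy^2))

    and reports the minimum-magnitude partial correlation as the edge
    weight (the most conservative single-control estimate).  Collinear
    controls (|r| = 1 denominators) flag the edge undefined.
    """
    partners = [p for p in partners if p != seed_gene]
    if expr.shape[1] < 5:
        raise ValueError("need at least 5 samples")
    sub = expr.loc[[seed_gene] + partners]
    r = np.corrcoef(sub.to_numpy(dtype=float))
    names = [seed_gene] + partners
    idx = {g: i for i, g in enumerate(names)}
    rows = []
    for y in partners:
        iy = idx[y]
        r_xy = r[0, iy]
        controls = [z for z in partners if z != y]
        if not controls:
            rows.append(
                {"seed": seed_gene, "partner": y, "partial_r": r_xy,
                 "control": "", "undefined": False, "sign": int(np.sign(r_xy))}
            )
            continue
        best = None
        undefined = True
        for z in controls:
            iz = idx[z]
            r_xz, r_zy = r[0, iz], r[iz, iy]
            denom = (1 - r_xz**2) * (1 - r_zy**2)
            if denom <= 1e-12:
                continue
            pr = (r_xy - r_xz * r_zy) / np.sqrt(denom)
            undefined = False
            if best is None or abs(pr) < abs(best[0]):
                best = (pr, z)
        if undefined:
            rows.append(
                {"seed": seed_gene, "partner": y, "partial_r": np.nan,
                 "control": "", "undefined": True, "sign": 0}
            )
        else:
            rows.append(
                {"seed": seed_gene, "partner": y, "partial_r": float(best[0]),
                 "control": best[1], "undefined": False,
                 "sign": int(np.sign(best[0]))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-cell fraction-positive correlation
# ---------------------------------------------------------------------------

def fraction_positive_correlation(
    counts: pd.DataFrame, patients: pd.Series, gene_a: str, gene_b: str
):
    """Spearman correlation of per-patient positive-cell fractions.

    ``counts`` is genes x cells; ``patients`` maps cell id -> patient id.
    A cell is positive for a gene when its count exceeds 0.  Patients with
    zero cells are impossible by construction here, but the grouping drops
    empty groups anyway.  Requires >= 5 patients.  Returns (rho, p).
    """
    cells = [c for c in counts.columns if c in patients.index]
    pat = patients[cells]
    if pat.nunique() < 5:
        raise ValueError("need at least 5 patients")
    fa = (counts.loc[gene_a, cells] > 0).groupby(pat).mean()
    fb = (counts.loc[gene_b, cells] > 0).groupby(pat).mean()
    res = stats.spearmanr(fa.to_numpy(), fb.to_numpy())
    return float(res.statistic), float(res.pvalue)
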