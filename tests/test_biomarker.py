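"""Biomarker discovery: correlations, signatures, enrichment, ROC, trees."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from grscreen import biomarker as bm
from grscreen import datagen

AOC = {"s1": 0.1, "s2": 0.3, "s3": 0.5, "s4": 0.7, "s5": 0.9}


def _expr(rows):
    return pd.DataFrame(rows, columns=list(AOC))


# --- genewise correlation -----------------------------------------------------

def test_correlation_exact_signs():
    vec = np.array(list(AOC.values()))
    expr = _expr({"up": vec, "down": -vec, "flat": np.full(5, 3.0)})
    expr = expr.T if expr.shape[0] != 3 else expr
    expr = pd.DataFrame(
        [vec, -vec, np.full(5, 3.0)], index=["up", "down", "flat"], columns=list(AOC)
    )
    out = bm.genewise_correlation(expr, AOC)
    assert out.loc["up", "r"] == pytest.approx(1.0)
    assert out.loc["down", "r"] == pytest.approx(-1.0)
    assert bool(out.loc["flat", "zero_variance"])
    assert np.isnan(out.loc["flat", "r"])


def test_correlation_matches_scipy_oracle(rng):
    expr = pd.DataFrame(
        rng.normal(size=(20, 5)),
        index=[f"g{i}" for i in range(20)],
        columns=list(AOC),
    )
    out = bm.genewise_correlation(expr, AOC)
    for g in expr.index:
        r, p = stats.pearsonr(expr.loc[g], list(AOC.values()))
        assert out.loc[g, "r"] == pytest.approx(r, abs=1e-10)
        assert out.loc[g, "p"] == pytest.approx(p, abs=1e-10)


def test_correlation_requires_four_samples():
    expr = pd.DataFrame([[1, 2, 3]], index=["g"], columns=["s1", "s2", "s3"])
    with pytest.raises(ValueError):
        bm.genewise_correlation(expr, AOC)


# --- signatures ----------------------------------------------------------------

def test_signatures_recover_planted_at_zero_noise():
    expr = datagen.simulate_expression(AOC, n_genes=120, n_pos=20, n_neg=20,
                                       noise_sd=0.0, seed=4)
    cors = bm.genewise_correlation(expr, AOC)
    sig = bm.build_signatures(cors, cutoff=0.01)
    assert set(expr.attrs["planted_pos"]).issubset(sig.pcgs)
    assert set(expr.attrs["planted_neg"]).issubset(sig.ncgs)
    assert not set(sig.pcgs) & set(sig.ncgs)
    # every member satisfies its sign and p constraint per an independent oracle
    aoc = np.array([AOC[c] for c in expr.columns])
    for g in sig.pcgs:
        r, p = stats.pearsonr(expr.loc[g], aoc)
        assert r > 0 and p < 0.01
    for g in sig.ncgs:
        r, p = stats.pearsonr(expr.loc[g], aoc)
        assert r < 0 and p < 0.01


def test_signatures_empty_at_cutoff_zero():
    expr = datagen.simulate_expression(AOC, n_genes=50, n_pos=5, n_neg=5, seed=1)
    cors = bm.genewise_correlation(expr, AOC)
    sig = bm.build_signatures(cors, cutoff=0.0)
    assert sig.pcgs == [] and sig.ncgs == []


def test_signature_size_calibrated_under_null(rng):
    """Independent expression: ~1% of genes pass p<0.01 (3 SE band)."""
    n_genes, n = 10000, 10
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n)],
    )
    aoc = {f"s{i}": float(rng.uniform()) for i in range(n)}
    sig = bm.build_signatures(bm.genewise_correlation(expr, aoc), cutoff=0.01)
    frac = (sig.n_positive + sig.n_negative) / n_genes
    se = np.sqrt(0.01 * 0.99 / n_genes)
    assert abs(frac - 0.01) < 3 * se


# --- enrichment -------------------------------------------------------------------

def test_enrichment_hand_stepped_oracle():
    stats_ = pd.Series(
        [5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0],
        index=[f"g{i}" for i in range(10)],
    )
    gene_set = ["g0", "g2", "g9"]
    res = bm.preranked_enrichment(stats_, gene_set, n_perm=100, seed=0)
    # hand-stepped weighted KS running sum (weights |stat|, denom 5+3+5=13)
    steps = []
    run = 0.0
    for g, s in stats_.items():
        if g in gene_set:
            run += abs(s) / 13.0
        else:
            run -= 1.0 / 7.0
        steps.append(run)
    expected_es = steps[int(np.argmax(np.abs(steps)))]
    assert res.es == pytest.approx(expected_es, abs=1e-12)


def test_enrichment_top_k_set_maximal():
    stats_ = pd.Series(np.linspace(10, -10, 50), index=[f"g{i}" for i in range(50)])
    res = bm.preranked_enrichment(stats_, [f"g{i}" for i in range(5)], n_perm=200, seed=1)
    assert res.es > 0.8
    # at the permutation floor given same-sign null conditioning
    assert 1 / (res.n_perm + 1) <= res.p <= 0.02
    assert np.sign(res.nes) == np.sign(res.es)


def test_enrichment_random_sets_have_moderate_nes(rng):
    stats_ = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
    hits = 0
    trials = 60
    for t in range(trials):
        gs = list(rng.choice(stats_.index, size=15, replace=False))
        res = bm.preranked_enrichment(stats_, gs, n_perm=120, seed=t)
        hits += abs(res.nes) <= 1.5
    assert hits / trials >= 0.85


def test_enrichment_input_validation():
    stats_ = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    with pytest.raises(ValueError):
        bm.preranked_enrichment(stats_, ["a", "b"], n_perm=100)
    with pytest.raises(ValueError):
        bm.preranked_enrichment(stats_, ["a", "b", "zzz"], n_perm=100)
    with pytest.raises(ValueError):
        bm.preranked_enrichment(stats_, ["a", "b", "c"], n_perm=10)


# --- ROC ---------------------------------------------------------------------------

def test_roc_perfect_separation():
    values = np.array([1, 2, 3, 10, 11, 12], dtype=float)
    labels = np.array([0, 0, 0, 1, 1, 1])
    res = bm.roc_single_marker(values, labels)
    assert res.auc == 1.0
    assert res.sensitivity == 100.0
    assert res.specificity == 100.0
    assert 3 < res.cutoff <= 10


def test_roc_null_centered(rng):
    aucs = []
    for _ in range(100):
        values = rng.normal(size=30)
        labels = rng.permutation([0] * 15 + [1] * 15)
        aucs.append(bm.roc_single_marker(values, labels).auc)
    assert abs(np.mean(aucs) - 0.5) < 0.03


def test_roc_auc_matches_pair_counting(rng):
    values = rng.normal(size=17)
    labels = np.array([1] * 7 + [0] * 10)
    res = bm.roc_single_marker(values, labels)
    pos, neg = values[labels == 1], values[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert res.auc == pytest.approx(wins / (7 * 10), abs=1e-12)
    assert res.auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)


def test_roc_invariant_under_monotone_transform(rng):
    values = rng.normal(size=24)
    labels = (rng.uniform(size=24) < 0.4).astype(int)
    labels[:2] = [0, 1]  # both classes present
    base = bm.roc_single_marker(values, labels)
    trans = bm.roc_single_marker(np.exp(values / 2), labels)
    assert base.auc == pytest.approx(trans.auc, abs=1e-12)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        bm.roc_single_marker([1.0, 2.0], [1, 1])


# --- decision tree -------------------------------------------------------------------

def _groups(labels_by_sample):
    return pd.DataFrame(
        {"line_id": list(labels_by_sample), "group": list(labels_by_sample.values())}
    )


def test_tree_perfect_single_gene_split():
    expr = pd.DataFrame(
        [[1.0, 2.0, 8.0, 9.0], [5.0, 5.1, 5.2, 4.9]],
        index=["marker", "noise"],
        columns=list("abcd"),
    )
    groups = _groups({"a": "resistant", "b": "resistant", "c": "sensitive",
                      "d": "sensitive"})
    root, conf = bm.decision_tree_biomarker(expr, groups, max_depth=1)
    assert root.gene == "marker"
    assert 2.0 < root.threshold < 8.0
    assert np.trace(conf.to_numpy()) == 4  # training accuracy 1


def test_tree_recovers_planted_two_marker_structure():
    aoc = {f"s{i}": v for i, v in enumerate(np.linspace(0.05, 0.95, 9))}
    expr = datagen.simulate_expression(aoc, n_genes=30, n_pos=0, n_neg=0,
                                       noise_sd=0.0, seed=2)
    from grscreen.classify import classify_lines

    groups = classify_lines(aoc).rename(columns={})
    root, conf = bm.decision_tree_biomarker(
        expr, groups, candidate_genes=["CA12", "IGFL1"], max_depth=2
    )
    # the sentinels separate resistant (high IGFL1/CA12) from sensitive
    assert root.gene in ("CA12", "IGFL1")
    assert not root.is_leaf
    assert np.trace(conf.to_numpy()) >= 7  # near-perfect training fit


def test_tree_depth1_matches_sklearn_split():
    rng = np.random.default_rng(7)
    expr = pd.DataFrame(
        rng.normal(size=(5, 10)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(10)],
    )
    labels = ["resistant"] * 5 + ["sensitive"] * 5
    groups = _groups(dict(zip(expr.columns, labels)))
    root, _ = bm.decision_tree_biomarker(expr, groups, max_depth=1)
    sk = DecisionTreeClassifier(max_depth=1, random_state=0).fit(
        expr.T.to_numpy(), labels
    )
    assert expr.index[sk.tree_.feature[0]] == root.gene
    # sklearn computes the midpoint in float32-adjacent order; agree to 1e-6
    assert root.threshold == pytest.approx(sk.tree_.threshold[0], abs=1e-6)


def test_tree_unsplittable_returns_leaf():
    expr = pd.DataFrame([[1.0, 1.0, 1.0]], index=["g"], columns=list("abc"))
    groups = _groups({"a": "resistant", "b": "sensitive", "c": "sensitive"})
    root, _ = bm.decision_tree_biomarker(expr, groups)
    assert root.is_leaf
    assert root.label == "sensitive"


# --- partial correlation ---------------------------------------------------------------

def test_partial_correlation_matches_residual_oracle(rng):
    x = rng.normal(size=30)
    z = rng.normal(size=30)
    y = 0.6 * x + 0.5 * z + 0.3 * rng.normal(size=30)
    expr = pd.DataFrame([x, y, z], index=["seed", "y", "z"],
                        columns=[f"s{i}" for i in range(30)])
    out = bm.partial_correlation(expr, "seed", ["y", "z"]).set_index("partner")
    # oracle: correlate the regression residuals of seed~z and y~z
    def resid(a, b):
        beta = np.polyfit(b, a, 1)
        return a - np.polyval(beta, b)

    oracle = stats.pearsonr(resid(x, z), resid(y, z)).statistic
    assert out.loc["y", "partial_r"] == pytest.approx(oracle, abs=1e-10)


def test_partial_correlation_collinear_flagged():
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    z = rng.normal(size=12)
    expr = pd.DataFrame([x, z.copy(), z], index=["seed", "y", "z"],
                        columns=[f"s{i}" for i in range(12)])
    out = bm.partial_correlation(expr, "seed", ["y", "z"]).set_index("partner")
    assert bool(out.loc["y", "undefined"]) or abs(out.loc["y", "partial_r"]) < 1e-6


def test_partial_correlation_single_partner_is_marginal(rng):
    x = rng.normal(size=20)
    y = 0.5 * x + rng.normal(size=20)
    expr = pd.DataFrame([x, y], index=["seed", "y"],
                        columns=[f"s{i}" for i in range(20)])
    out = bm.partial_correlation(expr, "seed", ["y"]).set_index("partner")
    assert out.loc["y", "partial_r"] == pytest.approx(
        stats.pearsonr(x, y).statistic, abs=1e-12
    )


# --- fraction-positive correlation --------------------------------------------------------

def test_fraction_positive_perfect_link():
    counts, patients = datagen.simulate_cells(8, cells_per_patient=50,
                                              frac_positive_link=1.0, seed=5)
    rho, p = bm.fraction_positive_correlation(counts, patients, "CA12", "NFKB1")
    assert rho == pytest.approx(1.0)
    assert p < 0.01


def test_fraction_positive_matches_rank_oracle():
    counts, patients = datagen.simulate_cells(8, cells_per_patient=40,
                                              frac_positive_link=0.6, seed=9)
    rho, _ = bm.fraction_positive_correlation(counts, patients, "CA12", "RELA")
    fa = (counts.loc["CA12"] > 0).groupby(patients).mean()
    fb = (counts.loc["RELA"] > 0).groupby(patients).mean()
    oracle = stats.pearsonr(stats.rankdata(fa), stats.rankdata(fb)).statistic
    assert rho == pytest.approx(oracle, abs=1e-12)


def test_fraction_positive_requires_five_patients():
    counts, patients = datagen.simulate_cells(5, cells_per_patient=10, seed=0)
    sub = patients[patients.isin(["PT01", "PT02", "PT03"])]
    with pytest.raises(ValueError):
        bm.fraction_positive_correlation(counts[sub.index], sub, "CA12", "NFKB1")
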