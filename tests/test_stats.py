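"""Statistical primitives against independent oracles, and the pipelines."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from functree import (ContingencyTable, GeneList, StatsError, bonferroni,
                      build_tree, coverage, display_value, enrich_genelist,
                      enrich_genus, enrich_metagenome, fisher_exact,
                      rank_test, variability)
from functree.synth import (make_gene_data, make_membership, make_profiles,
                            standard_config)


# ---------------------------------------------------------------------------
# coverage

def test_coverage_fractions(tiny_tree):
    cov = coverage(tiny_tree, "P", {"K1"})
    assert (cov.ko_total, cov.ko_exp, cov.cov) == (2, 1, 0.5)
    assert coverage(tiny_tree, "P", {"K1", "K2"}).cov == 1.0
    assert coverage(tiny_tree, "P", set()).cov == 0.0


def test_coverage_unknown_function_and_observed(tiny_tree):
    with pytest.raises(Exception):
        coverage(tiny_tree, "nope", set())
    with pytest.raises(StatsError, match="K9"):
        coverage(tiny_tree, "P", {"K9"})


# ---------------------------------------------------------------------------
# rank test

def _enumeration_oracle(a, b, alternative):
    ranks = sps.rankdata(np.concatenate([a, b]))
    na, n = len(a), len(a) + len(b)
    obs = ranks[:na].sum()
    ge = le = tot = 0
    for idx in itertools.combinations(range(n), na):
        s = ranks[list(idx)].sum()
        tot += 1
        ge += s >= obs - 1e-9
        le += s <= obs + 1e-9
    if alternative == "greater":
        return ge / tot
    return min(1.0, 2.0 * min(ge / tot, le / tot))


def test_rank_test_exact_tail_probability():
    # a=[5,6,7] vs b=[1,2,3]: only 1 of the C(6,3)=20 rank splits reaches
    # the observed rank sum
    assert rank_test([5, 6, 7], [1, 2, 3], "greater") == pytest.approx(1 / 20)


@pytest.mark.parametrize("sizes", [(1, 1), (1, 8), (3, 3), (4, 6), (5, 5),
                                   (7, 4), (8, 8)])
@pytest.mark.parametrize("alternative", ["greater", "two-sided"])
def test_rank_test_matches_enumeration_with_ties(sizes, alternative):
    rng = np.random.default_rng(sum(sizes) * 7 + (alternative == "greater"))
    for _ in range(3):
        a = rng.integers(0, 4, sizes[0]).astype(float)
        b = rng.integers(0, 4, sizes[1]).astype(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        assert rank_test(a, b, alternative) == pytest.approx(
            _enumeration_oracle(a, b, alternative), abs=1e-12)


def test_rank_test_identical_groups_not_significant():
    assert rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater") >= 0.5


def test_rank_test_two_sided_is_symmetric():
    a, b = [1.0, 5.0, 9.0, 2.0], [3.0, 4.0, 8.0]
    assert rank_test(a, b, "two-sided") == pytest.approx(
        rank_test(b, a, "two-sided"))


def test_rank_test_degenerate_all_identical():
    assert rank_test([2.0] * 10, [2.0] * 30, "greater") == 1.0


def test_rank_test_asymptotic_matches_scipy():
    rng = np.random.default_rng(0)
    a, b = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
    expected = sps.mannwhitneyu(a, b, alternative="greater",
                                method="asymptotic").pvalue
    assert rank_test(a, b, "greater") == pytest.approx(float(expected))


# ---------------------------------------------------------------------------
# Fisher's exact test

def _fisher_oracle(a, b, c, d):
    """Exact-rational brute force over all margin-preserving tables."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    acc = Fraction(0)
    for x in range(a, min(r1, c1) + 1):
        acc += Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
    return float(acc)


def test_fisher_degenerate_single_table():
    assert fisher_exact(ContingencyTable(0, 0, 7, 5)) == 1.0


def test_fisher_perfect_association():
    assert fisher_exact(ContingencyTable(5, 0, 0, 5)) == pytest.approx(
        1 / 252, rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                 st.integers(0, 12), st.integers(0, 12)).filter(lambda t: sum(t) > 0))
def test_fisher_matches_oracle_and_scipy(cells):
    a, b, c, d = cells
    p = fisher_exact(ContingencyTable(a, b, c, d))
    assert p == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-12, abs=1e-300)
    scipy_p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    assert p == pytest.approx(float(scipy_p), rel=1e-9)


def test_fisher_rejects_negative_cells():
    with pytest.raises(StatsError):
        ContingencyTable(-1, 0, 0, 1)


# ---------------------------------------------------------------------------
# bonferroni and the display transform

def test_bonferroni_scales_and_caps():
    assert bonferroni({"f1": 0.01, "f2": 0.4}) == {"f1": 0.02, "f2": 0.8}
    assert bonferroni({"only": 0.3}) == {"only": 0.3}
    assert bonferroni({"a": 0.9, "b": 0.9, "c": 0.9, "d": 0.9, "e": 0.9}) == {
        k: 1.0 for k in "abcde"}


def test_display_value_examples():
    assert display_value(0.01, 1.0) == pytest.approx(2.0)
    assert display_value(0.06, 0.9) == 0.0
    assert display_value(0.001, 0.5) == pytest.approx(1.5)


def test_display_value_rejects_nonpositive_p():
    with pytest.raises(StatsError):
        display_value(0.0, 1.0)


def test_display_value_monotone_in_p_and_cov():
    ps = [0.04, 0.01, 0.001]
    vals = [display_value(p, 0.8) for p in ps]
    assert vals == sorted(vals)
    covs = [0.1, 0.5, 1.0]
    assert [display_value(0.01, c) for c in covs] == sorted(
        display_value(0.01, c) for c in covs)


# ---------------------------------------------------------------------------
# variability

def _flat_profiles(tree, rows):
    kos = sorted(tree.ko_universe)
    df = pd.DataFrame(rows, columns=kos)
    return df.div(df.sum(axis=1), axis=0)


def test_variability_constant_function_is_zero(tiny_tree):
    profiles = pd.DataFrame(
        [[0.25, 0.25, 0.5], [0.25, 0.25, 0.5]],
        columns=["K1", "K2", "K3"])
    vals = variability(tiny_tree, profiles)
    assert vals["P"] == 0.0


def test_variability_hand_computed_sigma(tiny_tree):
    # summed pathway abundance 0.2 vs 0.4 across two samples: population
    # sigma 0.1, coverage 1 -> val 0.1
    profiles = pd.DataFrame([[0.1, 0.1, 0.8], [0.2, 0.2, 0.6]],
                            columns=["K1", "K2", "K3"])
    vals = variability(tiny_tree, profiles)
    assert vals["P"] == pytest.approx(0.1)
    vals1 = variability(tiny_tree, profiles, ddof=1)
    assert vals1["P"] == pytest.approx(0.1 * math.sqrt(2))


def test_variability_requires_two_samples(tiny_tree):
    with pytest.raises(StatsError, match="2 samples"):
        variability(tiny_tree, pd.DataFrame([[0.5, 0.3, 0.2]],
                                            columns=["K1", "K2", "K3"]))


# ---------------------------------------------------------------------------
# pipelines on the standard synthetic scenario

@pytest.fixture(scope="module")
def standard_run():
    cfg = standard_config(seed=11)
    tree = build_tree(make_membership(cfg))
    return cfg, tree


def test_enrich_metagenome_recovers_planted_pathway(standard_run):
    cfg, tree = standard_run
    query, background = make_profiles(tree, cfg)
    results = enrich_metagenome(query, background, tree)
    nonko = [r for r in results if r.layer != "ko"]
    best = max(nonko, key=lambda r: r.val)
    assert best.val > 0
    assert best.function_id == "P0001"


def test_enrich_metagenome_no_enriched_kos_means_p_one(tiny_tree):
    # identical query/background: stage 1 flags nothing, stage 2 all p = 1
    rows = [[0.2, 0.3, 0.5]] * 4
    q = pd.DataFrame(rows, columns=["K1", "K2", "K3"], index=list("abcd"))
    results = enrich_metagenome(q, q.copy(), tiny_tree)
    for r in results:
        if r.layer != "ko":
            assert r.p_raw == 1.0 and r.val == 0.0


def test_enrich_metagenome_rejects_mismatched_universe(tiny_tree):
    q = pd.DataFrame([[0.5, 0.5]], columns=["K1", "K2"])
    b = pd.DataFrame([[1.0]], columns=["K1"])
    with pytest.raises(StatsError, match="universes differ"):
        enrich_metagenome(q, b, tiny_tree)


def test_enrich_genus_recovers_planted_pathway(standard_run):
    cfg, tree = standard_run
    data = make_gene_data(tree, cfg)
    results = enrich_genus(data.counts, data.focal, tree)
    nonko = [r for r in results if r.layer != "ko"]
    best = max(r.val for r in nonko)
    planted = next(r for r in nonko if r.function_id == "P0001")
    assert best > 0
    assert planted.val >= best  # ties with fully planted ancestors allowed


def test_enrich_genus_focal_must_be_strict_subset(standard_run, tiny_tree):
    counts = pd.DataFrame([[1, 0, 2], [0, 1, 1]], columns=["K1", "K2", "K3"],
                          index=["o1", "o2"])
    with pytest.raises(StatsError, match="strict subset"):
        enrich_genus(counts, {"o1", "o2"}, tiny_tree)


def test_enrich_genelist_closed_form_hypergeometric(tiny_tree):
    """Universe of 20 genes; the 5 query genes are exactly the genes of one
    function: p = 1 / C(20, 5)."""
    universe = frozenset("g%02d" % i for i in range(20))
    gene_to_ko = {"g%02d" % i: frozenset({"K1"}) for i in range(5)}
    genes = GeneList(genes=frozenset("g%02d" % i for i in range(5)),
                     organism_universe=universe, gene_to_ko=gene_to_ko)
    results = enrich_genelist(genes, tiny_tree)
    m_res = next(r for r in results if r.function_id == "M")  # M = {K1}
    assert m_res.p_raw == pytest.approx(1 / math.comb(20, 5), rel=1e-12)


def test_enrich_genelist_unmapped_function_reported_untested(tiny_tree):
    universe = frozenset({"g1", "g2"})
    genes = GeneList(genes=frozenset({"g1"}), organism_universe=universe,
                     gene_to_ko={"g1": frozenset({"K1"})})
    results = enrich_genelist(genes, tiny_tree)
    # K3's subtree has no mapped genes at all
    k3 = next(r for r in results if r.function_id == "K3")
    assert not k3.tested and k3.p_raw == 1.0 and k3.val == 0.0


def test_enrich_genelist_rejects_unknown_and_empty_lists(tiny_tree):
    with pytest.raises(Exception, match="gx"):
        enrich_genelist(GeneList(frozenset({"gx"}), frozenset({"g1"}), {}),
                        tiny_tree)
    with pytest.raises(Exception, match="empty"):
        enrich_genelist(GeneList(frozenset(), frozenset({"g1"}), {}), tiny_tree)


def test_enrich_genelist_recovers_planted_pathway(standard_run):
    cfg, tree = standard_run
    data = make_gene_data(tree, cfg)
    results = enrich_genelist(data.genes, tree)
    nonko = [r for r in results if r.layer != "ko"]
    best = max(nonko, key=lambda r: r.val)
    assert best.val > 0 and best.function_id == "P0001"
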