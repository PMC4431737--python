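"""Statistical machinery for Functional Tree mapping.

Primitives
----------
* ``coverage`` — the fraction of a function's assigned KOs observed in the
  query data, used to down-weight sparsely supported enrichment,

      cov_j = KO_exp,j / KO_total,j ;

* ``rank_test`` — two-sample Wilcoxon rank-sum (Mann-Whitney) test with
  midranks: exact enumeration of all rank splits when both groups have at
  most ``EXACT_LIMIT`` observations, continuity-corrected normal
  approximation (with tie correction) above that;
* ``fisher_exact`` — one-sided Fisher's exact test on a 2x2 table, summed in
  log-factorial space;
* ``bonferroni`` — family-wise correction p -> min(1, m p);
* ``display_value`` — the rendered node value

      val_j = log10(1 / p_corrected,j) * cov_j     if p_corrected,j < alpha
      val_j = 0                                    otherwise.

Pipelines
---------
* ``variability`` — per function, the standard deviation across samples of
  the summed relative abundance of its KOs, times coverage;
* ``enrich_genus`` — rank test of per-organism gene counts, focal genera vs
  the remaining organisms, per function;
* ``enrich_metagenome`` — two-stage flow: rank test per KO (query vs
  background abundances) to flag enriched KOs, then Fisher's exact test per
  upper-layer function on the enriched/assigned 2x2 table over the full KO
  universe (hidden KOs included);
* ``enrich_genelist`` — Fisher's exact test per function on the
  expressed/associated 2x2 table over the genome-wide gene universe.

Bonferroni families are per pipeline stage: the KO-layer family of the
metagenome flow is corrected separately from its upper-layer family; the
genus and gene-list flows each form a single family. m is the number of
functions actually tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError
from .hierarchy import FunctionalTree
from .io import GeneList

#: exact rank-test enumeration is used when both groups are at most this big
EXACT_LIMIT = 8

#: p-values are floored here before the log transform
P_FLOOR = 1e-300

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# primitives

@dataclass(frozen=True)
class Coverage:
    """KO coverage of a function: observed over assigned."""

    ko_total: int
    ko_exp: int

    def __post_init__(self):
        if self.ko_total <= 0:
            raise StatsError("coverage undefined: no KOs assigned under the function")
        if not 0 <= self.ko_exp <= self.ko_total:
            raise StatsError("ko_exp must lie in [0, ko_total]")

    @property
    def cov(self) -> float:
        return self.ko_exp / self.ko_total


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (enriched|expressed) x (assigned|associated)."""

    a: int  # enriched and assigned
    b: int  # non-enriched and assigned
    c: int  # enriched and not assigned
    d: int  # non-enriched and not assigned

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise StatsError("contingency table total must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-function test outcome plus the display value."""

    function_id: str
    layer: str
    p_raw: float
    p_corrected: float
    cov: float
    val: float
    significant: bool
    tested: bool = True
    name: str = ""


def coverage(tree: FunctionalTree, function_id: str,
             observed_kos: Iterable[str]) -> Coverage:
    """Coverage of ``function_id`` given the KOs observed in the query."""
    kos = tree.function_ko_set(function_id)
    if not kos:
        raise StatsError("function %r has no KOs assigned under it" % function_id)
    observed = set(observed_kos)
    unknown = observed - set(tree.ko_universe)
    if unknown:
        raise StatsError("observed KOs not in the tree: %s"
                         % ", ".join(sorted(unknown)))
    return Coverage(ko_total=len(kos), ko_exp=len(kos & observed))


def rank_test(group_a: Sequence[float], group_b: Sequence[float],
              alternative: str = "greater") -> float:
    """Two-sample Wilcoxon rank-sum test p-value.

    Exact permutation enumeration over all C(n, n_a) rank splits (midranks
    for ties; the observed split counts toward the tail) when both groups
    have at most EXACT_LIMIT observations, otherwise the continuity-corrected
    normal approximation.
    """
    if alternative not in ("greater", "two-sided"):
        raise StatsError("alternative must be 'greater' or 'two-sided'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("rank test requires two non-empty groups")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 1.0  # degenerate: all values identical
    if a.size <= EXACT_LIMIT and b.size <= EXACT_LIMIT:
        return _rank_test_exact(a, b, alternative)
    res = sps.mannwhitneyu(a, b, alternative=alternative, use_continuity=True,
                           method="asymptotic")
    return float(min(1.0, max(res.pvalue, 0.0)))


def _rank_test_exact(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact permutation distribution of the rank sum, by counting.

    Midranks doubled to integers; an integer DP counts, for every subset
    size, how many subsets of the pooled ranks reach each rank sum — an
    exact equivalent of enumerating all C(n, n_a) splits.
    """
    ranks = sps.rankdata(np.concatenate([a, b]))
    ranks2 = np.rint(ranks * 2).astype(int)  # midranks are multiples of 1/2
    n, na = ranks2.size, a.size
    observed = int(ranks2[:na].sum())
    max_sum = int(ranks2.sum())
    # counts[k][s] = number of k-subsets with doubled-rank sum s
    counts = [[0] * (max_sum + 1) for _ in range(na + 1)]
    counts[0][0] = 1
    for r in ranks2.tolist():
        for k in range(na - 1, -1, -1):
            row, nxt = counts[k], counts[k + 1]
            for s in range(max_sum - r, -1, -1):
                if row[s]:
                    nxt[s + r] += row[s]
    dist = counts[na]
    total = sum(dist)
    ge = sum(dist[observed:])
    p_greater = ge / total
    if alternative == "greater":
        return p_greater
    le = sum(dist[:observed + 1])
    return min(1.0, 2.0 * min(p_greater, le / total))


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """One-sided Fisher's exact test: the hypergeometric tail P(A >= a).

    Point probabilities are the single-table factorial formula, evaluated
    and summed in log-factorial space for numerical stability.
    """
    if alternative != "greater":
        raise StatsError("only the 'greater' alternative is supported")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lf = math.lgamma  # log-factorial via lgamma(x + 1)
    # log of the margin term shared by every table with these margins:
    # r1! (n-r1)! c1! (n-c1)! / n!
    log_margins = (lf(r1 + 1) + lf(n - r1 + 1)
                   + lf(c1 + 1) + lf(n - c1 + 1) - lf(n + 1))
    hi = min(r1, c1)
    total = 0.0
    for x in range(a, hi + 1):
        log_p = log_margins - (lf(x + 1) + lf(r1 - x + 1)
                               + lf(c1 - x + 1) + lf(n - r1 - c1 + x + 1))
        total += math.exp(log_p)
    return float(min(1.0, total))


def bonferroni(p_values: Mapping[str, float]) -> dict[str, float]:
    """Family-wise Bonferroni correction: p -> min(1, m p)."""
    m = len(p_values)
    for k, p in p_values.items():
        if not 0.0 < p <= 1.0:
            raise StatsError("p-value for %r outside (0, 1]: %r" % (k, p))
    return {k: min(1.0, m * p) for k, p in p_values.items()}


def display_value(p_corrected: float, cov: float = 1.0,
                  alpha: float = DEFAULT_ALPHA, log_base: float = 10.0) -> float:
    """val = log(1/p) * cov when significant (p < alpha), else 0."""
    if p_corrected <= 0.0:
        raise StatsError("p-value must be positive (floor it at %g)" % P_FLOOR)
    if p_corrected > 1.0:
        raise StatsError("p-value above 1: %r" % p_corrected)
    if not 0.0 <= cov <= 1.0:
        raise StatsError("coverage outside [0, 1]: %r" % cov)
    if p_corrected >= alpha:
        return 0.0
    p = max(p_corrected, P_FLOOR)
    return math.log(1.0 / p, log_base) * cov


# ---------------------------------------------------------------------------
# pipelines

def _check_profiles(profiles: pd.DataFrame, tree: FunctionalTree,
                    relative: bool, what: str) -> None:
    unknown = sorted(set(profiles.columns) - set(tree.ko_universe))
    if unknown:
        raise StatsError("%s columns not in the tree KO universe: %s"
                         % (what, ", ".join(unknown[:10])))
    if relative:
        sums = profiles.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise StatsError("%s rows must be relative abundances summing to 1" % what)


def variability(tree: FunctionalTree, profiles: pd.DataFrame,
                ddof: int = 0) -> dict[str, float]:
    """Functional variability: val_j = sigma_j * cov_j.

    sigma_j is the standard deviation (population by default) across samples
    of the per-sample summed relative abundance of the KOs under function j;
    cov_j counts a KO as observed if it is non-zero in at least one sample.
    """
    if len(profiles) < 2:
        raise StatsError("variability requires at least 2 samples")
    _check_profiles(profiles, tree, relative=True, what="profile")
    observed = frozenset(profiles.columns[(profiles > 0).any(axis=0)])
    out: dict[str, float] = {}
    for fid in tree.function_ids():
        kos = tree.function_ko_set(fid)
        if not kos:
            continue
        cols = sorted(kos & set(profiles.columns))
        sums = profiles[cols].sum(axis=1).to_numpy() if cols else np.zeros(len(profiles))
        sigma = float(np.std(sums, ddof=ddof))
        cov = len(kos & observed) / len(kos)
        out[fid] = sigma * cov
    return out


def _result(tree, fid, p_raw, p_corr, cov, alpha, log_base,
            coverage_weight, tested=True):
    significant = tested and p_corr < alpha
    val = display_value(p_corr, cov if coverage_weight else 1.0,
                        alpha, log_base) if tested else 0.0
    return EnrichmentResult(function_id=fid, layer=tree.layer_of(fid),
                            p_raw=p_raw, p_corrected=p_corr, cov=cov, val=val,
                            significant=significant, tested=tested,
                            name=tree.name_of(fid))


def enrich_genus(gene_counts: pd.DataFrame, focal: Iterable[str],
                 tree: FunctionalTree, alpha: float = DEFAULT_ALPHA,
                 alternative: str = "greater",
                 log_base: float = 10.0) -> list[EnrichmentResult]:
    """Pan-genomic enrichment of focal organisms against the remainder.

    gene_counts is an organisms-by-KO matrix of gene counts.  Per function,
    the per-organism gene counts summed over the function's KOs are compared
    between the focal group and all remaining organisms with the rank-sum
    test; Bonferroni over all tested functions; val per the coverage-weighted
    display transform, where a KO counts as focal-associated if at least one
    focal organism has a gene in it.
    """
    focal = set(focal)
    organisms = set(gene_counts.index)
    if not focal or not focal < organisms:
        raise StatsError("focal set must be a non-empty strict subset of organisms")
    _check_profiles(gene_counts, tree, relative=False, what="gene-count")
    focal_idx = sorted(focal)
    rest_idx = sorted(organisms - focal)
    focal_observed = frozenset(
        gene_counts.columns[(gene_counts.loc[focal_idx] > 0).any(axis=0)])

    p_raw: dict[str, float] = {}
    covs: dict[str, float] = {}
    untested: list[str] = []
    for fid in tree.function_ids():
        kos = tree.function_ko_set(fid)
        if not kos:
            continue
        cols = sorted(kos & set(gene_counts.columns))
        if not cols:
            untested.append(fid)
            continue
        sums = gene_counts[cols].sum(axis=1)
        fa = sums.loc[focal_idx].to_numpy(dtype=float)
        bb = sums.loc[rest_idx].to_numpy(dtype=float)
        if fa.sum() == 0 and bb.sum() == 0:
            untested.append(fid)  # function absent from all organisms
            continue
        p_raw[fid] = rank_test(fa, bb, alternative)
        covs[fid] = len(kos & focal_observed) / len(kos)
    p_corr = bonferroni(p_raw)
    results = [
        _result(tree, fid, p_raw[fid], p_corr[fid], covs[fid], alpha, log_base,
                coverage_weight=True)
        for fid in sorted(p_raw)
    ]
    results += [
        _result(tree, fid, 1.0, 1.0, 0.0, alpha, log_base,
                coverage_weight=True, tested=False)
        for fid in sorted(untested)
    ]
    return results


def enrich_metagenome(query_profiles: pd.DataFrame,
                      background_profiles: pd.DataFrame,
                      tree: FunctionalTree, alpha: float = DEFAULT_ALPHA,
                      alternative: str = "greater",
                      stage1_corrected: bool = True,
                      coverage_weight: bool = False,
                      log_base: float = 10.0) -> list[EnrichmentResult]:
    """Two-stage enrichment of a metagenome against a background.

    Stage 1: per KO, rank-sum test of query vs background relative
    abundances, Bonferroni over the KO family; a KO is flagged enriched when
    its (corrected, by default) p falls below alpha.  Stage 2: per non-KO
    function, Fisher's exact test on (enriched x assigned) counts over the
    full KO universe including hidden KOs, Bonferroni over the upper-layer
    family.  The display value carries no coverage factor unless
    ``coverage_weight`` is set.
    """
    if set(query_profiles.columns) != set(background_profiles.columns):
        raise StatsError("query and background KO universes differ")
    if query_profiles.empty or background_profiles.empty:
        raise StatsError("profile sets must be non-empty")
    _check_profiles(query_profiles, tree, relative=True, what="query profile")
    _check_profiles(background_profiles, tree, relative=True, what="background profile")

    # stage 1: KO family
    kos_tested = sorted(query_profiles.columns)
    p1_raw = {
        ko: rank_test(query_profiles[ko].to_numpy(dtype=float),
                      background_profiles[ko].to_numpy(dtype=float), alternative)
        for ko in kos_tested
    }
    p1_corr = bonferroni(p1_raw)
    flag = p1_corr if stage1_corrected else p1_raw
    enriched = frozenset(ko for ko in kos_tested if flag[ko] < alpha)
    observed = frozenset(query_profiles.columns[(query_profiles > 0).any(axis=0)])

    results = []
    for ko in kos_tested:
        cov = 1.0 if ko in observed else 0.0
        results.append(_result(tree, ko, p1_raw[ko], p1_corr[ko], cov,
                               alpha, log_base, coverage_weight))

    # stage 2: upper-layer family over the full KO universe, hidden included
    universe = tree.ko_universe
    n_enriched = len(enriched)
    p2_raw: dict[str, float] = {}
    covs: dict[str, float] = {}
    upper = tree.function_ids(layers=("biological_category", "biological_process",
                                      "pathway", "module"))
    for fid in upper:
        kos = tree.function_ko_set(fid)
        if not kos:
            continue
        a = len(kos & enriched)
        b = len(kos) - a
        c = n_enriched - a
        d = len(universe) - len(kos) - c
        p2_raw[fid] = fisher_exact(ContingencyTable(a, b, c, d))
        covs[fid] = len(kos & observed) / len(kos)
    p2_corr = bonferroni(p2_raw)
    results += [
        _result(tree, fid, p2_raw[fid], p2_corr[fid], covs[fid], alpha,
                log_base, coverage_weight)
        for fid in sorted(p2_raw)
    ]
    return results


def enrich_genelist(genes: GeneList, tree: FunctionalTree,
                    alpha: float = DEFAULT_ALPHA,
                    log_base: float = 10.0) -> list[EnrichmentResult]:
    """Gene-set enrichment of a query gene list against its genome.

    A gene associates with a function iff it maps to a KO under the
    function.  Per function: Fisher's exact test (greater) on the
    (in-list x associated) 2x2 table over the gene universe, Bonferroni over
    tested functions, then the coverage-weighted display value where ko_exp
    counts KOs hit by at least one input gene.
    """
    genes.validate()
    universe_size = len(genes.organism_universe)
    ko_to_genes: dict[str, set[str]] = {}
    for g, kos in genes.gene_to_ko.items():
        if g not in genes.organism_universe:
            continue
        for k in kos:
            ko_to_genes.setdefault(k, set()).add(g)
    query = set(genes.genes)
    hit_kos = frozenset(k for k, gs in ko_to_genes.items() if gs & query)

    p_raw: dict[str, float] = {}
    covs: dict[str, float] = {}
    untested: list[str] = []
    for fid in tree.function_ids():
        kos = tree.function_ko_set(fid)
        if not kos:
            continue
        assoc: set[str] = set()
        for k in sorted(kos):
            assoc |= ko_to_genes.get(k, set())
        if not assoc:
            untested.append(fid)  # no mapped genes: reported with p = 1
            continue
        a = len(assoc & query)
        b = len(assoc) - a
        c = len(query) - a
        d = universe_size - len(assoc) - c
        p_raw[fid] = fisher_exact(ContingencyTable(a, b, c, d))
        covs[fid] = len(kos & hit_kos) / len(kos)
    p_corr = bonferroni(p_raw)
    results = [
        _result(tree, fid, p_raw[fid], p_corr[fid], covs[fid], alpha, log_base,
                coverage_weight=True)
        for fid in sorted(p_raw)
    ]
    results += [
        _result(tree, fid, 1.0, 1.0, 0.0, alpha, log_base,
                coverage_weight=True, tested=False)
        for fid in sorted(untested)
    ]
    return results
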