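"""Synthetic fixtures with known planted structure.

Generates everything the pipelines consume — membership tables, relative
abundance profiles, organism gene-count matrices and gene lists — entirely
offline and bit-reproducibly under a fixed seed.  The generators only aim
for two statistical features: exchangeable null data at effect_size 1, and a
controllable multiplicative planted signal on a chosen set of functions.
Log-normal KO abundances and Poisson gene counts are used as minimal
realistic models; no attempt is made to emulate real ontology topology or
real microbiome abundance distributions.

The named *standard* scenario (2 categories, 4 processes, 12 pathways, 30
modules, 300 KOs, 10% unassigned KOs, 20+20 samples, planted pathway P0001
at effect 3x) is the reference condition used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import FuncTreeError
from .hierarchy import FunctionalTree, MembershipTables
from .io import GeneList


@dataclass(frozen=True)
class FixtureConfig:
    """All knobs of the fixture generators; defaults are the standard scenario."""

    n_categories: int = 2
    n_processes: int = 4
    n_pathways: int = 12
    n_modules: int = 30
    n_kos: int = 300
    unassigned_fraction: float = 0.1
    n_query_samples: int = 20
    n_background_samples: int = 20
    planted_functions: frozenset[str] = frozenset({"P0001"})
    effect_size: float = 3.0
    abundance_dispersion: float = 0.5
    seed: int = 0
    # secondary pathway membership for a KO (exercises multi-placement)
    multi_pathway_fraction: float = 0.1
    # pan-genomic / gene-list scale (both groups within the exact-test regime)
    n_organisms: int = 16
    n_focal: int = 8
    gene_rate: float = 2.0
    genes_per_ko: int = 2
    n_unmapped_genes: int = 60
    n_signal_genes: int = 30
    n_noise_genes: int = 20


STANDARD = FixtureConfig()


def standard_config(seed: int = 0, **overrides) -> FixtureConfig:
    """The standard scenario at a given seed (optionally tweaked)."""
    return replace(STANDARD, seed=seed, **overrides)


def _rng(config: FixtureConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def _ids(prefix: str, n: int, width: int) -> list[str]:
    return ["%s%0*d" % (prefix, width, i + 1) for i in range(n)]


def make_membership(config: FixtureConfig) -> MembershipTables:
    """Random nested membership tables honoring the layer order.

    Exactly round(unassigned_fraction * n_kos) KOs are left out of all
    modules and pathways; each pathway receives at least one KO; each module
    is a subset of one host pathway's KOs (so the subset attachment policy
    always places it), and a fraction of KOs gain a second pathway.
    """
    c = config
    if min(c.n_categories, c.n_processes, c.n_pathways, c.n_modules, c.n_kos) < 1:
        raise FuncTreeError("all layer counts must be >= 1")
    n_unassigned = int(round(c.n_kos * c.unassigned_fraction))
    n_assigned = c.n_kos - n_unassigned
    if n_assigned < c.n_pathways:
        raise FuncTreeError("infeasible nesting: fewer assigned KOs (%d) than "
                            "pathways (%d)" % (n_assigned, c.n_pathways))
    if c.n_modules > n_assigned:
        raise FuncTreeError("infeasible nesting: more modules (%d) than assigned "
                            "KOs (%d)" % (c.n_modules, n_assigned))
    if c.n_processes < c.n_categories or c.n_pathways < c.n_processes:
        raise FuncTreeError("layer counts must not decrease downward")
    rng = _rng(c, 0)

    categories = _ids("C", c.n_categories, 2)
    processes = _ids("B", c.n_processes, 2)
    pathways = _ids("P", c.n_pathways, 4)
    modules = _ids("M", c.n_modules, 4)
    kos = _ids("K", c.n_kos, 5)

    # upper skeleton: guarantee coverage, then fill randomly
    proc_cat = {pr: categories[i] if i < c.n_categories
                else categories[rng.integers(c.n_categories)]
                for i, pr in enumerate(processes)}
    path_proc = {p: processes[i] if i < c.n_processes
                 else processes[rng.integers(c.n_processes)]
                 for i, p in enumerate(pathways)}
    skeleton = {p: (path_proc[p], proc_cat[path_proc[p]]) for p in pathways}

    shuffled = list(kos)
    rng.shuffle(shuffled)
    unassigned = set(shuffled[:n_unassigned])
    assigned = shuffled[n_unassigned:]

    # deal one KO to each pathway first, then the rest at random; a fraction
    # of KOs join a second pathway
    ko_to_pathways: dict[str, set[str]] = {}
    for i, ko in enumerate(assigned):
        p = pathways[i] if i < c.n_pathways else pathways[rng.integers(c.n_pathways)]
        ko_to_pathways.setdefault(ko, set()).add(p)
    if c.n_pathways > 1 and c.multi_pathway_fraction > 0:
        for ko in assigned:
            if rng.random() < c.multi_pathway_fraction:
                others = [p for p in pathways if p not in ko_to_pathways[ko]]
                if others:
                    ko_to_pathways[ko].add(others[rng.integers(len(others))])

    pathway_kos: dict[str, list[str]] = {p: [] for p in pathways}
    for ko in assigned:
        for p in ko_to_pathways[ko]:
            pathway_kos[p].append(ko)

    # each module samples a subset of its host pathway's KOs
    ko_to_modules: dict[str, set[str]] = {}
    for j, m in enumerate(modules):
        host = pathways[j % c.n_pathways]
        pool = sorted(pathway_kos[host])
        size = int(rng.integers(1, max(2, len(pool) // 2 + 1)))
        chosen = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        for idx in sorted(chosen):
            ko_to_modules.setdefault(pool[idx], set()).add(m)

    names = {fid: "Synthetic %s" % fid
             for fid in categories + processes + pathways + modules + kos}
    tables = MembershipTables(
        ko_to_modules={k: frozenset(v) for k, v in ko_to_modules.items()},
        ko_to_pathways={k: frozenset(ko_to_pathways.get(k, set()))
                        for k in assigned + sorted(unassigned)},
        pathway_skeleton=skeleton,
        names=names,
    )
    missing = set(c.planted_functions) - set(pathways) - set(modules)
    if missing:
        raise FuncTreeError("planted functions not generated: %s"
                            % ", ".join(sorted(missing)))
    return tables


def planted_ko_set(tree: FunctionalTree, config: FixtureConfig) -> frozenset[str]:
    out: frozenset[str] = frozenset()
    for fid in sorted(config.planted_functions):
        out |= tree.function_ko_set(fid)
    return out


def make_profiles(tree: FunctionalTree,
                  config: FixtureConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative-abundance profiles (query, background), samples x KO.

    Per sample, KO abundances are i.i.d. log-normal with the configured
    dispersion; KOs under planted functions are multiplied by effect_size in
    query samples only; rows are renormalized to sum to 1.
    """
    c = config
    rng = _rng(c, 1)
    kos = sorted(tree.ko_universe)
    planted = planted_ko_set(tree, c)
    mask = np.array([k in planted for k in kos], dtype=float)

    def draw(n: int, boosted: bool) -> np.ndarray:
        x = rng.lognormal(mean=0.0, sigma=c.abundance_dispersion, size=(n, len(kos)))
        if boosted:
            x *= np.where(mask > 0, c.effect_size, 1.0)
        return x / x.sum(axis=1, keepdims=True)

    query = draw(c.n_query_samples, boosted=True)
    background = draw(c.n_background_samples, boosted=False)
    qidx = ["q%03d" % (i + 1) for i in range(c.n_query_samples)]
    bidx = ["b%03d" % (i + 1) for i in range(c.n_background_samples)]
    return (pd.DataFrame(query, index=qidx, columns=kos),
            pd.DataFrame(background, index=bidx, columns=kos))


class GeneData(NamedTuple):
    """Pan-genomic and gene-list fixtures sharing one gene<->KO annotation."""

    counts: pd.DataFrame          # organisms x KO gene counts
    focal: frozenset[str]         # focal organism ids
    genes: GeneList               # query list + universe + gene->KO mapping


def make_gene_data(tree: FunctionalTree, config: FixtureConfig) -> GeneData:
    """Poisson gene counts per organism/KO plus a planted query gene list.

    Focal organisms draw counts at rate * effect_size on planted KOs.  The
    gene universe holds genes_per_ko genes per KO plus unmapped genes; the
    query list samples signal genes from planted-KO genes and noise genes
    uniformly from the rest.
    """
    c = config
    rng = _rng(c, 2)
    kos = sorted(tree.ko_universe)
    planted = planted_ko_set(tree, c)
    if not 0 < c.n_focal < c.n_organisms:
        raise FuncTreeError("need 0 < n_focal < n_organisms")
    organisms = _ids("ORG", c.n_organisms, 3)
    focal = frozenset(organisms[:c.n_focal])
    rates = np.full((c.n_organisms, len(kos)), c.gene_rate)
    focal_rows = np.array([o in focal for o in organisms])
    planted_cols = np.array([k in planted for k in kos])
    rates[np.ix_(focal_rows, planted_cols)] *= c.effect_size
    counts = pd.DataFrame(rng.poisson(rates), index=organisms, columns=kos)

    gene_to_ko = {}
    for k in kos:
        for i in range(c.genes_per_ko):
            gene_to_ko["g_%s_%d" % (k, i + 1)] = frozenset({k})
    unmapped = ["g_none_%03d" % (i + 1) for i in range(c.n_unmapped_genes)]
    universe = sorted(gene_to_ko) + unmapped

    # at effect_size <= 1 the list is an exchangeable draw from the universe
    # (null); otherwise signal genes come from planted-KO genes, noise genes
    # uniformly from the rest
    if c.effect_size <= 1.0:
        pool = sorted(universe)
        take = min(c.n_signal_genes + c.n_noise_genes, len(pool))
        chosen = list(np.array(pool)[rng.choice(len(pool), take, replace=False)])
    else:
        signal_pool = sorted(g for g, ks in gene_to_ko.items() if ks & planted)
        noise_pool = sorted(set(universe) - set(signal_pool))
        n_signal = min(c.n_signal_genes, len(signal_pool))
        n_noise = min(c.n_noise_genes, len(noise_pool))
        chosen = list(np.array(signal_pool)[rng.choice(len(signal_pool), n_signal,
                                                       replace=False)])
        chosen += list(np.array(noise_pool)[rng.choice(len(noise_pool), n_noise,
                                                       replace=False)])
    genes = GeneList(genes=frozenset(chosen),
                     organism_universe=frozenset(universe),
                     gene_to_ko=gene_to_ko)
    return GeneData(counts=counts, focal=focal, genes=genes)
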