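"""Population-level statistics: diversity, differentiation, nest network.

Nucleotide diversity and Hudson-type F_ST use missing-data-aware
ratio-of-sums estimators (per-site difference and comparison counts are
accumulated separately and divided once), so unevenly missing genotypes
do not bias the ratios.  The nest network weights nest pairs by F_ST
and reports a minimum-spanning-tree backbone plus the percolation
threshold at which the thresholded graph stays connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genodata import GenotypeMatrix

log = logging.getLogger(__name__)


def _site_counts(M: GenotypeMatrix, ids: list[str]):
    """Per-site called allele-copy counts n_i and alt-copy counts a_i."""
    sub = M.subset_samples(ids)
    called = ~np.isnan(sub.dosages)
    n = 2.0 * called.sum(axis=1)
    a = np.nansum(sub.dosages, axis=1)
    return n, a


def nucleotide_diversity(M: GenotypeMatrix, ids: list[str]) -> float:
    """Average pairwise diversity (pi) with the ratio-of-sums convention.

    ``pi = sum_i D_i / sum_i C_i`` where ``D_i = a_i (n_i - a_i)`` is
    the number of differing pairs among the ``n_i`` called allele
    copies at site i and ``C_i = n_i (n_i - 1) / 2``.  Sites with < 2
    called copies contribute to neither sum.  NaN when no site is
    usable (logged).
    """
    n, a = _site_counts(M, ids)
    use = n >= 2
    if not use.any():
        log.warning("no site with >= 2 called allele copies; pi undefined")
        return float("nan")
    D = (a * (n - a))[use]
    C = (n * (n - 1) / 2.0)[use]
    return float(D.sum() / C.sum())


def hudson_fst(M: GenotypeMatrix, ids1: list[str], ids2: list[str]) -> float:
    """Hudson-type F_ST between two groups, ratio-of-sums over sites.

    ``F_ST = sum_i (pi_between,i - pi_within,i) / sum_i pi_between,i``
    with ``pi_between,i = (a1 (n2 - a2) + a2 (n1 - a1)) / (n1 n2)`` and
    ``pi_within,i`` the average of the two unbiased within-group
    per-site diversities.  Sites need >= 2 called copies per group.
    """
    n1, a1 = _site_counts(M, ids1)
    n2, a2 = _site_counts(M, ids2)
    use = (n1 >= 2) & (n2 >= 2)
    if not use.any():
        return float("nan")
    n1, a1, n2, a2 = n1[use], a1[use], n2[use], a2[use]
    pi_b = (a1 * (n2 - a2) + a2 * (n1 - a1)) / (n1 * n2)
    pi_w = 0.5 * (2 * a1 * (n1 - a1) / (n1 * (n1 - 1))
                  + 2 * a2 * (n2 - a2) / (n2 * (n2 - 1)))
    denom = pi_b.sum()
    if denom == 0.0:
        return float("nan")
    return float((pi_b - pi_w).sum() / denom)


def pairwise_fst(M: GenotypeMatrix,
                 groups: dict[str, list[str]]) -> pd.DataFrame:
    """Symmetric pairwise Hudson F_ST matrix over named groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            v = hudson_fst(M, groups[gi], groups[gj])
            out.loc[gi, gj] = out.loc[gj, gi] = v
    return out


@dataclass
class NestNetwork:
    fst: pd.DataFrame            # pairwise nest F_ST (clamped >= 0)
    graph: nx.Graph              # complete weighted graph
    mst: nx.Graph                # minimum spanning backbone
    percolation_threshold: float
    degrees: pd.Series           # MST degree per nest ("star" diagnostics)


def nest_network(M: GenotypeMatrix,
                 nest_groups: dict[str, list[str]]) -> NestNetwork:
    """F_ST-weighted nest connectivity network with MST backbone.

    Negative F_ST estimates are clamped to 0 (logged).  The percolation
    threshold is the largest edge weight that must be admitted for the
    thresholded graph to stay connected, i.e. the maximum MST edge
    weight; the MST degree table flags hub ("star centre") nests.
    """
    if len(nest_groups) < 3:
        raise ValueError("need at least 3 nests")
    fst = pairwise_fst(M, nest_groups)
    neg = (fst.values < 0).sum() // 2
    if neg:
        log.info("clamped %d negative F_ST edge(s) to 0", int(neg))
    fst = fst.clip(lower=0.0)
    g = nx.Graph()
    names = list(nest_groups)
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            g.add_edge(a, b, weight=float(fst.loc[a, b]))
    mst = nx.minimum_spanning_tree(g)
    thr = max((d["weight"] for _, _, d in mst.edges(data=True)), default=0.0)
    degrees = pd.Series({n: d for n, d in mst.degree()}).sort_index()
    return NestNetwork(fst, g, mst, float(thr), degrees)


@dataclass
class SexClutchSummary:
    n_male: int
    n_female: int
    binom_p: float
    t_stat: float
    t_p: float
    clutch_mean: float
    clutch_min: int
    clutch_max: int
    n_nests: int


def sex_and_clutch_summary(nest_table: pd.DataFrame,
                           parasitic_eggs: set[str] | None = None
                           ) -> SexClutchSummary:
    """Offspring sex ratio and clutch-size summary.

    Parasitic eggs are excluded before both computations (they belong
    to another female's reproductive output).  The 50:50 test is an
    exact two-sided binomial test; the one-sample t statistic on the
    0/1 sex codes is also reported for comparability with approximate
    analyses, but the binomial p-value is the primary result.
    """
    parasitic_eggs = parasitic_eggs or set()
    eggs = nest_table[(nest_table["role"] == "offspring")
                      & ~nest_table["sample_id"].isin(parasitic_eggs)]
    sexes = eggs["sex"].dropna()
    sexes = sexes[sexes.isin(["M", "F"])]
    n_m = int((sexes == "M").sum())
    n_f = int((sexes == "F").sum())
    if n_m + n_f == 0:
        raise ValueError("no sexed offspring")
    binom_p = float(stats.binomtest(n_m, n_m + n_f, 0.5).pvalue)
    codes = (sexes == "M").astype(float)
    if codes.std(ddof=1) > 0:
        t_stat, t_p = stats.ttest_1samp(codes, 0.5)
    else:
        t_stat, t_p = np.inf, 0.0
    clutches = eggs.groupby("nest_id")["sample_id"].count()
    return SexClutchSummary(
        n_male=n_m, n_female=n_f, binom_p=binom_p,
        t_stat=float(t_stat), t_p=float(t_p),
        clutch_mean=float(clutches.mean()),
        clutch_min=int(clutches.min()), clutch_max=int(clutches.max()),
        n_nests=int(len(clutches)),
    )
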