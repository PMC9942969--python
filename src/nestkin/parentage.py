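"""Maternity, sibship dyads and paternal-lineage partitioning.

This replaces full-pedigree sibship MCMC with a transparent,
deterministic pairwise machinery:

* maternity is verified by the opposing-homozygote count (a true
  mother-offspring pair cannot be homozygous for different alleles at
  an error-free site), backed by the pair's Ajk;
* egg-egg dyads are classified full-sib / half-sib / unrelated by
  likelihoods built from IBD-conditional genotype-pair probabilities
  under HWE, with Cotterman coefficients (k0, k1, k2) of
  (0.25, 0.50, 0.25), (0.50, 0.50, 0) and (1, 0, 0), a per-allele
  genotyping-error mixture, and the conventional 0.2 relatedness floor
  for reporting sib dyads;
* each clutch is partitioned into paternal sib-groups as the connected
  components of its full-sib graph, with a paternal-allele consistency
  likelihood ratio (same father vs two independent HWE fathers)
  refining ambiguous edges;
* lineages are merged across nests when inter-nest dyads look like
  half-sibs sharing a father (promiscuous male) or full-sibs sharing
  both parents (a renesting pair).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RELATIONSHIPS = ("unrelated", "half_sib", "full_sib")
#: Cotterman (k0, k1, k2) per relationship
COTTERMAN = {
    "full_sib": (0.25, 0.50, 0.25),
    "half_sib": (0.50, 0.50, 0.0),
    "unrelated": (1.0, 0.0, 0.0),
}
#: preference order on log-likelihood ties: least related wins
_TIE_ORDER = {"unrelated": 0, "half_sib": 1, "full_sib": 2}

DYAD_AJK_FLOOR = 0.2
DEFAULT_ERROR = 0.005
MIN_SHARED_SITES = 50


@dataclass
class MaternityResult:
    hen_id: str
    egg_id: str
    accept: bool | None           # None = indeterminate (too few sites)
    mismatch_rate: float
    n_opposing: int
    n_sites: int
    ajk: float | None = None


@dataclass
class DyadScore:
    """Relationship log-likelihoods for one pair of offspring."""

    id1: str
    id2: str
    lnl: dict[str, float]
    best: str
    n_sites: int
    ajk: float | None = None

    @property
    def lr_fs_hs(self) -> float:
        return self.lnl["full_sib"] - self.lnl["half_sib"]


@dataclass
class PaternalLineage:
    lineage_id: str
    egg_ids: list[str]
    nest_ids: list[str]
    mother_id: str | None = None


def genotype_error_matrix(error: float) -> np.ndarray:
    """P(observed genotype | true genotype) under per-allele flips.

    Each of the two allele copies flips independently with probability
    ``error``.  Rows are true dosage 0/1/2, columns observed.
    """
    e = error
    return np.array([
        [(1 - e) ** 2, 2 * e * (1 - e), e ** 2],
        [e * (1 - e), (1 - e) ** 2 + e ** 2, e * (1 - e)],
        [e ** 2, 2 * e * (1 - e), (1 - e) ** 2],
    ])


def genotype_pair_probs(p: float | np.ndarray,
                        relationship: str) -> np.ndarray:
    """P(g1, g2 | relationship) over the 9 true genotype pairs under HWE.

    Built from the IBD-state mixture ``k0 P0 + k1 P1 + k2 P2`` where
    P0 is independence, P2 is identity, and P1 draws one allele of g2
    identical by descent from a uniformly chosen allele of g1.  ``p``
    is the alt-allele frequency (scalar or array); the result has shape
    (..., 3, 3) and each 3x3 slice sums to 1.
    """
    k0, k1, k2 = COTTERMAN[relationship]
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=-1)     # (..., 3)
    P0 = hwe[..., :, None] * hwe[..., None, :]
    P2 = hwe[..., :, None] * np.eye(3)
    # transmission given one IBD allele from g1
    z = np.zeros_like(p)
    T = np.stack([
        np.stack([q, p, z], axis=-1),
        np.stack([0.5 * q, 0.5 * np.ones_like(p), 0.5 * p], axis=-1),
        np.stack([z, q, p], axis=-1),
    ], axis=-2)                                            # (..., 3, 3)
    P1 = hwe[..., :, None] * T
    return k0 * P0 + k1 * P1 + k2 * P2


def maternity_check(hen: np.ndarray, egg: np.ndarray,
                    error_allowance: float = 0.01,
                    ajk: float | None = None,
                    ajk_floor: float = DYAD_AJK_FLOOR,
                    min_sites: int = MIN_SHARED_SITES,
                    hen_id: str = "hen", egg_id: str = "egg"
                    ) -> MaternityResult:
    """Opposing-homozygote maternity test.

    Counts sites where hen and egg are homozygous for different alleles
    (dosages 0/2 or 2/0); maternity is accepted when the opposing rate
    is at most ``error_allowance`` and, when an Ajk value is supplied,
    the pair's Ajk exceeds the 0.2 floor.  Fewer than ``min_sites``
    shared called sites yields an indeterminate (None) verdict.
    """
    shared = ~np.isnan(hen) & ~np.isnan(egg)
    n = int(shared.sum())
    if n < min_sites:
        return MaternityResult(hen_id, egg_id, None, np.nan, 0, n, ajk)
    h, e = hen[shared], egg[shared]
    opp = int((((h == 0) & (e == 2)) | ((h == 2) & (e == 0))).sum())
    rate = opp / n
    accept = rate <= error_allowance and (ajk is None or ajk > ajk_floor)
    return MaternityResult(hen_id, egg_id, bool(accept), rate, opp, n, ajk)


def dyad_likelihoods(x1: np.ndarray, x2: np.ndarray, p: np.ndarray,
                     error: float = DEFAULT_ERROR,
                     id1: str = "a", id2: str = "b",
                     ajk: float | None = None) -> DyadScore:
    """Classify one offspring pair as full-sib / half-sib / unrelated.

    Sites missing in either sample or monomorphic in the frequency
    reference are skipped; observed genotypes are a per-allele error
    mixture over the true-pair probabilities.  On exact log-likelihood
    ties the less related relationship wins (conservative against
    false sibship).
    """
    usable = (~np.isnan(x1) & ~np.isnan(x2)
              & np.isfinite(p) & (p > 0.0) & (p < 1.0))
    g1 = x1[usable].astype(int)
    g2 = x2[usable].astype(int)
    pu = p[usable]
    E = genotype_error_matrix(error)
    lnl = {}
    for rel in RELATIONSHIPS:
        Pt = genotype_pair_probs(pu, rel)          # (S, 3, 3)
        Pobs = np.einsum("sab,ax,by->sxy", Pt, E, E)
        lnl[rel] = float(np.log(Pobs[np.arange(len(g1)), g1, g2]).sum())
    best = max(RELATIONSHIPS,
               key=lambda r: (lnl[r], -_TIE_ORDER[r]))
    return DyadScore(id1, id2, lnl, best, int(usable.sum()), ajk)


def paternal_allele_llr(egg1: np.ndarray, egg2: np.ndarray,
                        hen1: np.ndarray, hen2: np.ndarray,
                        p: np.ndarray) -> float:
    """Same-father vs different-fathers log-likelihood ratio.

    At sites where each egg's paternal allele is deducible from its
    hen's genotype (hen homozygous, or hen heterozygous with the egg
    homozygous), compares the probability of the two paternal alleles
    being drawn from one HWE father against two independent HWE
    fathers.  Positive values favour a shared father.
    """

    def deduce(egg: np.ndarray, hen: np.ndarray) -> np.ndarray:
        """Paternal allele (0/1) or NaN where not deducible."""
        pat = np.full(egg.shape, np.nan)
        ok = ~np.isnan(egg) & ~np.isnan(hen)
        hom0 = ok & (hen == 0) & (egg <= 1)
        pat[hom0] = egg[hom0]
        hom2 = ok & (hen == 2) & (egg >= 1)
        pat[hom2] = egg[hom2] - 1
        het = ok & (hen == 1)
        pat[het & (egg == 0)] = 0
        pat[het & (egg == 2)] = 1
        return pat

    a1 = deduce(egg1, hen1)
    a2 = deduce(egg2, hen2)
    use = ~np.isnan(a1) & ~np.isnan(a2) & (p > 0) & (p < 1)
    if not use.any():
        return 0.0
    a1, a2, pu = a1[use], a2[use], p[use]
    # P(a1, a2 | one HWE father): E[(F/2)^alt (1 - F/2)^ref] over F ~ HWE
    p11 = pu ** 2 + pu * (1 - pu) / 2.0
    p10 = pu * (1 - pu) / 2.0
    p00 = (1 - pu) ** 2 + pu * (1 - pu) / 2.0
    same = np.where(a1 + a2 == 2, p11, np.where(a1 + a2 == 0, p00, p10))
    diff = np.where(a1 == 1, pu, 1 - pu) * np.where(a2 == 1, pu, 1 - pu)
    return float(np.log(same).sum() - np.log(diff).sum())


def partition_paternal_groups(
    egg_genos: dict[str, np.ndarray],
    hen_geno: np.ndarray | None,
    p: np.ndarray,
    ajk: dict[tuple[str, str], float] | None = None,
    error: float = DEFAULT_ERROR,
    ambiguity_margin: float = 3.0,
) -> tuple[list[list[str]], list[DyadScore]]:
    """Partition one clutch's maternal eggs into paternal sib-groups.

    Builds a graph over the eggs with an edge where the full-sib
    relationship wins (and the pair's Ajk, when available, clears the
    0.2 floor); paternal lineages are its connected components.  Where
    the full-sib vs half-sib margin is below ``ambiguity_margin`` (in
    log-likelihood units) and the hen genotype is available, the
    paternal-allele consistency likelihood ratio decides the edge.
    Returns the groups (deterministic order) and all dyad scores.
    """
    ids = list(egg_genos)
    if len(ids) <= 1:
        return [ids] if ids else [], []
    scores = []
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b in itertools.combinations(ids, 2):
        pair_ajk = None
        if ajk is not None:
            pair_ajk = ajk.get((a, b), ajk.get((b, a)))
        sc = dyad_likelihoods(egg_genos[a], egg_genos[b], p, error=error,
                              id1=a, id2=b, ajk=pair_ajk)
        scores.append(sc)
        connect = sc.best == "full_sib"
        if abs(sc.lr_fs_hs) < ambiguity_margin and hen_geno is not None:
            llr = paternal_allele_llr(egg_genos[a], egg_genos[b],
                                      hen_geno, hen_geno, p)
            connect = llr > 0.0
        if connect and pair_ajk is not None and not pair_ajk > DYAD_AJK_FLOOR:
            connect = False
        if connect:
            g.add_edge(a, b)
    comps = sorted(nx.connected_components(g),
                   key=lambda c: ids.index(min(c, key=ids.index)))
    groups = [sorted(c, key=ids.index) for c in comps]
    groups.sort(key=lambda c: (-len(c), ids.index(c[0])))
    return groups, scores


def link_cross_nest_lineages(
    lineages: list[PaternalLineage],
    egg_genos: dict[str, np.ndarray],
    hen_genos: dict[str, np.ndarray | None],
    p: np.ndarray,
    ajk: dict[tuple[str, str], float] | None = None,
    error: float = DEFAULT_ERROR,
    ajk_band: tuple[float, float] = (0.15, 0.40),
) -> dict[str, str]:
    """Merge paternal lineages shared across nests.

    Two lineages from different mothers merge when their inter-lineage
    egg dyads are predominantly half-sib with median Ajk inside
    ``ajk_band`` and the paternal-allele LR favours one father
    (a promiscuous male).  Two lineages from the same mother (a
    renesting hen's clutches) merge when the cross dyads are
    predominantly full-sib.  Returns lineage_id -> merged id (the
    lexicographically first member of each merged set).
    """
    parent = {ln.lineage_id: ln.lineage_id for ln in lineages}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for la, lb in itertools.combinations(lineages, 2):
        pairs = [(a, b) for a in la.egg_ids for b in lb.egg_ids]
        if not pairs:
            continue
        same_mother = (la.mother_id is not None
                       and la.mother_id == lb.mother_id)
        if ajk is not None and not same_mother:
            # cheap prescreen: lineage pairs whose cross-pair Ajk sits at
            # the unrelated baseline cannot share a father
            pre = [ajk.get((a, b), ajk.get((b, a))) for a, b in pairs]
            pre = [v for v in pre if v is not None and np.isfinite(v)]
            if pre and np.median(pre) <= 0.10:
                continue
        best_counts = {r: 0 for r in RELATIONSHIPS}
        ajks, llrs = [], []
        for a, b in pairs:
            pair_ajk = None
            if ajk is not None:
                pair_ajk = ajk.get((a, b), ajk.get((b, a)))
            sc = dyad_likelihoods(egg_genos[a], egg_genos[b], p,
                                  error=error, id1=a, id2=b)
            best_counts[sc.best] += 1
            if pair_ajk is not None:
                ajks.append(pair_ajk)
            ha = hen_genos.get(la.mother_id)
            hb = hen_genos.get(lb.mother_id)
            if ha is not None and hb is not None:
                llrs.append(paternal_allele_llr(
                    egg_genos[a], egg_genos[b], ha, hb, p))
        n = len(pairs)
        if same_mother:
            merge = best_counts["full_sib"] >= n / 2.0
        else:
            hs_majority = best_counts["half_sib"] >= n / 2.0
            med_ajk = float(np.median(ajks)) if ajks else None
            in_band = (med_ajk is None
                       or ajk_band[0] < med_ajk < ajk_band[1])
            llr_ok = (not llrs) or float(np.median(llrs)) > 0.0
            merge = hs_majority and in_band and llr_ok
        if merge:
            ra, rb = find(la.lineage_id), find(lb.lineage_id)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    return {ln.lineage_id: find(ln.lineage_id) for ln in lineages}


def detect_renesting(lineages: list[PaternalLineage],
                     merged: dict[str, str]) -> pd.DataFrame:
    """Report, per hen with multiple clutches, whether the father is shared.

    A renesting pair re-uses the same paternal lineage across both
    nesting attempts; a hen whose clutches resolve to different merged
    lineages changed mates between attempts.
    """
    by_mother: dict[str, list[PaternalLineage]] = {}
    for ln in lineages:
        if ln.mother_id is not None:
            by_mother.setdefault(ln.mother_id, []).append(ln)
    rows = []
    for mother, lns in sorted(by_mother.items()):
        nests = sorted({n for ln in lns for n in ln.nest_ids})
        if len(nests) < 2:
            continue
        primary_by_nest = {}
        for nest in nests:
            cands = [ln for ln in lns if nest in ln.nest_ids]
            primary = max(cands, key=lambda l: len(l.egg_ids))
            primary_by_nest[nest] = merged[primary.lineage_id]
        shared = len(set(primary_by_nest.values())) == 1
        rows.append({"hen_id": mother, "nest_ids": nests,
                     "shared_father": shared,
                     "primary_lineages": primary_by_nest})
    return pd.DataFrame(rows, columns=["hen_id", "nest_ids",
                                       "shared_father", "primary_lineages"])


def dyad_table(scores: list[DyadScore]) -> pd.DataFrame:
    """Long-format dyad report (one row per pair)."""
    return pd.DataFrame([{
        "id1": s.id1, "id2": s.id2,
        "lnL_FS": s.lnl["full_sib"], "lnL_HS": s.lnl["half_sib"],
        "lnL_U": s.lnl["unrelated"], "best": s.best,
        "n_sites": s.n_sites, "ajk": s.ajk,
    } for s in scores])
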