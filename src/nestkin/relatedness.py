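"""Pairwise relatedness (unadjusted Ajk) and family clustering.

The Ajk statistic of Yang et al. (the VCFtools ``--relatedness``
estimator) measures genome-wide relatedness from allele-frequency-
standardised dosages: ~0 for unrelated pairs, ~0.25 for second-degree,
~0.5 for first-degree relatives.  Family groups are recovered as
single-linkage connected components over high-Ajk edges, which also
exposes clutches laid by an unsampled outside hen.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix


@dataclass
class AjkMatrix:
    """Symmetric pairwise Ajk relatedness with per-pair usable-site counts."""

    sample_ids: list[str]
    values: np.ndarray   # (N, N) floats; NaN where no usable site exists
    n_sites: np.ndarray  # (N, N) ints: usable sites per pair

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table in the VCFtools --relatedness layout."""
        rows = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i, n):
                rows.append((self.sample_ids[i], self.sample_ids[j],
                             int(self.n_sites[i, j]), self.values[i, j]))
        return pd.DataFrame(
            rows, columns=["INDV1", "INDV2", "N_SITES", "RELATEDNESS_AJK"])


def ajk_matrix(M: GenotypeMatrix, freqs: np.ndarray | None = None) -> AjkMatrix:
    """Unadjusted Ajk relatedness over all sample pairs.

    Off-diagonal ``A_jk = mean_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i))``
    and diagonal ``A_jj = mean_i (x_ij^2 - (1 + 2p_i) x_ij + 2 p_i^2) /
    (2 p_i (1 - p_i))``, where ``p_i`` is the alt-allele frequency
    estimated from the samples in ``M`` (or supplied via ``freqs``).
    Sites fixed in the frequency reference, or missing in either member
    of a pair, are skipped for that pair; means are over each pair's own
    usable-site count.  Pairs with no usable site are NaN.
    """
    if M.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = M.allele_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    valid = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not valid.any():
        raise ValueError("no polymorphic site available")
    X = M.dosages[valid]
    p = p[valid]
    denom = 2.0 * p * (1.0 - p)

    called = ~np.isnan(X)
    Z = np.where(called, (X - 2.0 * p[:, None]) / np.sqrt(denom)[:, None], 0.0)
    num = Z.T @ Z
    counts = called.astype(float).T @ called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = num / counts
    A[counts == 0] = np.nan

    # diagonal uses the self-relatedness form, not the cross-product
    diag_term = np.where(
        called,
        (X**2 - (1.0 + 2.0 * p[:, None]) * X + 2.0 * p[:, None]**2)
        / denom[:, None],
        0.0,
    )
    diag_counts = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = diag_term.sum(axis=0) / diag_counts
    np.fill_diagonal(A, np.where(diag_counts > 0, diag, np.nan))
    np.fill_diagonal(counts, diag_counts)
    return AjkMatrix(list(M.sample_ids), A, counts.astype(int))


def family_clusters(A: AjkMatrix, threshold: float = 0.35) -> dict[str, int]:
    """Single-linkage family groups: components of the Ajk > threshold graph.

    The default threshold (0.35) sits between the half-sib (~0.25) and
    first-degree (~0.5) expectations.  Returns sample -> cluster index;
    indices are assigned in order of each cluster's first sample, so the
    labelling is invariant to internal graph ordering.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    g = nx.Graph()
    g.add_nodes_from(A.sample_ids)
    n = len(A.sample_ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = A.values[i, j]
            if np.isfinite(v) and v > threshold:
                g.add_edge(A.sample_ids[i], A.sample_ids[j])
    comps = sorted(nx.connected_components(g),
                   key=lambda c: min(A.sample_ids.index(s) for s in c))
    return {s: k for k, comp in enumerate(comps) for s in comp}


def detect_unsampled_mother_groups(
    clusters: dict[str, int],
    nest_table: pd.DataFrame,
    maternity_accept: dict[str, bool | None],
) -> pd.DataFrame:
    """Find clutches laid by an unsampled hen inside a sampled nest.

    Any family cluster containing >= 2 eggs that sit in one nest and
    each fail maternity against the resident hen is reported as an
    inferred-unsampled-mother group, with a generated maternal lineage
    id of the form ``<nest>.2``.  Singleton failures are reported with a
    null group id (flagged individually, no group formed).
    """
    eggs = nest_table[nest_table["role"] == "offspring"]
    failed = eggs[eggs["sample_id"].map(
        lambda s: maternity_accept.get(s) is False)]
    rows = []
    for nest, sub in failed.groupby("nest_id"):
        by_cluster: dict[int, list[str]] = {}
        for s in sub["sample_id"]:
            by_cluster.setdefault(clusters.get(s, -1), []).append(s)
        k = 2
        for cl, members in sorted(by_cluster.items()):
            if len(members) >= 2:
                rows.append({"group_id": f"{nest}.{k}", "nest_id": nest,
                             "cluster": cl, "egg_ids": sorted(members)})
                k += 1
            else:
                rows.append({"group_id": None, "nest_id": nest,
                             "cluster": cl, "egg_ids": sorted(members)})
    return pd.DataFrame(rows, columns=["group_id", "nest_id", "cluster",
                                       "egg_ids"])
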