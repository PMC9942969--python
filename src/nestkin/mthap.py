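"""mtDNA control-region haplotypes: collapsing, networks, haplogroups.

Aligned control-region sequences are collapsed into exact-match
haplotypes (alignment columns carrying a gap or N in any sequence are
excluded from comparison), connected into a minimum spanning network
under Hamming distance, assigned to the Old World A / New World B
haplogroups by nearest labelled reference, and screened for hen-
offspring haplotype mismatches within nests — the maternal-inheritance
signal of conspecific nest parasitism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

IUPAC_MISSING = set("-N?.")


@dataclass
class HaplotypeSet:
    """Exact-match haplotype partition of an alignment."""

    haplotypes: dict[str, str]        # haplotype id -> comparable sequence
    assignment: dict[str, str]        # sample -> haplotype id
    used_columns: np.ndarray          # alignment columns used for comparison

    @property
    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {h: 0 for h in self.haplotypes}
        for h in self.assignment.values():
            c[h] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, h) for s, h in self.assignment.items()],
            columns=["sample_id", "haplotype"])


def read_fasta(path: str) -> dict[str, str]:
    """Aligned FASTA -> {name: sequence} (Biopython reader)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def collapse_haplotypes(sequences: dict[str, str] | str) -> HaplotypeSet:
    """Group identical sequences into haplotypes.

    Accepts a mapping or a FASTA path.  Sequences are uppercased; any
    alignment column containing a gap, N, ? or . in any sequence is
    dropped from the comparison (and logged).  Haplotype ids are H1,
    H2, ... in order of first appearance.
    """
    if isinstance(sequences, str):
        sequences = read_fasta(sequences)
    if not sequences:
        raise ValueError("no sequences provided")
    seqs = {k: v.upper() for k, v in sequences.items()}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        detail = ", ".join(f"{k}={len(v)}" for k, v in list(seqs.items())[:5])
        raise ValueError(f"sequences are not aligned to one length ({detail})")
    arr = np.array([list(s) for s in seqs.values()])
    bad = np.zeros(arr.shape[1], dtype=bool)
    for ch in IUPAC_MISSING:
        bad |= (arr == ch).any(axis=0)
    used = np.flatnonzero(~bad)
    if bad.any():
        log.info("excluded %d alignment column(s) with gaps/N", int(bad.sum()))
    haplotypes: dict[str, str] = {}
    key_to_id: dict[str, str] = {}
    assignment: dict[str, str] = {}
    for name, s in seqs.items():
        key = "".join(s[i] for i in used)
        if key not in key_to_id:
            hid = f"H{len(key_to_id) + 1}"
            key_to_id[key] = hid
            haplotypes[hid] = key
        assignment[name] = key_to_id[key]
    return HaplotypeSet(haplotypes, assignment, used)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def build_network(H: HaplotypeSet) -> nx.Graph:
    """Minimum spanning network over haplotypes under Hamming distance.

    Kruskal by weight class: edges of a given distance are admitted when
    their endpoints are in different components of the strictly-shorter-
    edge graph, and components merge only after the whole class is
    processed — so all tied minimum spanning edges are retained and the
    result is a network, not a single tree.  Total weight of any
    spanning tree inside the network equals the MST weight.
    """
    ids = list(H.haplotypes)
    g = nx.Graph()
    counts = H.counts
    for h in ids:
        g.add_node(h, count=counts[h])
    if len(ids) <= 1:
        return g
    dists = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dists.append((hamming(H.haplotypes[ids[i]], H.haplotypes[ids[j]]),
                          ids[i], ids[j]))
    parent = {h: h for h in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    dists.sort(key=lambda t: t[0])
    i = 0
    while i < len(dists):
        w = dists[i][0]
        cls = []
        while i < len(dists) and dists[i][0] == w:
            cls.append(dists[i])
            i += 1
        added = []
        for _, a, b in cls:
            if find(a) != find(b):
                g.add_edge(a, b, weight=w)
                added.append((a, b))
        for a, b in added:
            parent[find(a)] = find(b)
    return g


def assign_haplogroup(H: HaplotypeSet,
                      references: dict[str, str]) -> dict[str, str | None]:
    """Nearest-reference haplogroup per haplotype (ties -> unassigned).

    ``references`` maps a haplogroup label (e.g. ``OW-A``, ``NW-B``) to
    a representative full-length sequence; reference sequences are
    restricted to the columns used by the haplotype set.
    """
    if not references:
        raise ValueError("no reference haplotypes supplied")
    refs = {}
    for label, seq in references.items():
        seq = seq.upper()
        if len(seq) > len(H.used_columns):
            seq = "".join(seq[i] for i in H.used_columns)
        refs[label] = seq
    out: dict[str, str | None] = {}
    for hid, seq in H.haplotypes.items():
        d = {label: hamming(seq, rseq) for label, rseq in refs.items()}
        best = min(d.values())
        winners = [label for label, v in d.items() if v == best]
        if len(winners) > 1:
            log.warning("haplotype %s equidistant from %s; unassigned",
                        hid, winners)
            out[hid] = None
        else:
            out[hid] = winners[0]
    return out


def nest_mismatches(H: HaplotypeSet,
                    nest_table: pd.DataFrame) -> pd.DataFrame:
    """Per-nest hen-offspring haplotype comparison.

    For each nest: the hen's haplotype (or, when the hen is unsampled,
    the clutch-majority haplotype; a tie is flagged indeterminate), the
    offspring haplotype counts, and the eggs whose haplotype differs
    from the maternal one.
    """
    rows = []
    for nest, sub in nest_table.groupby("nest_id", sort=True):
        hens = sub[sub["role"] == "hen"]["sample_id"].tolist()
        eggs = sub[sub["role"] == "offspring"]["sample_id"].tolist()
        egg_haps = {e: H.assignment[e] for e in eggs if e in H.assignment}
        hen_hap: str | None = None
        indeterminate = False
        if hens and hens[0] in H.assignment:
            hen_hap = H.assignment[hens[0]]
        else:
            counts = pd.Series(list(egg_haps.values())).value_counts()
            if len(counts) and (len(counts) == 1
                                or counts.iloc[0] > counts.iloc[1]):
                hen_hap = str(counts.index[0])
            else:
                indeterminate = True
        mism = sorted(e for e, h in egg_haps.items() if h != hen_hap) \
            if hen_hap is not None else []
        rows.append({
            "nest_id": nest,
            "hen_haplotype": hen_hap,
            "hen_sampled": bool(hens and hens[0] in H.assignment),
            "offspring_haplotypes": dict(
                pd.Series(list(egg_haps.values())).value_counts()),
            "mismatch_eggs": mism,
            "indeterminate": indeterminate,
        })
    return pd.DataFrame(rows)


def write_network(g: nx.Graph, edge_tsv: str,
                  graphml: str | None = None) -> None:
    rows = [(a, b, d["weight"]) for a, b, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["haplotype1", "haplotype2", "steps"]).to_csv(
        edge_tsv, sep="\t", index=False)
    if graphml:
        nx.write_graphml(g, graphml)
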