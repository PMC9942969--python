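"""End-to-end orchestration: filter -> relatedness -> ancestry -> mtDNA ->
parentage -> strategy classification -> population statistics.

The pipeline runs either on files (VCF + mtDNA FASTA + nest CSV + panel
labels) or on a simulated study, under one seed, and produces a report
bundle whose centrepiece is the pairing table (per-nest maternal
lineage with inferred paternal lineages, egg counts and species
labels) and the population-rate summary.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import genodata, mthap, parentage, popstats, relatedness, strategies
from .genodata import FilterSpec, GenotypeMatrix
from .synthgen import SimConfig, SimResult, simulate_study

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs (or a simulate block), per-stage thresholds, seed, output."""

    # either explicit inputs ...
    vcf: str | None = None
    mtdna_fasta: str | None = None
    nest_csv: str | None = None
    panel_csv: str | None = None
    haplogroup_refs_fasta: str | None = None
    # ... or a simulation
    simulate: SimConfig | None = None

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    ld_r2: float = 0.5
    parentage_min_maf: float = 0.45
    family_threshold: float = 0.35
    maternity_allowance: float = 0.01
    dyad_error: float = parentage.DEFAULT_ERROR
    purity_threshold: float = 0.98
    n_boot: int = 10
    run_ancestry: bool = True
    link_lineages: bool = True
    run_popstats: bool = True
    seed: int = 1
    outdir: str | None = None

    def __post_init__(self) -> None:
        has_inputs = self.vcf is not None
        if has_inputs == (self.simulate is not None):
            raise ValueError("provide either input paths or a simulate block")


@dataclass
class PipelineResult:
    config: PipelineConfig
    ajk: relatedness.AjkMatrix
    clusters: dict[str, int]
    maternity: dict[str, parentage.MaternityResult]
    haplotype_set: mthap.HaplotypeSet
    nest_mismatch: pd.DataFrame
    egg_origins: dict[str, str]
    lineages: list[parentage.PaternalLineage]
    merged_lineages: dict[str, str]
    renesting: pd.DataFrame
    calls: list[strategies.StrategyCall]
    pairing_table: strategies.PairingTable
    rates: dict
    ancestry_table: pd.DataFrame | None = None
    lineage_species: dict[str, str] | None = None
    maternal_species: dict[str, str] | None = None
    pi: dict[str, float] | None = None
    fst: pd.DataFrame | None = None
    nest_net: popstats.NestNetwork | None = None
    sex_clutch: popstats.SexClutchSummary | None = None
    n_sites: dict[str, int] = field(default_factory=dict)
    sim: SimResult | None = None   # kept when run in simulate mode

    def calls_by_nest(self) -> dict[str, str]:
        return {c.nest_id: c.label for c in self.calls}


def _load_inputs(cfg: PipelineConfig):
    for name in ("vcf", "mtdna_fasta", "nest_csv", "panel_csv"):
        path = getattr(cfg, name)
        if path is not None and not os.path.exists(path):
            raise FileNotFoundError(f"{name} input not found: {path}")
    M = genodata.read_vcf(cfg.vcf)
    mtdna = mthap.read_fasta(cfg.mtdna_fasta) if cfg.mtdna_fasta else {}
    nest_table = pd.read_csv(cfg.nest_csv)
    panel_labels = {}
    if cfg.panel_csv:
        pl = pd.read_csv(cfg.panel_csv)
        panel_labels = dict(zip(pl["sample_id"], pl["population"]))
    hap_refs = {}
    if cfg.haplogroup_refs_fasta:
        hap_refs = mthap.read_fasta(cfg.haplogroup_refs_fasta)
    return M, panel_labels, nest_table, mtdna, hap_refs


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full inference chain and (optionally) write the report."""
    handler = None
    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        handler = logging.FileHandler(
            os.path.join(cfg.outdir, "pipeline.log"))
        handler.setLevel(logging.INFO)
        logging.getLogger("nestkin").addHandler(handler)
    try:
        sim = None
        if cfg.simulate is not None:
            sim = simulate_study(cfg.simulate)
            M, panel_labels, nest_table = (sim.genotypes, sim.panel_labels,
                                           sim.nest_table)
            mtdna, hap_refs = sim.mtdna, dict(sim.mtdna_pool.centers)
        else:
            M, panel_labels, nest_table, mtdna, hap_refs = _load_inputs(cfg)

        res = analyze_study(M, panel_labels, nest_table, mtdna, hap_refs, cfg)
        res.sim = sim
        if cfg.outdir:
            write_report(res, cfg.outdir)
    finally:
        if handler is not None:
            logging.getLogger("nestkin").removeHandler(handler)
            handler.close()
    return res


def analyze_study(M: GenotypeMatrix, panel_labels: dict[str, str],
                  nest_table: pd.DataFrame, mtdna: dict[str, str],
                  haplogroup_refs: dict[str, str],
                  cfg: PipelineConfig | None = None) -> PipelineResult:
    """The inference chain on in-memory inputs (the library entry point)."""
    cfg = cfg or PipelineConfig(simulate=SimConfig())
    n_sites_used: dict[str, int] = {"input": M.n_sites}

    focal_ids = list(dict.fromkeys(nest_table["sample_id"]))
    hens_by_nest = {n: sub[sub["role"] == "hen"]["sample_id"].tolist()
                    for n, sub in nest_table.groupby("nest_id")}
    eggs_by_nest = {n: sub[sub["role"] == "offspring"]["sample_id"].tolist()
                    for n, sub in nest_table.groupby("nest_id")}

    # --- site filtering on the focal set ------------------------------
    Mf = M.subset_samples(focal_ids)
    Mf_filt, _report = genodata.filter_sites(Mf, cfg.filter_spec)
    Mrel = genodata.ld_prune(Mf_filt, r2_threshold=cfg.ld_r2, seed=cfg.seed)
    Mpar = genodata.select_parentage_sites(Mf_filt, cfg.parentage_min_maf)
    n_sites_used["relatedness"] = Mrel.n_sites
    n_sites_used["parentage"] = Mpar.n_sites
    log.info("sites: %d input, %d relatedness, %d parentage",
             M.n_sites, Mrel.n_sites, Mpar.n_sites)

    # --- relatedness ---------------------------------------------------
    A = relatedness.ajk_matrix(Mrel)
    clusters = relatedness.family_clusters(A, cfg.family_threshold)
    ajk_lookup = {}
    for i, a in enumerate(A.sample_ids):
        for j in range(i + 1, len(A.sample_ids)):
            ajk_lookup[(a, A.sample_ids[j])] = float(A.values[i, j])

    def pair_ajk(a: str, b: str) -> float | None:
        return ajk_lookup.get((a, b), ajk_lookup.get((b, a)))

    # --- maternity -----------------------------------------------------
    par_idx = {s: j for j, s in enumerate(Mpar.sample_ids)}
    p_par = Mpar.allele_freqs()

    def par_geno(sid: str) -> np.ndarray:
        return Mpar.dosages[:, par_idx[sid]]

    maternity: dict[str, parentage.MaternityResult] = {}
    for nest, eggs in eggs_by_nest.items():
        hens = hens_by_nest.get(nest, [])
        hen = hens[0] if hens else None
        for egg in eggs:
            if hen is None:
                maternity[egg] = parentage.MaternityResult(
                    "", egg, None, np.nan, 0, 0)
                continue
            maternity[egg] = parentage.maternity_check(
                par_geno(hen), par_geno(egg),
                error_allowance=cfg.maternity_allowance,
                ajk=pair_ajk(hen, egg), hen_id=hen, egg_id=egg)

    # --- mtDNA ---------------------------------------------------------
    H = mthap.collapse_haplotypes(mtdna) if mtdna else None
    if H is not None:
        mism_table = mthap.nest_mismatches(H, nest_table)
        mtdna_mismatch: dict[str, bool | None] = {}
        for _, row in mism_table.iterrows():
            if row["indeterminate"]:
                for egg in eggs_by_nest.get(row["nest_id"], []):
                    mtdna_mismatch[egg] = None
            else:
                for egg in eggs_by_nest.get(row["nest_id"], []):
                    mtdna_mismatch[egg] = egg in row["mismatch_eggs"]
    else:
        mism_table = pd.DataFrame()
        mtdna_mismatch = {}

    # --- egg classification -------------------------------------------
    all_eggs = [e for eggs in eggs_by_nest.values() for e in eggs]
    accept = {e: m.accept for e, m in maternity.items()}
    origins = strategies.classify_eggs(accept, mtdna_mismatch, all_eggs)

    # --- paternal partitioning ----------------------------------------
    lineages: list[parentage.PaternalLineage] = []
    resident_lineage: dict[str, str] = {}
    k = 0
    for nest in sorted(eggs_by_nest):
        eggs = eggs_by_nest[nest]
        hens = hens_by_nest.get(nest, [])
        hen = hens[0] if hens else None
        resident = [e for e in eggs if origins[e] == "resident_maternal"]
        foreign = [e for e in eggs if origins[e] in ("parasitic",)]
        groups, _ = parentage.partition_paternal_groups(
            {e: par_geno(e) for e in resident},
            par_geno(hen) if hen else None,
            p_par, ajk=ajk_lookup, error=cfg.dyad_error)
        for grp in groups:
            k += 1
            lid = f"L{k:02d}"
            lineages.append(parentage.PaternalLineage(
                lid, grp, [nest], mother_id=hen))
            resident_lineage.update({e: lid for e in grp})
        if foreign:
            fgroups, _ = parentage.partition_paternal_groups(
                {e: par_geno(e) for e in foreign}, None,
                p_par, ajk=ajk_lookup, error=cfg.dyad_error)
            for grp in fgroups:
                k += 1
                lid = f"L{k:02d}"
                lineages.append(parentage.PaternalLineage(
                    lid, grp, [nest], mother_id=f"{nest}.2"))

    # --- cross-nest lineage linking & renesting -----------------------
    egg_genos = {e: par_geno(e) for e in all_eggs}
    hen_genos = {}
    for ln in lineages:
        if ln.mother_id in par_idx:
            hen_genos[ln.mother_id] = par_geno(ln.mother_id)
        else:
            hen_genos[ln.mother_id] = None
    if cfg.link_lineages and lineages:
        merged = parentage.link_cross_nest_lineages(
            lineages, egg_genos, hen_genos, p_par, ajk=ajk_lookup,
            error=cfg.dyad_error)
    else:
        merged = {ln.lineage_id: ln.lineage_id for ln in lineages}
    renest = parentage.detect_renesting(lineages, merged)

    # --- unsampled-mother groups --------------------------------------
    relatedness.detect_unsampled_mother_groups(clusters, nest_table, accept)

    # --- strategy calls ------------------------------------------------
    calls = []
    for nest in sorted(eggs_by_nest):
        nest_origins = {e: origins[e] for e in eggs_by_nest[nest]}
        calls.append(strategies.classify_nest(nest, nest_origins,
                                              resident_lineage))

    # --- ancestry ------------------------------------------------------
    anc_table = None
    qvs: dict[str, anc.QVector] = {}
    maternal_species: dict[str, str] = {}
    lineage_species: dict[str, str] = {}
    if cfg.run_ancestry and panel_labels:
        Mall, _ = genodata.filter_sites(M, cfg.filter_spec)
        Manc = genodata.ld_prune(Mall, r2_threshold=cfg.ld_r2, seed=cfg.seed)
        n_sites_used["ancestry"] = Manc.n_sites
        anc_table, qvs = anc.joint_analyze_samples(
            Manc, panel_labels, focal_ids, threshold=cfg.purity_threshold,
            n_boot=cfg.n_boot, seed=cfg.seed)
        for hen_list in hens_by_nest.values():
            for hen in hen_list:
                maternal_species[hen] = anc.purity_call(
                    qvs[hen], cfg.purity_threshold).label
        for ln in lineages:
            offspring_q = [qvs[e] for e in ln.egg_ids if e in qvs]
            if not offspring_q:
                continue
            if ln.mother_id in qvs:
                father_q = anc.infer_paternal_q(qvs[ln.mother_id], offspring_q)
                lineage_species[ln.lineage_id] = anc.purity_call(
                    father_q, cfg.purity_threshold).label
            else:
                # unsampled mother: the offspring mean is the best available
                # proxy for the parental ancestry (mother ~ father ~ mean)
                mean_q = np.vstack([o.q for o in offspring_q]).mean(axis=0)
                proxy = anc.QVector(q=mean_q, se=np.zeros_like(mean_q))
                lineage_species[ln.lineage_id] = anc.purity_call(
                    proxy, cfg.purity_threshold).label

    # --- pairing table -------------------------------------------------
    pt = build_pairing_table(nest_table, lineages, merged,
                             maternal_species, lineage_species, origins)
    rates = strategies.population_rates(calls, pt)

    # --- population statistics ----------------------------------------
    pi = fst = net = sexes = None
    if cfg.run_popstats:
        groups = {}
        for pop in sorted(set(panel_labels.values())):
            groups[pop] = [s for s, p in panel_labels.items() if p == pop]
        groups["NC"] = focal_ids
        Msub, _ = genodata.filter_sites(M, cfg.filter_spec)
        pi = {g: popstats.nucleotide_diversity(Msub, ids)
              for g, ids in groups.items()}
        fst = popstats.pairwise_fst(Msub, groups)
        nest_groups = {n: (hens_by_nest.get(n, []) + eggs_by_nest[n])
                       for n in sorted(eggs_by_nest)}
        net = popstats.nest_network(Mrel, nest_groups) \
            if len(nest_groups) >= 3 else None
        parasitic = {e for e, o in origins.items() if o == "parasitic"}
        sexes = popstats.sex_and_clutch_summary(nest_table, parasitic)

    return PipelineResult(
        config=cfg, ajk=A, clusters=clusters, maternity=maternity,
        haplotype_set=H, nest_mismatch=mism_table, egg_origins=origins,
        lineages=lineages, merged_lineages=merged, renesting=renest,
        calls=calls, pairing_table=pt, rates=rates,
        ancestry_table=anc_table, lineage_species=lineage_species or None,
        maternal_species=maternal_species or None,
        pi=pi, fst=fst, nest_net=net, sex_clutch=sexes,
        n_sites=n_sites_used,
    )


def build_pairing_table(nest_table: pd.DataFrame,
                        lineages: list[parentage.PaternalLineage],
                        merged: dict[str, str],
                        maternal_species: dict[str, str],
                        lineage_species: dict[str, str],
                        origins: dict[str, str]) -> strategies.PairingTable:
    """Assemble the pairing table from inferred lineages.

    One row per maternal lineage: sampled hens (all their nests
    combined) and inferred unsampled mothers (parasitic clutches,
    pointing at their host nest).
    """
    hen_nests: dict[str, list[str]] = {}
    for _, row in nest_table[nest_table["role"] == "hen"].iterrows():
        hen_nests.setdefault(row["sample_id"], []).append(row["nest_id"])

    by_mother: dict[str, list[parentage.PaternalLineage]] = {}
    for ln in lineages:
        by_mother.setdefault(ln.mother_id, []).append(ln)

    rows = []
    for mother, lns in sorted(by_mother.items(), key=lambda kv: str(kv[0])):
        sampled = mother in hen_nests
        nests = sorted({n for ln in lns for n in ln.nest_ids})
        paternal: dict[str, int] = {}
        for ln in lns:
            mid = merged[ln.lineage_id]
            paternal[mid] = paternal.get(mid, 0) + len(ln.egg_ids)
        plist = [(mid, cnt, lineage_species.get(mid, "NA"))
                 for mid, cnt in sorted(paternal.items())]
        rows.append({
            "nest_id": "+".join(nests) if sampled else f"{nests[0]}.2",
            "maternal_lineage": mother,
            "maternal_species": maternal_species.get(mother, "NA"),
            "hen_sampled": sampled,
            "paternal": plist,
            "parasitic_clutch": not sampled,
            "host_nest": "" if sampled else nests[0],
            "note": "",
        })
    columns = ["nest_id", "maternal_lineage", "maternal_species",
               "hen_sampled", "paternal", "parasitic_clutch", "host_nest",
               "note"]
    return strategies.PairingTable(pd.DataFrame(rows, columns=columns))


def write_report(res: PipelineResult, outdir: str) -> str:
    """Write per-stage artifacts plus a consolidated markdown report."""
    os.makedirs(outdir, exist_ok=True)
    res.ajk.to_frame().to_csv(os.path.join(outdir, "relatedness.tsv"),
                              sep="\t", index=False)
    pd.Series(res.clusters, name="cluster").rename_axis("sample_id") \
        .to_csv(os.path.join(outdir, "family_clusters.csv"))
    res.pairing_table.to_csv(os.path.join(outdir, "pairing_table.csv"))
    if res.ancestry_table is not None:
        res.ancestry_table.to_csv(os.path.join(outdir, "ancestry.tsv"),
                                  sep="\t", index=False)
    if res.nest_net is not None:
        import networkx as nx

        rows = [(a, b, d["weight"])
                for a, b, d in res.nest_net.mst.edges(data=True)]
        pd.DataFrame(rows, columns=["nest1", "nest2", "fst"]).to_csv(
            os.path.join(outdir, "nest_network_mst.tsv"), sep="\t",
            index=False)
        nx.write_graphml(res.nest_net.graph,
                         os.path.join(outdir, "nest_network.graphml"))
    with open(os.path.join(outdir, "rates.json"), "w") as fh:
        json.dump(res.rates, fh, indent=1, default=str)

    lines = ["# nestkin pipeline report", ""]
    lines.append("## Site counts")
    for stage, n in res.n_sites.items():
        lines.append(f"- {stage}: {n} sites")
    lines += ["", "## Nest strategy calls", ""]
    for c in res.calls:
        lines.append(f"- {c.nest_id}: {c.label} "
                     f"({c.n_resident} resident / {c.n_parasitic} parasitic "
                     f"/ {c.n_ambiguous} ambiguous eggs; "
                     f"{c.n_paternal_lineages} paternal lineage(s))")
    lines += ["", "## Population rates", ""]
    for key, val in res.rates.items():
        if isinstance(val, dict) and "count" in val:
            lines.append(f"- {key}: {val['count']} of {val['denominator']} "
                         f"({val['pct']:.1f}%)")
        else:
            lines.append(f"- {key}: {val}")
    if res.sex_clutch is not None:
        sc = res.sex_clutch
        lines += ["", "## Sex ratio and clutch size", "",
                  f"- {sc.n_male} males / {sc.n_female} females; exact "
                  f"binomial p = {sc.binom_p:.3f} (t = {sc.t_stat:.2f}, "
                  f"p = {sc.t_p:.3f})",
                  f"- clutch size mean {sc.clutch_mean:.1f} "
                  f"(range {sc.clutch_min}-{sc.clutch_max}) over "
                  f"{sc.n_nests} nests"]
    path = os.path.join(outdir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
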