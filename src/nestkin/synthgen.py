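"""Synthetic nesting-duck study generator.

Emulates the sampling design of a coastal brood study: three reference
panels (American black duck ``ABDU``, wild mallard ``WMA``, game-farm
mallard ``GFM``) with low nuclear divergence, a set of nests with known
mating strategies (monogamy, extra-pair copulation, conspecific nest
parasitism, renesting, cross-nest shared fathers), Mendelian SNP
genotypes with genotyping error and missingness, and a small two-
haplogroup mtDNA control-region haplotype pool inherited maternally.

Every downstream inference stage can therefore be tested against the
generator's ground truth without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, write_vcf

POPS = ("ABDU", "WMA", "GFM")
#: father species are drawn from this distribution (pure black duck
#: majority with occasional wild-mallard or F1 sires)
FATHER_SPECIES = (("ABDU", 0.8), ("WMA", 0.1), ("ABDUxWMA", 0.1))

NW_LABEL = "NW-B"
OW_LABEL = "OW-A"


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the field conditions the pipeline is meant to
    resolve: ~2,000 ddRAD-like biallelic SNPs, 50 reference birds per
    panel, 19 nests with clutches of 5-13 eggs, 35% of nests with a
    single extra-pair egg, two parasitized nests, one promiscuous father
    shared between two nests, one renesting hen, ~15% F1-hybrid hens,
    2% missing genotypes, 0.5% per-allele genotyping error, and a
    625 bp mtDNA region carrying 7 New World B and 1 Old World A
    haplotypes ~15 mutations apart.
    """

    n_sites: int = 2000
    n_ref_per_pop: int = 50
    fst_abdu_wma: float = 0.02
    fst_gfm: float = 0.10
    n_nests: int = 19
    clutch_min: int = 5
    clutch_max: int = 13
    prop_monogamous: float = 0.65
    prop_epc: float = 0.35
    n_parasitized: int = 2
    n_shared_father_pairs: int = 1
    n_renest_hens: int = 1
    hybrid_hen_fraction: float = 0.15
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.005
    mtdna_length: int = 625
    n_nw_haplotypes: int = 7
    n_ow_haplotypes: int = 1
    haplogroup_divergence: int = 15
    epc_eggs_per_nest: int = 1
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("prop_monogamous", "prop_epc", "hybrid_hen_fraction",
                     "missing_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be a proportion in [0, 1]")
        for name in ("fst_abdu_wma", "fst_gfm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1)")
        if self.prop_monogamous + self.prop_epc > 1.0 + 1e-9:
            raise ValueError("prop_monogamous + prop_epc must be <= 1")
        if self.clutch_min > self.clutch_max or self.clutch_min < 1:
            raise ValueError("require 1 <= clutch_min <= clutch_max")
        if self.n_parasitized > self.n_nests:
            raise ValueError("n_parasitized cannot exceed n_nests")
        if self.n_renest_hens >= self.n_nests:
            raise ValueError("n_renest_hens must be < n_nests")
        if self.haplogroup_divergence > self.mtdna_length:
            raise ValueError("haplogroup divergence exceeds mtDNA length")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class MtdnaPool:
    """mtDNA haplotype pool: sequences, haplogroup labels, group centers."""

    sequences: dict[str, str]
    haplogroups: dict[str, str]
    centers: dict[str, str]  # haplogroup label -> central sequence


@dataclass
class TruthTable:
    """Simulator ground truth for recovery tests.

    ``eggs`` has one row per egg (true parents, father species, mtDNA
    haplotype, parasitic flag); ``nests`` one row per nest (resident hen
    and strategy label); ``individuals`` one row per genotyped sample
    (species, sex and the true 3-component ancestry vector).
    """

    eggs: pd.DataFrame
    nests: pd.DataFrame
    individuals: pd.DataFrame

    def to_json(self, path: str) -> None:
        payload = {
            "eggs": self.eggs.to_dict(orient="records"),
            "nests": self.nests.to_dict(orient="records"),
            "individuals": self.individuals.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimResult:
    """Bundle of everything the simulator produces for one study."""

    config: SimConfig
    genotypes: GenotypeMatrix        # reference panels + hens + eggs
    panel_labels: dict[str, str]     # reference sample -> population
    nest_table: pd.DataFrame         # sample_id, nest_id, role, sex, population_label
    mtdna: dict[str, str]            # focal sample -> control-region sequence
    mtdna_pool: MtdnaPool
    truth: TruthTable

    @property
    def focal_ids(self) -> list[str]:
        return list(dict.fromkeys(self.nest_table["sample_id"]))


def _species_q(species: str) -> tuple[float, float, float]:
    if species in POPS:
        return tuple(1.0 if p == species else 0.0 for p in POPS)
    parts = species.split("x")
    return tuple((1.0 / len(parts)) if p in parts else 0.0 for p in POPS)


def draw_reference_freqs(config: SimConfig) -> np.ndarray:
    """Per-population site allele frequencies under a Balding-Nichols model.

    Ancestral frequencies are uniform on [0.05, 0.95]; each population's
    frequency is a Beta draw centred on the ancestral value with its own
    divergence parameter F (ABDU and WMA share ``fst_abdu_wma``; GFM uses
    ``fst_gfm``).  Independent draws with parameter F yield a pairwise
    Hudson F_ST of ~F between two panels.  Returns an (n_sites, 3) array
    in ABDU, WMA, GFM column order.
    """
    rng = np.random.default_rng([config.seed, 11])
    anc = rng.uniform(0.05, 0.95, size=config.n_sites)
    fs = {"ABDU": config.fst_abdu_wma, "WMA": config.fst_abdu_wma,
          "GFM": config.fst_gfm}
    cols = []
    for pop in POPS:
        F = fs[pop]
        if F == 0.0:
            cols.append(anc.copy())
        else:
            a = anc * (1.0 - F) / F
            b = (1.0 - anc) * (1.0 - F) / F
            cols.append(rng.beta(a, b))
    return np.column_stack(cols)


def simulate_mtdna_pool(config: SimConfig) -> MtdnaPool:
    """Build the two-haplogroup control-region haplotype pool.

    The NW-B and OW-A group centres differ at ``haplogroup_divergence``
    positions; each haplotype sits 0-3 substitutions from its centre, so
    inter-group Hamming distances are at least divergence - 6.
    """
    rng = np.random.default_rng([config.seed, 13])
    bases = np.array(list("ACGT"))
    L = config.mtdna_length
    nw_center = rng.integers(0, 4, size=L)
    ow_center = nw_center.copy()
    div_pos = rng.choice(L, size=config.haplogroup_divergence, replace=False)
    ow_center[div_pos] = (ow_center[div_pos] + rng.integers(1, 4, size=len(div_pos))) % 4

    def derive(center: np.ndarray, n: int, prefix: str) -> dict[str, str]:
        out: dict[str, str] = {}
        seen = set()
        k = 0
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 100 * n + 100:
                raise RuntimeError("could not generate distinct haplotypes")
            nmut = 0 if not out else int(rng.integers(1, 4))
            seq = center.copy()
            if nmut:
                pos = rng.choice(L, size=nmut, replace=False)
                seq[pos] = (seq[pos] + rng.integers(1, 4, size=nmut)) % 4
            s = "".join(bases[seq])
            if s in seen:
                continue
            seen.add(s)
            k += 1
            out[f"{prefix}{k}"] = s
        return out

    nw = derive(nw_center, config.n_nw_haplotypes, "NW")
    ow = derive(ow_center, config.n_ow_haplotypes, "OW")
    sequences = {**nw, **ow}
    haplogroups = {h: NW_LABEL for h in nw} | {h: OW_LABEL for h in ow}
    centers = {NW_LABEL: "".join(bases[nw_center]),
               OW_LABEL: "".join(bases[ow_center])}
    return MtdnaPool(sequences, haplogroups, centers)


class _Founders:
    """Unsampled true genotypes used for Mendelian transmission."""

    def __init__(self, freqs: np.ndarray, rng: np.random.Generator):
        self.freqs = freqs
        self.rng = rng
        self.genotypes: dict[str, np.ndarray] = {}
        self.species: dict[str, str] = {}

    def draw(self, name: str, species: str) -> np.ndarray:
        f = self.freqs
        pop_idx = {p: i for i, p in enumerate(POPS)}
        if species in POPS:
            g = self.rng.binomial(2, f[:, pop_idx[species]])
        else:  # F1: one allele from each parental population
            a, b = species.split("x")
            g = (self.rng.binomial(1, f[:, pop_idx[a]])
                 + self.rng.binomial(1, f[:, pop_idx[b]]))
        g = g.astype(float)
        self.genotypes[name] = g
        self.species[name] = species
        return g


def _transmit(mother: np.ndarray, father: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Mendelian draw: one uniformly chosen allele from each parent."""
    return (rng.binomial(1, mother / 2.0)
            + rng.binomial(1, father / 2.0)).astype(float)


def _observe(g: np.ndarray, error: float, missing: float,
             rng: np.random.Generator) -> np.ndarray:
    """Apply per-allele flip error and missingness to a true genotype."""
    obs = g.copy()
    if error > 0:
        obs = obs - rng.binomial(obs.astype(int), error) \
                  + rng.binomial((2 - obs).astype(int), error)
    obs = obs.astype(float)
    if missing > 0:
        obs[rng.random(len(obs)) < missing] = np.nan
    return obs


def simulate_nests(config: SimConfig, freqs: np.ndarray,
                   pool: MtdnaPool | None = None) -> SimResult:
    """Simulate the full study: panels, hens, clutches and ground truth.

    Hens and fathers are unrelated founders (pure, or F1 hybrid for a
    ``hybrid_hen_fraction`` of hens).  Each egg is a Mendelian draw from
    its true parents with per-allele genotyping error and missingness.
    EPC nests receive exactly ``epc_eggs_per_nest`` egg(s) from a second
    father; parasitized nests receive 1-2 eggs from an unsampled outside
    hen carrying a different mtDNA haplotype; shared-father nest pairs
    are sired by one male; renesting hens lay two clutches (two nest ids)
    with the same father.  mtDNA is inherited maternally verbatim.
    """
    if pool is None:
        pool = simulate_mtdna_pool(config)
    if freqs.shape != (config.n_sites, len(POPS)):
        raise ValueError("freqs must be (n_sites, 3) from draw_reference_freqs")
    rng = np.random.default_rng([config.seed, 17])
    founders = _Founders(freqs, rng)

    n_hens = config.n_nests - config.n_renest_hens
    hen_ids = [f"HEN{i + 1:02d}" for i in range(n_hens)]
    nest_ids = [f"N{i + 1:02d}" for i in range(config.n_nests)]
    # hen i owns nest i; renest hen i additionally owns nest n_hens + i
    nest_owner = {nest_ids[i]: hen_ids[i] for i in range(n_hens)}
    renest_nests: set[str] = set()
    for i in range(config.n_renest_hens):
        extra = nest_ids[n_hens + i]
        nest_owner[extra] = hen_ids[i]
        renest_nests.update({nest_ids[i], extra})

    eligible = [n for n in nest_ids if n not in renest_nests]

    # cross-nest shared-father pairs (kept otherwise monogamous)
    if 2 * config.n_shared_father_pairs > len(eligible):
        raise ValueError("not enough nests for the requested shared-father pairs")
    shared_nests = list(rng.choice(eligible, size=2 * config.n_shared_father_pairs,
                                   replace=False))
    shared_pairs = [(shared_nests[2 * i], shared_nests[2 * i + 1])
                    for i in range(config.n_shared_father_pairs)]

    # EPC nests and parasitized nests (parasitism may coincide with EPC)
    candidates = [n for n in eligible if n not in shared_nests]
    n_epc = int(round(config.prop_epc * config.n_nests))
    if n_epc > len(candidates):
        raise ValueError("not enough nests for the requested EPC proportion")
    epc_nests = set(rng.choice(candidates, size=n_epc, replace=False)) \
        if n_epc else set()
    if config.n_parasitized > len(candidates):
        raise ValueError("not enough nests to parasitize")
    para_nests = set(rng.choice(candidates, size=config.n_parasitized,
                                replace=False)) if config.n_parasitized else set()

    # hen species and founders
    n_hybrid = int(round(config.hybrid_hen_fraction * n_hens))
    hybrid_hens = set(rng.choice(hen_ids, size=n_hybrid, replace=False)) \
        if n_hybrid else set()
    hen_true: dict[str, np.ndarray] = {}
    for h in hen_ids:
        sp = "ABDUxWMA" if h in hybrid_hens else "ABDU"
        hen_true[h] = founders.draw(h, sp)

    sp_names = [s for s, _ in FATHER_SPECIES]
    sp_probs = [p for _, p in FATHER_SPECIES]

    def new_father(name: str) -> np.ndarray:
        sp = rng.choice(sp_names, p=sp_probs)
        return founders.draw(name, str(sp))

    # one primary father per hen; shared-father pairs collapse to one male
    hen_father: dict[str, str] = {}
    for h in hen_ids:
        fid = f"SIRE_{h}"
        new_father(fid)
        hen_father[h] = fid
    for a, b in shared_pairs:
        ha, hb = nest_owner[a], nest_owner[b]
        hen_father[hb] = hen_father[ha]

    # mtDNA haplotypes for hens
    hap_ids = list(pool.sequences)
    hen_hap = {h: str(rng.choice(hap_ids)) for h in hen_ids}

    # build clutches
    egg_rows, nest_rows, table_rows = [], [], []
    mtdna: dict[str, str] = {}
    genos: dict[str, np.ndarray] = {}
    sexes: dict[str, str] = {h: "F" for h in hen_ids}

    for h in hen_ids:
        table_rows += [(h, nest, "hen", "F", "NC")
                       for nest in nest_ids if nest_owner[nest] == h]
        genos[h] = _observe(hen_true[h], config.genotype_error_rate,
                            config.missing_rate, rng)
        mtdna[h] = pool.sequences[hen_hap[h]]

    for nest in nest_ids:
        hen = nest_owner[nest]
        clutch = int(rng.integers(config.clutch_min, config.clutch_max + 1))
        is_epc = nest in epc_nests
        is_para = nest in para_nests
        father = hen_father[hen]
        egg_parents = [(hen, father)] * clutch
        if is_epc:
            epc_father = f"EPC_SIRE_{nest}"
            new_father(epc_father)
            for k in range(min(config.epc_eggs_per_nest, clutch - 1)):
                egg_parents[clutch - 1 - k] = (hen, epc_father)
        para_parents = []
        if is_para:
            pmother = f"PARA_HEN_{nest}"
            founders.draw(pmother, "ABDU")
            pfather = f"PARA_SIRE_{nest}"
            new_father(pfather)
            other = [hid for hid in hap_ids if hid != hen_hap[hen]]
            phap = str(rng.choice(other))
            n_extra = int(rng.integers(1, 3))
            para_parents = [(pmother, pfather)] * n_extra
            founders.species.setdefault(pmother, "ABDU")
            hen_hap[pmother] = phap
        for k, (mo, fa) in enumerate(egg_parents + para_parents, start=1):
            egg = f"{nest}E{k:02d}"
            true_g = _transmit(founders.genotypes[mo], founders.genotypes[fa], rng)
            genos[egg] = _observe(true_g, config.genotype_error_rate,
                                  config.missing_rate, rng)
            sex = "F" if rng.random() < 0.5 else "M"
            sexes[egg] = sex
            parasitic = mo != hen
            mtdna[egg] = pool.sequences[hen_hap[mo]]  # maternal, verbatim
            egg_rows.append({
                "sample_id": egg, "nest_id": nest,
                "true_mother_id": mo, "true_father_id": fa,
                "father_species": founders.species[fa],
                "mtdna_haplotype_id": hen_hap[mo],
                "is_parasitic": parasitic,
            })
            table_rows.append((egg, nest, "offspring", sex, "NC"))
        strategy = "monogamous"
        if is_epc and is_para:
            strategy = "parasitized_and_EPC"
        elif is_epc:
            strategy = "multi_paternal_EPC"
        elif is_para:
            strategy = "parasitized"
        nest_rows.append({"nest_id": nest, "hen_id": hen, "strategy": strategy})

    # reference panels
    panel_labels: dict[str, str] = {}
    for pi, pop in enumerate(POPS):
        for r in range(config.n_ref_per_pop):
            sid = f"{pop}_REF{r + 1:02d}"
            g = rng.binomial(2, freqs[:, pi]).astype(float)
            genos[sid] = _observe(g, config.genotype_error_rate,
                                  config.missing_rate, rng)
            panel_labels[sid] = pop
            founders.species[sid] = pop

    sample_ids = list(genos)
    sites = pd.DataFrame({
        "chrom": "1",
        "pos": (np.arange(config.n_sites) + 1) * 100,
        "ref": "A", "alt": "G", "qual": 60.0,
    })
    M = GenotypeMatrix(sample_ids, sites,
                       np.column_stack([genos[s] for s in sample_ids]))

    indiv_rows = []
    for sid in sample_ids:
        sp = founders.species.get(sid)
        if sp is None:  # egg: species from parents
            row = next(r for r in egg_rows if r["sample_id"] == sid)
            qm = np.array(_species_q(founders.species[row["true_mother_id"]]))
            qf = np.array(_species_q(founders.species[row["true_father_id"]]))
            q = (qm + qf) / 2.0
            sp = "x".join(p for p, qi in zip(POPS, q) if qi > 0) \
                if np.count_nonzero(q) > 1 else POPS[int(np.argmax(q))]
        else:
            q = np.array(_species_q(sp))
        indiv_rows.append({
            "sample_id": sid, "species": sp,
            "sex": sexes.get(sid, "U"),
            "q_ABDU": q[0], "q_WMA": q[1], "q_GFM": q[2],
        })

    truth = TruthTable(
        eggs=pd.DataFrame(egg_rows),
        nests=pd.DataFrame(nest_rows),
        individuals=pd.DataFrame(indiv_rows),
    )
    nest_table = pd.DataFrame(
        table_rows, columns=["sample_id", "nest_id", "role", "sex",
                             "population_label"])
    return SimResult(config, M, panel_labels, nest_table, mtdna, pool, truth)


def simulate_study(config: SimConfig | None = None) -> SimResult:
    """Convenience wrapper: draw frequencies, the mtDNA pool and the study."""
    config = config or SimConfig()
    freqs = draw_reference_freqs(config)
    pool = simulate_mtdna_pool(config)
    return simulate_nests(config, freqs, pool)


def write_outputs(sim: SimResult, outdir: str) -> dict[str, str]:
    """Write VCF, mtDNA FASTA, nest CSV and truth JSON; return the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "fasta": os.path.join(outdir, "mtdna.fasta"),
        "nests": os.path.join(outdir, "nests.csv"),
        "truth": os.path.join(outdir, "truth.json"),
        "panels": os.path.join(outdir, "panel_labels.csv"),
    }
    write_vcf(sim.genotypes, paths["vcf"])
    with open(paths["fasta"], "w") as fh:
        for sid, seq in sim.mtdna.items():
            fh.write(f">{sid}\n{seq}\n")
    sim.nest_table.to_csv(paths["nests"], index=False)
    sim.truth.to_json(paths["truth"])
    pd.DataFrame(sorted(sim.panel_labels.items()),
                 columns=["sample_id", "population"]).to_csv(
        paths["panels"], index=False)
    return paths
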