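"""Breeding-strategy classification and population-level rates.

Combines the two evidence channels — nuclear maternity (opposing-
homozygote test + Ajk) and mtDNA haplotype matching — to classify each
egg as resident-maternal, parasitic, or ambiguous; classifies nests as
monogamous, multi-paternal (extra-pair copulation), parasitized, or
both; and summarises population rates from a pairing table (per-nest
maternal lineage with its paternal lineages and egg counts).  A
packaged pairing-table fixture of 20 observed black duck broods allows
the printed population rates to be recomputed exactly without any
genotype data.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

EGG_ORIGINS = ("resident_maternal", "parasitic", "ambiguous")
NEST_STRATEGIES = ("monogamous", "multi_paternal_EPC", "parasitized",
                   "parasitized_and_EPC", "indeterminate")


@dataclass
class PairingTable:
    """Per-maternal-lineage pairing rows (the printed-table analog).

    ``rows`` columns: nest_id, maternal_lineage, maternal_species,
    hen_sampled (bool), paternal (list of (lineage_id, egg_count,
    species) tuples), parasitic_clutch (bool), host_nest, note.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.rows
        if r["nest_id"].duplicated().any():
            dups = r.loc[r["nest_id"].duplicated(), "nest_id"].tolist()
            raise ValueError(f"duplicate nest ids: {dups}")
        for _, row in r.iterrows():
            if not row["paternal"]:
                raise ValueError(f"{row['nest_id']}: empty paternal list")
            for lid, cnt, _sp in row["paternal"]:
                if cnt < 1:
                    raise ValueError(
                        f"{row['nest_id']}: egg count < 1 for {lid}")
            if row["parasitic_clutch"] and not row["host_nest"]:
                raise ValueError(
                    f"{row['nest_id']}: parasitic clutch without host nest")

    @classmethod
    def from_csv(cls, path) -> "PairingTable":
        df = pd.read_csv(path, dtype={"host_nest": str, "note": str},
                         keep_default_na=False)
        df["hen_sampled"] = df["hen_sampled"].astype(str) == "True"
        df["parasitic_clutch"] = df["parasitic_clutch"].astype(str) == "True"

        def parse(cell: str):
            out = []
            for part in str(cell).split(";"):
                lid, cnt, sp = part.strip().split(":")
                out.append((lid, int(cnt), sp))
            return out

        df["paternal"] = df["paternal_lineages"].map(parse)
        return cls(df.drop(columns=["paternal_lineages"]))

    def to_csv(self, path) -> None:
        df = self.rows.copy()
        df["paternal_lineages"] = df["paternal"].map(
            lambda ps: ";".join(f"{l}:{c}:{s}" for l, c, s in ps))
        df.drop(columns=["paternal"]).to_csv(path, index=False)


def load_reference_pairing_table() -> PairingTable:
    """The packaged 20-brood observed pairing table."""
    res = importlib.resources.files("nestkin") / "fixtures" / "nc_broods_pairings.csv"
    with importlib.resources.as_file(res) as path:
        return PairingTable.from_csv(path)


@dataclass
class StrategyCall:
    nest_id: str
    label: str
    n_parasitic: int
    n_resident: int
    n_ambiguous: int
    n_paternal_lineages: int
    mtdna_mismatch_eggs: list[str] = field(default_factory=list)


def classify_eggs(maternity_accept: dict[str, bool | None],
                  mtdna_mismatch: dict[str, bool | None],
                  egg_ids: list[str]) -> dict[str, str]:
    """Per-egg origin from the two evidence channels.

    An egg is parasitic only when BOTH channels point away from the
    resident hen (nuclear maternity rejected AND mtDNA mismatched);
    a single foreign-looking channel — or a missing/indeterminate
    channel — yields ``ambiguous`` (logged for review), never a silent
    default.
    """
    out: dict[str, str] = {}
    for egg in egg_ids:
        acc = maternity_accept.get(egg)
        mism = mtdna_mismatch.get(egg)
        if acc is None or mism is None:
            log.info("egg %s: missing evidence channel -> ambiguous", egg)
            out[egg] = "ambiguous"
        elif acc is False and mism:
            out[egg] = "parasitic"
        elif acc and not mism:
            out[egg] = "resident_maternal"
        else:
            log.info("egg %s: evidence channels disagree -> ambiguous", egg)
            out[egg] = "ambiguous"
    return out


def classify_nest(nest_id: str,
                  egg_origins: dict[str, str],
                  resident_lineages: dict[str, str]) -> StrategyCall:
    """Nest strategy from its eggs' origins and paternal lineages.

    ``resident_lineages`` maps each resident-maternal egg to its
    paternal lineage id.  Parasitized iff any parasitic egg; multi-
    paternal (EPC) iff the resident eggs span >= 2 paternal lineages;
    the labels combine; a nest whose eggs are all ambiguous is
    indeterminate.
    """
    n_par = sum(1 for v in egg_origins.values() if v == "parasitic")
    n_res = sum(1 for v in egg_origins.values() if v == "resident_maternal")
    n_amb = sum(1 for v in egg_origins.values() if v == "ambiguous")
    lineages = {resident_lineages[e] for e, v in egg_origins.items()
                if v == "resident_maternal" and e in resident_lineages}
    if n_amb and not n_par and not n_res:
        label = "indeterminate"
    elif n_par and len(lineages) >= 2:
        label = "parasitized_and_EPC"
    elif n_par:
        label = "parasitized"
    elif len(lineages) >= 2:
        label = "multi_paternal_EPC"
    else:
        label = "monogamous"
    return StrategyCall(nest_id, label, n_par, n_res, n_amb,
                        len(lineages),
                        mtdna_mismatch_eggs=[])


def rates_from_pairing_table(pt: PairingTable) -> dict:
    """Population-level summary rates computed purely from a pairing table.

    Every rate carries its numerator and denominator.  Multi-paternal
    and monogamous counts use the printed-table conventions: parasitic-
    clutch rows are excluded from the nest denominator but count as
    maternal lineages; a row is multi-paternal when it lists >= 2
    paternal lineages; the primary mate of a row is the father of the
    strictly largest egg count (ties -> no primary, logged).
    """
    rows = pt.rows
    nest_rows = rows[~rows["parasitic_clutch"].astype(bool)]
    n_nests = len(nest_rows)
    multi = int((nest_rows["paternal"].map(len) >= 2).sum())
    mono = int((rows["paternal"].map(len) == 1).sum())
    n_lineages = len(rows)
    paternal_ids = {lid for ps in rows["paternal"] for lid, _, _ in ps}
    offspring = int(sum(c for ps in rows["paternal"] for _, c, _ in ps))
    sampled = rows[rows["hen_sampled"].astype(bool)]
    pure_hens = int((sampled["maternal_species"] == "ABDU").sum())

    primary_abdu = 0
    n_primary = 0
    for _, row in rows.iterrows():
        counts = sorted((c for _, c, _ in row["paternal"]), reverse=True)
        if len(counts) > 1 and counts[0] == counts[1]:
            log.info("%s: tied primary father; excluded from primary-mate "
                     "rate", row["nest_id"])
            continue
        n_primary += 1
        primary = max(row["paternal"], key=lambda t: t[1])
        if primary[2] == "ABDU":
            primary_abdu += 1

    def rate(count: int, denom: int) -> dict:
        return {"count": count, "denominator": denom,
                "pct": 100.0 * count / denom if denom else float("nan")}

    return {
        "multi_paternal_nests": rate(multi, n_nests),
        "monogamous_maternal_lineages": rate(mono, n_lineages),
        "maternal_lineage_count": n_lineages,
        "paternal_lineage_count": len(paternal_ids),
        "total_sampled_offspring": offspring,
        "pure_abdu_hens": rate(pure_hens, len(sampled)),
        "primary_mate_pure_abdu": rate(primary_abdu, n_primary),
        "parasitic_clutches": int(rows["parasitic_clutch"].sum()),
    }


def population_rates(calls: list[StrategyCall],
                     pt: PairingTable) -> dict:
    """Rates for a genotype-level run: pairing-table rates + strategy counts."""
    if not calls:
        raise ValueError("no nests classified")
    out = rates_from_pairing_table(pt)
    labels = pd.Series([c.label for c in calls])
    out["parasitized_nests"] = int(
        labels.isin(["parasitized", "parasitized_and_EPC"]).sum())
    out["strategy_counts"] = labels.value_counts().to_dict()
    return out
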