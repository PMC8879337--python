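"""HDG quantification: hit filtering, RPKG normalisation, cluster
aggregation, group totals and ratio-SD difference flagging.

RPKG (reads per kilobase per genome equivalent) corrects raw hit counts
for gene length and for community sequencing depth / average genome size:

    rpkg(gene) = hits(gene) / (gene_length_kb * genome_equivalents)

with gene_length_kb = 3 * model_length_aa / 1000 by default (the
profile-HMM match-state length converted amino acids -> nucleotides).
Enzyme-complex clusters are summarised as the arithmetic mean RPKG of
their *structural* subunits; electron-transport and ferredoxin-reductase
subunits are excluded from the mean because their models also recruit
homologues from unrelated pathways.

Between-environment differences are flagged per functional group: for the
units detected on both sides of an axis, ratios numerator/denominator are
formed, and units whose ratio falls outside the group's mean +/- 1 sample
SD band are flagged as substantially different.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gene_catalog import GeneCatalog, UnknownGeneError, cluster_members
from .io_formats import HmmHitRecord

__all__ = [
    "SampleScale",
    "DEFAULT_EVALUE_MAX",
    "DEFAULT_SCORE_MIN",
    "filter_hits",
    "rpkg_normalize",
    "aggregate_clusters",
    "group_totals",
    "ratio_flags",
]

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_SCORE_MIN = 25.0


@dataclasses.dataclass(frozen=True)
class SampleScale:
    """Depth scaling for one sample: genome equivalents and library size."""

    sample_id: str
    genome_equivalents: float
    library_reads: int

    def __post_init__(self) -> None:
        if self.genome_equivalents <= 0:
            raise ValueError("genome_equivalents must be positive")
        if self.library_reads <= 0:
            raise ValueError("library_reads must be positive")


def filter_hits(
    hits: Iterable[HmmHitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    score_min: float = DEFAULT_SCORE_MIN,
) -> list[HmmHitRecord]:
    """Accept hits passing both thresholds; one hit per (contig, gene).

    When several domains of the same gene land on one contig, the
    best-scoring domain is kept (ties: lowest e-value, then leftmost
    alignment start, for determinism).
    """
    best: dict[tuple[str, str, str], HmmHitRecord] = {}
    for h in hits:
        if h.e_value > evalue_max or h.bit_score < score_min:
            continue
        key = (h.sample_id, h.contig_id, h.gene_symbol)
        prev = best.get(key)
        if prev is None or (
            (-h.bit_score, h.e_value, h.ali_from) < (-prev.bit_score, prev.e_value, prev.ali_from)
        ):
            best[key] = h
    return [best[k] for k in sorted(best)]


def rpkg_normalize(
    accepted_hits: Iterable[HmmHitRecord],
    catalog: GeneCatalog,
    scale: SampleScale,
    length_from: str = "model",
) -> pd.DataFrame:
    """Per-gene RPKG table for one sample (explicit zero rows included).

    ``length_from`` selects the gene-length term: "model" (3 x catalog
    model length, default) or "alignment" (3 x mean aligned span of the
    sample's accepted hits; falls back to the model length for genes
    without hits).
    """
    if length_from not in ("model", "alignment"):
        raise ValueError(f"unknown length_from {length_from!r}")
    counts: dict[str, int] = {sym: 0 for sym in catalog.symbols}
    spans: dict[str, list[int]] = {}
    for h in accepted_hits:
        if h.sample_id != scale.sample_id:
            raise ValueError(
                f"hit sample {h.sample_id!r} does not match scale {scale.sample_id!r}"
            )
        if h.gene_symbol not in catalog:
            raise UnknownGeneError(h.gene_symbol)
        counts[h.gene_symbol] += 1
        spans.setdefault(h.gene_symbol, []).append(h.ali_to - h.ali_from + 1)
    rows = []
    for sym in catalog.symbols:
        entry = catalog.entry(sym)
        if length_from == "alignment" and spans.get(sym):
            length_aa = float(np.mean(spans[sym]))
        else:
            length_aa = float(entry.model_length_aa)
        length_kb = 3.0 * length_aa / 1000.0
        rpkg = counts[sym] / (length_kb * scale.genome_equivalents)
        rows.append(
            {
                "sample_id": scale.sample_id,
                "unit_id": sym,
                "unit_kind": "gene",
                "functional_group": entry.functional_group,
                "rpkg": rpkg,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "unit_id", "unit_kind",
                                       "functional_group", "rpkg"])


def aggregate_clusters(gene_table: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    """Append cluster rows: mean RPKG over structural subunits per sample.

    Gene rows pass through untouched; electron-transport/reductase
    subunits stay in the table as gene rows but never enter a cluster
    mean. A cluster whose structural subunits are all zero gets mean 0.
    """
    if (gene_table["unit_kind"] != "gene").any():
        raise ValueError("aggregate_clusters expects a gene-only table")
    out = [gene_table]
    gene_rpkg = gene_table.set_index(["sample_id", "unit_id"])["rpkg"]
    rows = []
    for sample_id in sorted(gene_table["sample_id"].unique()):
        for cid in catalog.cluster_ids:
            structural = cluster_members(catalog, cid, "structural")
            values = [gene_rpkg.get((sample_id, g), 0.0) for g in structural]
            group = catalog.entry(structural[0]).functional_group
            rows.append(
                {
                    "sample_id": sample_id,
                    "unit_id": cid,
                    "unit_kind": "cluster",
                    "functional_group": group,
                    "rpkg": float(np.mean(values)),
                }
            )
    out.append(pd.DataFrame(rows, columns=gene_table.columns))
    return pd.concat(out, ignore_index=True)


def _quant_units(table: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    """Restrict an aggregated table to quantification units.

    Units are cluster rows plus standalone-gene rows; cluster-member gene
    rows (structural or electron-transport) are dropped so clusters count
    once and their subunits are never double-counted.
    """
    unit_ids = {uid for uid, _, _ in catalog.units()}
    mask = table.apply(
        lambda r: (r["unit_kind"] == "cluster" and r["unit_id"] in unit_ids)
        or (r["unit_kind"] == "gene" and r["unit_id"] in unit_ids),
        axis=1,
    )
    return table[mask]


def group_totals(table: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    """Per-sample total RPKG over quantification units, plus per-group sums.

    Expects a cluster-aggregated table. Returns tidy rows
    (sample_id, functional_group, rpkg) with functional_group "all" for
    the overall sum.
    """
    units = _quant_units(table, catalog)
    per_group = (
        units.groupby(["sample_id", "functional_group"], as_index=False)["rpkg"].sum()
    )
    overall = units.groupby("sample_id", as_index=False)["rpkg"].sum()
    overall["functional_group"] = "all"
    out = pd.concat([per_group, overall[per_group.columns]], ignore_index=True)
    return out.sort_values(["sample_id", "functional_group"]).reset_index(drop=True)


def ratio_flags(
    table: pd.DataFrame,
    catalog: GeneCatalog,
    numerator_sample: str,
    denominator_sample: str,
    axis_label: str | None = None,
    n_sd: float = 1.0,
) -> pd.DataFrame:
    """Flag units whose between-sample ratio leaves the group mean+/-SD band.

    For each functional group, ratios numerator/denominator are computed
    over units with rpkg > 0 in both samples; mean and sample SD (n-1)
    are taken over those ratios, and each unit is flagged ``within``,
    ``above`` or ``below`` the band [mean - n_sd*SD, mean + n_sd*SD].
    Units detected on only one side get the sentinel flags
    ``undetected_in_denominator`` / ``undetected_in_numerator`` and stay
    out of the group statistics; units detected in neither are omitted.
    Groups with fewer than two finite ratios have undefined SD: their
    units are flagged ``within`` with group_sd null.
    """
    units = _quant_units(table, catalog)
    axis = axis_label or f"{numerator_sample}_over_{denominator_sample}"
    num = units[units["sample_id"] == numerator_sample].set_index("unit_id")
    den = units[units["sample_id"] == denominator_sample].set_index("unit_id")
    if num.empty or den.empty:
        raise ValueError("both samples must be present in the table")
    rows = []
    for unit_id in sorted(set(num.index) | set(den.index)):
        a = float(num["rpkg"].get(unit_id, 0.0))
        b = float(den["rpkg"].get(unit_id, 0.0))
        if a == 0.0 and b == 0.0:
            continue
        group = (num if unit_id in num.index else den)["functional_group"][unit_id]
        if b == 0.0:
            rows.append((unit_id, group, None, "undetected_in_denominator"))
        elif a == 0.0:
            rows.append((unit_id, group, None, "undetected_in_numerator"))
        else:
            rows.append((unit_id, group, a / b, None))
    df = pd.DataFrame(rows, columns=["unit_id", "functional_group", "ratio", "flag"])
    out_rows = []
    for group, sub in df.groupby("functional_group", sort=True):
        finite = sub["ratio"].dropna().astype(float)
        if len(finite) >= 2:
            mean = float(finite.mean())
            sd = float(finite.std(ddof=1))
        elif len(finite) == 1:
            mean, sd = float(finite.iloc[0]), None
        else:
            mean, sd = None, None
        for _, r in sub.iterrows():
            flag = r["flag"]
            if flag is None:
                ratio = float(r["ratio"])
                if sd is None:
                    flag = "within"
                elif ratio > mean + n_sd * sd:
                    flag = "above"
                elif ratio < mean - n_sd * sd:
                    flag = "below"
                else:
                    flag = "within"
            out_rows.append(
                {
                    "unit_id": r["unit_id"],
                    "functional_group": group,
                    "axis": axis,
                    "ratio": r["ratio"],
                    "group_mean": mean,
                    "group_sd": sd,
                    "flag": flag,
                }
            )
    cols = ["unit_id", "functional_group", "axis", "ratio", "group_mean", "group_sd", "flag"]
    return (
        pd.DataFrame(out_rows, columns=cols)
        .sort_values(["functional_group", "unit_id"])
        .reset_index(drop=True)
    )
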