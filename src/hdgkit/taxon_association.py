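"""Contig-level association of HDGs with prokaryotic genera.

Contigs carrying at least one accepted hit to a *specific* HDG (genes on
the general-metabolism exclusion list are dropped) are matched to their
contig taxonomy; distinct contigs are counted per (genus, gene, sample),
counts are scaled to the smallest metagenome, the top genera are ranked
per functional group, and each genus is given a novelty category against
the HDO reference list and an optional reference-genome (BRITE-style)
gene-profile table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .gene_catalog import GeneCatalog
from .io_formats import ContigTaxonomyRecord, HmmHitRecord

__all__ = [
    "UNASSIGNED",
    "NOVELTY_CATEGORIES",
    "collect_specific_hdg_contigs",
    "associate",
    "scale_to_smallest",
    "top_genera",
    "flag_novelty",
    "read_brite_profiles",
]

UNASSIGNED = "unassigned"

# Category -> star colour in reporting: known degrader (no star), not
# previously described with no reference-genome HDGs (black), observed
# genes all backed by reference genomes (green), reference genomes
# disagree (red), genus absent from the reference-genome table (blue).
NOVELTY_CATEGORIES = (
    "known_degrader",
    "not_previously_described_no_brite_hdg",
    "brite_concordant",
    "brite_discordant",
    "missing_from_brite",
)


def collect_specific_hdg_contigs(
    accepted_hits: Iterable[HmmHitRecord],
    catalog: GeneCatalog,
) -> set[tuple[str, str, str]]:
    """Distinct (sample, contig, gene) for hits to non-excluded HDGs.

    A contig with two hits of the same gene contributes the pair once;
    hits to genes on the general-metabolism exclusion list are dropped
    gene-wise (a contig that also carries a specific gene stays, labelled
    with the specific gene only).
    """
    excluded = catalog.general_exclusion_list
    return {
        (h.sample_id, h.contig_id, h.gene_symbol)
        for h in accepted_hits
        if h.gene_symbol not in excluded
    }


def associate(
    contig_gene_pairs: set[tuple[str, str, str]],
    contig_taxonomy: Iterable[ContigTaxonomyRecord],
) -> pd.DataFrame:
    """Count distinct contigs per (genus, gene, sample).

    Contigs lacking a genus-rank classification (or any taxonomy record)
    are tallied under the ``unassigned`` genus, reported separately by the
    caller. Returns tidy rows (genus, gene_symbol, sample_id,
    raw_contig_hits).
    """
    genus_of: dict[tuple[str, str], str] = {}
    for rec in contig_taxonomy:
        genus = rec.rank_name("genus")
        if genus is not None:
            genus_of[(rec.sample_id, rec.read_id)] = genus
    rows = [
        {
            "genus": genus_of.get((sample_id, contig_id), UNASSIGNED),
            "gene_symbol": gene,
            "sample_id": sample_id,
        }
        for sample_id, contig_id, gene in contig_gene_pairs
    ]
    if not rows:
        return pd.DataFrame(columns=["genus", "gene_symbol", "sample_id", "raw_contig_hits"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["genus", "gene_symbol", "sample_id"], as_index=False)
        .size()
        .rename(columns={"size": "raw_contig_hits"})
    )
    return out.sort_values(["genus", "gene_symbol", "sample_id"]).reset_index(drop=True)


def scale_to_smallest(
    records: pd.DataFrame,
    sample_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Scale raw contig counts to the smallest metagenome.

    ``sample_sizes`` are classified prokaryotic read counts per sample
    (configurably any positive size measure); scale_factor(s) =
    min(sizes) / size(s), so the smallest sample's factor is exactly 1.
    """
    if any(v <= 0 for v in sample_sizes.values()):
        raise ValueError("sample sizes must be positive")
    smallest = min(sample_sizes.values())
    factors = {s: smallest / v for s, v in sample_sizes.items()}
    missing = set(records["sample_id"].unique()) - set(factors)
    if missing:
        raise ValueError(f"no sample size for {sorted(missing)}")
    out = records.copy()
    out["scaled_hits"] = [
        r * factors[s] for r, s in zip(out["raw_contig_hits"], out["sample_id"])
    ]
    return out


def top_genera(
    records: pd.DataFrame,
    catalog: GeneCatalog,
    n: int = 100,
    pooled: bool = True,
) -> dict[str, list[str]]:
    """Rank genera per functional group by summed scaled hits.

    Pooled across samples by default (per-sample ranking via
    ``pooled=False`` returns the union of each sample's top n). The
    ``unassigned`` bucket never ranks. Ties break lexicographically.
    """
    if "scaled_hits" not in records.columns:
        raise ValueError("records must be scaled first (scale_to_smallest)")
    df = records[records["genus"] != UNASSIGNED].copy()
    df["functional_group"] = [
        catalog.entry(g).functional_group for g in df["gene_symbol"]
    ]
    result: dict[str, list[str]] = {}
    for group, sub in df.groupby("functional_group", sort=True):
        if pooled:
            sums = sub.groupby("genus")["scaled_hits"].sum()
            ordered = sorted(sums.items(), key=lambda kv: (-kv[1], kv[0]))
            result[group] = [g for g, _ in ordered[:n]]
        else:
            chosen: set[str] = set()
            for _, per_sample in sub.groupby("sample_id"):
                sums = per_sample.groupby("genus")["scaled_hits"].sum()
                ordered = sorted(sums.items(), key=lambda kv: (-kv[1], kv[0]))
                chosen.update(g for g, _ in ordered[:n])
            result[group] = sorted(chosen)
    return result


@dataclasses.dataclass(frozen=True)
class NoveltyFlag:
    genus: str
    category: str


def flag_novelty(
    genus_genes: Mapping[str, set[str]],
    hdo_reference: frozenset[str] | set[str],
    brite_profiles: Mapping[str, set[str]] | None = None,
) -> list[NoveltyFlag]:
    """Categorise each genus's HDG associations for novelty.

    ``genus_genes`` maps genus -> observed specific HDG symbols. A genus
    on the HDO reference list is a known degrader. Otherwise the
    reference-genome gene-profile table decides: absent table or absent
    genus -> ``missing_from_brite``; empty reference gene set ->
    ``not_previously_described_no_brite_hdg``; observed genes all present
    in the reference set -> ``brite_concordant``; any observed gene
    missing from a non-empty reference set -> ``brite_discordant``.
    """
    ref = {" ".join(g.split()) for g in hdo_reference}
    flags = []
    for genus in sorted(genus_genes):
        observed = genus_genes[genus]
        if " ".join(genus.split()) in ref:
            cat = "known_degrader"
        elif brite_profiles is None or genus not in brite_profiles:
            cat = "missing_from_brite"
        else:
            brite = brite_profiles[genus]
            if not brite:
                cat = "not_previously_described_no_brite_hdg"
            elif observed <= brite:
                cat = "brite_concordant"
            else:
                cat = "brite_discordant"
        flags.append(NoveltyFlag(genus, cat))
    return flags


def read_brite_profiles(path: str | Path) -> dict[str, set[str]]:
    """Read a reference-genome gene-profile table: genus TAB comma-separated genes."""
    profiles: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            genus = fields[0].strip()
            genes = set()
            if len(fields) > 1 and fields[1].strip():
                genes = {g.strip() for g in fields[1].split(",") if g.strip()}
            profiles[genus] = genes
    return profiles
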