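"""MAG quality filtering, consensus taxonomy, ANI clustering and HDG presence.

Quality follows the completeness/contamination convention for draft
genomes: bins below 50% complete or above 10% contaminated are excluded.
Consensus taxonomy is assigned by contig voting, walking ranks from
species upward: at genus and species the winning name must exceed 60% of
the contigs classified at that rank, at higher ranks 90%; the deepest
rank whose winner clears its cutoff is reported. Relatedness clusters are
single-linkage connected components over ANI > 95% (the conventional
species boundary).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import CANONICAL_RANKS
from .gene_catalog import GeneCatalog, cluster_members
from .io_formats import BinMembership, BinQcRecord, ContigTaxonomyRecord, HmmHitRecord

__all__ = [
    "MagRecord",
    "QC_COMPLETENESS_MIN",
    "QC_CONTAMINATION_MAX",
    "ANI_SPECIES_THRESHOLD",
    "qc_filter",
    "consensus_taxonomy",
    "ani_cluster",
    "mag_hdg_presence",
]

QC_COMPLETENESS_MIN = 50.0
QC_CONTAMINATION_MAX = 10.0
ANI_SPECIES_THRESHOLD = 95.0

GENUS_SPECIES_CUTOFF = 0.60
HIGH_RANK_CUTOFF = 0.90


@dataclasses.dataclass
class MagRecord:
    bin_id: str
    sample_id: str
    contig_ids: list[str]
    completeness: float
    contamination: float
    quality_pass: bool
    consensus_taxon: tuple[str, str] | None = None
    hdg_presence: dict[str, bool] = dataclasses.field(default_factory=dict)


def qc_filter(
    memberships: Iterable[BinMembership],
    qc: Iterable[BinQcRecord],
) -> tuple[list[MagRecord], dict[str, float]]:
    """Build MagRecords with the quality_pass flag and passer summary stats.

    Pass requires completeness >= 50 AND contamination <= 10 (boundary
    values pass: the exclusion rule is "<50%" / ">10%"). Bins without a
    QC record are an error; QC-only bins keep empty contig lists.
    """
    contigs: dict[str, list[str]] = {}
    sample_of: dict[str, str] = {}
    for m in memberships:
        contigs.setdefault(m.bin_id, []).append(m.contig_id)
        sample_of[m.bin_id] = m.sample_id
    qc_by_bin = {}
    for q in qc:
        qc_by_bin[q.bin_id] = q
    missing = set(contigs) - set(qc_by_bin)
    if missing:
        raise ValueError(f"bins without QC record: {sorted(missing)}")
    mags = []
    for bin_id in sorted(qc_by_bin):
        q = qc_by_bin[bin_id]
        passed = (
            q.completeness >= QC_COMPLETENESS_MIN
            and q.contamination <= QC_CONTAMINATION_MAX
        )
        mags.append(
            MagRecord(
                bin_id=bin_id,
                sample_id=sample_of.get(bin_id, ""),
                contig_ids=sorted(contigs.get(bin_id, [])),
                completeness=q.completeness,
                contamination=q.contamination,
                quality_pass=passed,
            )
        )
    passers = [m for m in mags if m.quality_pass]
    summary = {
        "n_pass": float(len(passers)),
        "mean_completeness": float(np.mean([m.completeness for m in passers])) if passers else float("nan"),
        "mean_contamination": float(np.mean([m.contamination for m in passers])) if passers else float("nan"),
    }
    return mags, summary


def consensus_taxonomy(
    mag: MagRecord,
    contig_taxonomy: Iterable[ContigTaxonomyRecord],
    length_weights: Mapping[str, float] | None = None,
) -> tuple[str, str] | None:
    """Consensus taxon of a MAG by contig voting, deepest rank first.

    Walks species -> superkingdom; at each rank the vote denominator is
    the contigs of the MAG classified at that rank, and the winning name
    must exceed 60% (genus/species) or 90% (higher ranks) of those votes.
    Votes are per contig by default; pass ``length_weights`` (contig ->
    length) for a length-weighted variant. Returns None when no rank's
    winner clears its cutoff or no contig is classified.
    """
    contig_set = set(mag.contig_ids)
    lineages = {
        rec.read_id: dict(rec.lineage)
        for rec in contig_taxonomy
        if rec.read_id in contig_set and rec.status == "classified"
    }
    if not lineages:
        return None

    def weight(contig: str) -> float:
        return 1.0 if length_weights is None else float(length_weights.get(contig, 0.0))

    for rank in reversed(CANONICAL_RANKS):  # species first
        votes: dict[str, float] = {}
        denom = 0.0
        for contig, lineage in lineages.items():
            name = lineage.get(rank)
            if name is None:
                continue
            w = weight(contig)
            denom += w
            votes[name] = votes.get(name, 0.0) + w
        if not votes or denom == 0:
            continue
        winner = max(sorted(votes), key=lambda n: votes[n])
        cutoff = GENUS_SPECIES_CUTOFF if rank in ("genus", "species") else HIGH_RANK_CUTOFF
        if votes[winner] / denom > cutoff:
            return (rank, winner)
    return None


def ani_cluster(matrix: pd.DataFrame, threshold: float = ANI_SPECIES_THRESHOLD) -> list[set[str]]:
    """Single-linkage clusters over pairwise ANI strictly above threshold.

    ``matrix`` is a square DataFrame (bins x bins, percent identity);
    asymmetry beyond 1e-6 is an error. Returns the partition as a list of
    bin-id sets, sorted by their smallest member; singletons included.
    """
    bins = list(matrix.index)
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("ANI matrix must be square")
    if not np.allclose(values, values.T, atol=1e-6):
        raise ValueError("ANI matrix is not symmetric")
    adj = csr_matrix(values > threshold)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, set[str]] = {}
    for b, lab in zip(bins, labels):
        clusters.setdefault(int(lab), set()).add(b)
    return sorted(clusters.values(), key=lambda s: min(s))


def mag_hdg_presence(
    mag: MagRecord,
    accepted_hits: Iterable[HmmHitRecord],
    catalog: GeneCatalog,
) -> dict[str, bool]:
    """HDG presence per quantification unit for one MAG.

    A standalone gene is present with >= 1 accepted hit on the MAG's
    contigs; a cluster is present when at least 50% of its structural
    subunits are detected (exactly half counts as present).
    """
    contig_set = set(mag.contig_ids)
    detected = {
        h.gene_symbol for h in accepted_hits if h.contig_id in contig_set
    }
    presence: dict[str, bool] = {}
    for unit_id, kind, _group in catalog.units():
        if kind == "gene":
            presence[unit_id] = unit_id in detected
        else:
            structural = cluster_members(catalog, unit_id, "structural")
            found = sum(1 for g in structural if g in detected)
            presence[unit_id] = found / len(structural) >= 0.5
    return presence
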