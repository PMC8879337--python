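"""Taxonomic community profiles and hydrocarbon-degrader (HDO) accounting.

Profiles are built per sample at one of the seven canonical ranks (or at
kingdom level). Genus-level proportions are expressed as percent of
*prokaryotic* reads — reads whose superkingdom is Bacteria or Archaea —
because that is the denominator all HDO proportions and top-genus figures
use; kingdom-level shares use all classified reads instead.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import CANONICAL_RANKS
from ._util import round_half_up
from .io_formats import ReadClassificationRecord, records_to_frame

__all__ = [
    "TaxonomicProfile",
    "ComparisonResult",
    "build_profile",
    "hdo_proportion",
    "compare_samples",
    "venn_partition",
    "top_n",
]

PROKARYOTIC_SUPERKINGDOMS = ("Bacteria", "Archaea")


@dataclasses.dataclass(frozen=True)
class TaxonomicProfile:
    """Per-sample relative abundances at one rank.

    ``proportions`` maps taxon name -> percent of prokaryotic reads (or of
    all classified reads when rank == "kingdom"). The remainder up to 100%
    is reads unclassified at the requested rank.
    """

    sample_id: str
    rank: str
    proportions: Mapping[str, float]
    total_reads: int
    prokaryotic_reads: int

    def proportion(self, taxon: str) -> float:
        if self.prokaryotic_reads == 0 and self.rank != "kingdom":
            raise ValueError(
                f"profile {self.sample_id!r} has no prokaryotic reads; "
                "proportions undefined"
            )
        return self.proportions.get(taxon, 0.0)


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """A pairwise taxon comparison between two samples.

    ``status`` is "ok" unless a fold change hit a zero denominator, in
    which case it is "numerator_only" and value/rounded are None.
    """

    taxon: str
    sample_a: str
    sample_b: str
    mode: str
    value: float | None
    rounded: float | None
    status: str = "ok"


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def build_profile(
    records: Iterable[ReadClassificationRecord] | pd.DataFrame,
    rank: str,
) -> TaxonomicProfile:
    """Build a taxonomic profile at ``rank`` from one sample's records.

    ``rank`` is one of the canonical ranks, or "kingdom" for the
    Bacteria/Archaea/other split over all classified reads. Mixed sample
    ids are an error. Reads classified but lacking the requested rank
    contribute only to the unclassified-at-rank remainder.
    """
    if rank != "kingdom" and rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    df = _as_frame(records)
    samples = df["sample_id"].unique()
    if len(samples) > 1:
        raise ValueError(f"records from multiple samples: {sorted(samples)}")
    sample_id = str(samples[0]) if len(samples) else "<empty>"
    total_reads = len(df)
    classified = df[df["status"] == "classified"]
    prok = classified[classified["superkingdom"].isin(PROKARYOTIC_SUPERKINGDOMS)]
    prokaryotic_reads = len(prok)

    if rank == "kingdom":
        denom = len(classified)
        counts = classified["superkingdom"].value_counts()
        props = {
            str(name): 100.0 * n / denom for name, n in counts.items()
        } if denom else {}
        return TaxonomicProfile(sample_id, rank, props, total_reads, prokaryotic_reads)

    if prokaryotic_reads == 0:
        return TaxonomicProfile(sample_id, rank, {}, total_reads, 0)
    at_rank = prok[prok[rank].notna()]
    counts = at_rank[rank].value_counts()
    props = {str(name): 100.0 * n / prokaryotic_reads for name, n in counts.items()}
    return TaxonomicProfile(sample_id, rank, props, total_reads, prokaryotic_reads)


def hdo_proportion(profile: TaxonomicProfile, reference: frozenset[str] | set[str]) -> float:
    """Summed percent of prokaryotic reads in genera on the HDO reference list.

    Matching is exact genus-name string match after whitespace
    normalisation ("Ca." prefixes are part of the name).
    """
    if profile.rank != "genus":
        raise ValueError(f"HDO proportion needs a genus profile, got {profile.rank!r}")
    ref = {" ".join(g.split()) for g in reference}
    return sum(
        p for name, p in profile.proportions.items() if " ".join(name.split()) in ref
    )


def compare_samples(
    value_a: float,
    value_b: float,
    mode: str,
    taxon: str = "",
    sample_a: str = "a",
    sample_b: str = "b",
    ndigits: int | None = None,
) -> ComparisonResult:
    """Between-sample comparison arithmetic on two proportions.

    ``difference_pp`` is a - b in percentage points (reported at 2
    decimals by default); ``fold_change`` is a / b (reported at 1 decimal).
    A fold change against a zero denominator is reported as the explicit
    "numerator_only" outcome rather than infinity.
    """
    if mode == "difference_pp":
        value = value_a - value_b
        nd = 2 if ndigits is None else ndigits
    elif mode == "fold_change":
        if value_b == 0:
            if value_a == 0:
                raise ValueError("fold change undefined: both values zero")
            return ComparisonResult(taxon, sample_a, sample_b, mode, None, None,
                                    status="numerator_only")
        value = value_a / value_b
        nd = 1 if ndigits is None else ndigits
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ComparisonResult(taxon, sample_a, sample_b, mode, value, round_half_up(value, nd))


def venn_partition(
    profiles: Sequence[TaxonomicProfile],
    threshold_pct: float = 0.05,
) -> dict[frozenset[str], frozenset[str]]:
    """Partition genera into Venn regions over the retained sets.

    A genus is retained in a sample when its proportion strictly exceeds
    ``threshold_pct`` percent of prokaryotic reads. Returns a mapping from
    each non-empty sample subset to the genera present in exactly those
    samples; all 2^k - 1 regions are present (possibly empty).
    """
    if len(profiles) < 2:
        raise ValueError("venn_partition needs at least two profiles")
    retained = {
        p.sample_id: frozenset(
            g for g, prop in p.proportions.items() if prop > threshold_pct
        )
        for p in profiles
    }
    samples = sorted(retained)
    regions: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(samples) + 1):
        for combo in itertools.combinations(samples, r):
            inside = set(combo)
            genera = set.intersection(*(set(retained[s]) for s in inside))
            for s in samples:
                if s not in inside:
                    genera -= retained[s]
            regions[frozenset(inside)] = frozenset(genera)
    return regions


def top_n(profile: TaxonomicProfile, n: int) -> list[str]:
    """The n most abundant taxa, descending; ties break lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(profile.proportions.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ordered[:n]]
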