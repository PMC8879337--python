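"""Registry of the targeted hydrocarbon-degradation genes (HDGs).

The catalog is the single home of gene semantics: functional group (alkane,
MAH, PAH, various), enzyme-complex cluster membership, subunit role
(structural vs electron-transport/ferredoxin-reductase vs standalone), the
general-metabolism flag behind the taxon-association exclusion list, and
the profile-HMM model length used for RPKG gene-length normalisation.
No downstream module hard-codes any of this.

The bundled default catalog covers the 92 KO-model genes plus the
custom-profile long-chain alkane gene almA. Entries not individually named
in the accompanying analysis are flagged ``curated`` in the data file and
are implementer-curated defaults, replaceable by pointing ``load_catalog``
at another TSV with the same columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import bundled_data_path

__all__ = [
    "FUNCTIONAL_GROUPS",
    "SUBUNIT_ROLES",
    "GeneEntry",
    "GeneCatalog",
    "UnknownGeneError",
    "CatalogError",
    "load_catalog",
    "load_default_catalog",
    "cluster_members",
    "load_hdo_reference",
]

FUNCTIONAL_GROUPS = ("alkane", "MAH", "PAH", "various")
SUBUNIT_ROLES = ("structural", "electron_transport_or_reductase", "standalone")

# Genes that, besides hydrocarbon degradation, participate in multiple
# general metabolic pathways; excluded from taxon-gene association.
DEFAULT_GENERAL_EXCLUSION = frozenset(
    {
        "rubB", "a-adh", "ADH1", "hcaB", "ped", "phe", "gst", "nahB",
        "phdK", "adh", "adhE", "adhP", "ALDH", "frmA", "phdE", "sdh",
    }
)


class CatalogError(ValueError):
    """Invalid catalog content."""


class UnknownGeneError(KeyError):
    """A gene symbol that does not resolve in the catalog."""


@dataclasses.dataclass(frozen=True)
class GeneEntry:
    gene_symbol: str
    ko_code: str | None
    functional_group: str
    cluster_id: str | None
    subunit_role: str
    general_metabolism: bool
    model_length_aa: int

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise CatalogError(
                f"{self.gene_symbol}: bad functional group {self.functional_group!r}"
            )
        if self.subunit_role not in SUBUNIT_ROLES:
            raise CatalogError(f"{self.gene_symbol}: bad subunit role {self.subunit_role!r}")
        if (self.cluster_id is None) != (self.subunit_role == "standalone"):
            raise CatalogError(
                f"{self.gene_symbol}: cluster_id must be set exactly for clustered "
                f"subunits (cluster_id={self.cluster_id!r}, role={self.subunit_role!r})"
            )
        if self.model_length_aa <= 0:
            raise CatalogError(f"{self.gene_symbol}: non-positive model length")


class GeneCatalog:
    """Validated set of GeneEntry plus the general-gene exclusion list."""

    def __init__(self, entries, general_exclusion_list=DEFAULT_GENERAL_EXCLUSION):
        entries = list(entries)
        symbols = [e.gene_symbol for e in entries]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise CatalogError(f"duplicate gene symbols: {dupes}")
        self._by_symbol = {e.gene_symbol: e for e in entries}
        self._alias = {}
        for e in entries:
            if e.ko_code:
                if e.ko_code in self._alias:
                    raise CatalogError(f"KO code {e.ko_code} mapped to two symbols")
                self._alias[e.ko_code] = e.gene_symbol
        self._clusters: dict[str, list[GeneEntry]] = {}
        for e in entries:
            if e.cluster_id is not None:
                self._clusters.setdefault(e.cluster_id, []).append(e)
        for cid, members in self._clusters.items():
            if not any(m.subunit_role == "structural" for m in members):
                raise CatalogError(f"cluster {cid!r} has no structural subunit")
        exclusion = frozenset(general_exclusion_list) & set(symbols)
        bad = [s for s in exclusion if not self._by_symbol[s].general_metabolism]
        if bad:
            raise CatalogError(
                f"exclusion list contains non-general genes: {sorted(bad)}"
            )
        self.general_exclusion_list = exclusion

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __iter__(self):
        return iter(sorted(self._by_symbol.values(), key=lambda e: e.gene_symbol))

    def entry(self, symbol: str) -> GeneEntry:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise UnknownGeneError(symbol) from None

    def resolve(self, name: str) -> str | None:
        """Map an HMM query name (gene symbol or KO code) to a gene symbol."""
        if name in self._by_symbol:
            return name
        return self._alias.get(name)

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self._clusters)

    @property
    def symbols(self) -> list[str]:
        return sorted(self._by_symbol)

    def units(self) -> list[tuple[str, str, str]]:
        """Quantification units: (unit_id, unit_kind, functional_group).

        One cluster unit per cluster plus one gene unit per standalone gene.
        Cluster-member genes are not units of their own — their abundance
        enters only through the cluster mean (structural subunits) or is
        excluded (electron-transport/reductase subunits).
        """
        out: list[tuple[str, str, str]] = []
        for cid in self.cluster_ids:
            out.append((cid, "cluster", self._clusters[cid][0].functional_group))
        for e in self:
            if e.subunit_role == "standalone":
                out.append((e.gene_symbol, "gene", e.functional_group))
        return sorted(out)


def cluster_members(
    catalog: GeneCatalog, cluster_id: str, role_filter: str | None = None
) -> list[str]:
    """Gene symbols of a cluster, optionally restricted to one subunit role.

    Lexicographic order for determinism.
    """
    if cluster_id not in catalog._clusters:
        raise UnknownGeneError(cluster_id)
    members = catalog._clusters[cluster_id]
    if role_filter is not None:
        if role_filter not in SUBUNIT_ROLES:
            raise CatalogError(f"bad role filter {role_filter!r}")
        members = [m for m in members if m.subunit_role == role_filter]
    return sorted(m.gene_symbol for m in members)


def load_catalog(path: str | Path) -> GeneCatalog:
    """Load and validate a catalog TSV (columns matching GeneEntry fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "gene_symbol", "ko_code", "functional_group", "cluster_id",
        "subunit_role", "general_metabolism", "model_length_aa",
    }
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            GeneEntry(
                gene_symbol=row["gene_symbol"].strip(),
                ko_code=row["ko_code"].strip() or None,
                functional_group=row["functional_group"].strip(),
                cluster_id=row["cluster_id"].strip() or None,
                subunit_role=row["subunit_role"].strip(),
                general_metabolism=row["general_metabolism"].strip() in ("1", "true", "True"),
                model_length_aa=int(row["model_length_aa"]),
            )
        )
    return GeneCatalog(entries)


def load_default_catalog() -> GeneCatalog:
    with bundled_data_path("hdg_catalog.tsv") as p:
        return load_catalog(p)


def load_hdo_reference(path: str | Path | None = None) -> frozenset[str]:
    """Load the hydrocarbon-degrading-organism (HDO) genus reference list.

    One genus per line, '#' comments allowed; whitespace-normalised exact
    names. The bundled default is a synthetic stand-in of reference size
    369 (see the data file header).
    """
    if path is None:
        with bundled_data_path("hdo_genera.synthetic.txt") as p:
            return load_hdo_reference(p)
    names: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = " ".join(line.split())
            if not line or line.startswith("#"):
                continue
            names.append(line)
    if not names:
        raise CatalogError(f"{path}: empty HDO reference")
    if len(set(names)) != len(names):
        raise CatalogError(f"{path}: duplicate genus names")
    return frozenset(names)
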