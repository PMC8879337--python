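"""Synthetic pipeline inputs with known ground truth.

Every input dialect the pipeline reads can be generated here from a
:class:`ScenarioConfig`: per-read taxonomic classifications (multinomial
draws over a genus frequency table, with per-sample multiplicative
enrichment effects emulating environment shifts such as oil exposure),
profile-HMM hit tables (Poisson hit counts per gene at configured rates,
each hit placed on a contig whose genus is drawn from the gene's genus
weight vector), contig taxonomy, bin membership / QC / ANI matrix tables
for MAG analysis, and the per-sample depth-scale table.

The community model is multinomial and the hit model Poisson, chosen so
standard-error bounds for parameter-recovery tests are analytic. Output
is byte-identical under a fixed seed. Contig ids carry a ground-truth
provenance suffix (``~g=<genus>``) parsed only by tests, never by
pipeline code.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import CANONICAL_RANKS
from .gene_catalog import GeneCatalog, cluster_members, load_default_catalog
from .io_formats import HmmHitRecord, ReadClassificationRecord

__all__ = [
    "SampleSpec",
    "MagSpec",
    "ScenarioConfig",
    "ofotfjorden_like",
    "expected_genus_frequencies",
    "generate_reads_classification",
    "generate_hdg_hits",
    "generate_mags",
    "write_scenario",
    "lineage_for_genus",
]

# Archaeal genera recognised by the synthetic taxonomy; everything else is
# bacterial.
_ARCHAEAL_GENERA = frozenset(
    {
        "Nitrosopumilus", "Halobacterium", "Haloferax", "Haloarcula",
        "Natronomonas", "Thermococcus", "Archaeoglobus", "Methanosarcina",
        "Ferroglobus", "Halorubrum", "Ca. Nitrosomarinus", "Ca. Nitrosopelagicus",
    }
)

_BACTERIAL_SPINES = (
    ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Alteromonadaceae"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae"),
    ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Oceanospirillaceae"),
    ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae"),
    ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae"),
    ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae"),
    ("Cyanobacteria", "Cyanophyceae", "Synechococcales", "Synechococcaceae"),
)
_ARCHAEAL_SPINE = ("Thaumarchaeota", "Nitrososphaeria", "Nitrosopumilales", "Nitrosopumilaceae")

# Marine genera prominent in the bundled preset get their real family spine;
# everything else falls back to a checksum bucket.
_CURATED_SPINES = {
    "Colwellia": 0, "Glaciecola": 0, "Paraglaciecola": 0, "Pseudoalteromonas": 0,
    "Alteromonas": 0, "Shewanella": 0, "Idiomarina": 0, "Moritella": 0,
    "Planktomarina": 1, "Sulfitobacter": 1, "Roseovarius": 1, "Ruegeria": 1,
    "Octadecabacter": 1, "Loktanella": 1, "Roseobacter": 1,
    "Bermanella": 2, "Oleispira": 2, "Marinomonas": 2, "Alcanivorax": 2,
    "Marinobacter": 2, "Halomonas": 2,
    "Polaribacter": 3, "Flavobacterium": 3,
    "Ca. Actinomarina": 4,
    "Synechococcus": 7,
}


def lineage_for_genus(genus: str) -> tuple[tuple[str, str], ...]:
    """Deterministic full lineage for a synthetic genus.

    Preset-prominent marine genera map to their real family spine;
    other bacterial genera are spread over a fixed set of phylum/class/
    order/family spines by a stable (non-salted) checksum of the name;
    the recognised archaeal genera share one thaumarchaeotal spine.
    """
    if genus in _ARCHAEAL_GENERA:
        sk, spine = "Archaea", _ARCHAEAL_SPINE
    else:
        sk = "Bacteria"
        idx = _CURATED_SPINES.get(genus, sum(ord(c) for c in genus) % len(_BACTERIAL_SPINES))
        spine = _BACTERIAL_SPINES[idx]
    phylum, klass, order, family = spine
    return (
        ("superkingdom", sk),
        ("phylum", phylum),
        ("class", klass),
        ("order", order),
        ("family", family),
        ("genus", genus),
        ("species", f"{genus} synthetica"),
    )


def _lineage_string(lineage: Sequence[tuple[str, str]]) -> str:
    return "; ".join(name for _, name in lineage) + ";"


@dataclasses.dataclass(frozen=True)
class SampleSpec:
    name: str
    prokaryotic_read_count: int
    genome_equivalents: float
    fraction_unclassified: float = 0.25
    fraction_eukaryotic: float = 0.02


@dataclasses.dataclass(frozen=True)
class MagSpec:
    bin_id: str
    sample_id: str
    true_lineage: tuple[tuple[str, str], ...]
    contig_count: int
    completeness: float
    contamination: float
    vote_share: float = 0.95
    planted_units: tuple[str, ...] = ()
    species_pair_with: str | None = None  # bin sharing >95% ANI


@dataclasses.dataclass
class ScenarioConfig:
    """Full specification of a synthetic study.

    ``genus_base_frequencies`` is the baseline (seawater-like) community;
    ``enrichment_effects`` maps (sample, genus) to a multiplicative factor
    applied before renormalisation. ``hdg_hit_rates`` maps (sample, gene)
    to expected accepted hits per 1e5 prokaryotic reads; ``genus_gene_links``
    maps gene -> genus weight vector for placing hits on contigs.
    """

    seed: int
    samples: list[SampleSpec]
    genus_base_frequencies: dict[str, float]
    enrichment_effects: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    hdg_hit_rates: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    genus_gene_links: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    mag_specs: list[MagSpec] = dataclasses.field(default_factory=list)
    fail_filter_fraction: float = 0.1
    contig_genus_unassigned_fraction: float = 0.05
    decoy_models_per_sample: int = 2

    def sample(self, name: str) -> SampleSpec:
        for s in self.samples:
            if s.name == name:
                return s
        raise KeyError(name)

    def _rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(abs(hash_stream(stream)),))
        return np.random.default_rng(ss)


def hash_stream(name: str) -> int:
    # stable small integer per stream name (not Python's salted hash)
    return sum((i + 1) * ord(c) for i, c in enumerate(name)) % (2**16)


def expected_genus_frequencies(config: ScenarioConfig, sample: str) -> dict[str, float]:
    """Post-enrichment, renormalised genus frequencies for one sample."""
    weights = {
        g: f * config.enrichment_effects.get((sample, g), 1.0)
        for g, f in config.genus_base_frequencies.items()
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("genus frequencies sum to zero")
    return {g: w / total for g, w in weights.items()}


def generate_reads_classification(
    config: ScenarioConfig,
) -> dict[str, pd.DataFrame]:
    """Draw per-read genus labels for every sample.

    Returns one DataFrame per sample in the flattened classification
    layout (read_id, sample_id, status, taxon_id, one column per rank).
    Prokaryotic reads are a multinomial over the enriched genus
    frequencies; a configured fraction of reads is emitted unclassified
    and a small fraction as eukaryotic.
    """
    rng = config._rng("reads")
    genera = sorted(config.genus_base_frequencies)
    taxid = {g: 1000 + i for i, g in enumerate(genera)}
    out: dict[str, pd.DataFrame] = {}
    for spec in config.samples:
        freqs = expected_genus_frequencies(config, spec.name)
        p = np.array([freqs[g] for g in genera])
        counts = rng.multinomial(spec.prokaryotic_read_count, p)
        classified_frac = 1.0 - spec.fraction_unclassified - spec.fraction_eukaryotic
        n_unclassified = int(round(spec.prokaryotic_read_count
                                   * spec.fraction_unclassified / classified_frac))
        n_euk = int(round(spec.prokaryotic_read_count
                          * spec.fraction_eukaryotic / classified_frac))

        genus_col: list[str | None] = []
        status_col: list[str] = []
        for g, n in zip(genera, counts):
            genus_col.extend([g] * int(n))
            status_col.extend(["classified"] * int(n))
        genus_col.extend([None] * (n_euk + n_unclassified))
        status_col.extend(["classified"] * n_euk)
        status_col.extend(["unclassified"] * n_unclassified)

        n_total = len(status_col)
        order = rng.permutation(n_total)
        rows = {rank: [None] * n_total for rank in CANONICAL_RANKS}
        read_ids = [f"{spec.name}_r{i + 1}" for i in range(n_total)]
        status_arr = [status_col[j] for j in order]
        genus_arr = [genus_col[j] for j in order]
        taxid_col: list[int | None] = []
        for i, (st, g) in enumerate(zip(status_arr, genus_arr)):
            if st == "unclassified":
                taxid_col.append(None)
                continue
            if g is None:  # eukaryotic
                taxid_col.append(2759)
                rows["superkingdom"][i] = "Eukaryota"
                continue
            taxid_col.append(taxid[g])
            for rank, name in lineage_for_genus(g):
                rows[rank][i] = name
        df = pd.DataFrame(
            {
                "read_id": read_ids,
                "sample_id": spec.name,
                "status": status_arr,
                "taxon_id": taxid_col,
                **rows,
            }
        )
        out[spec.name] = df
    return out


def _frame_to_kaiju(df: pd.DataFrame, path: Path) -> None:
    cols = ["read_id", "status", "taxon_id", *CANONICAL_RANKS]
    with path.open("w") as fh:
        for read_id, status, taxon_id, *lineage in df[cols].itertuples(
            index=False, name=None
        ):
            if status == "unclassified":
                fh.write(f"U\t{read_id}\t0\n")
                continue
            names = [n for n in lineage if n is not None and n == n]
            taxid = int(taxon_id) if taxon_id is not None else 0
            if names:
                fh.write(f"C\t{read_id}\t{taxid}\t" + "; ".join(names) + ";\n")
            else:
                fh.write(f"C\t{read_id}\t{taxid}\n")


def generate_hdg_hits(
    config: ScenarioConfig,
    catalog: GeneCatalog | None = None,
) -> tuple[list[HmmHitRecord], list[ReadClassificationRecord], list]:
    """Poisson HDG hits on genus-labelled contigs for every sample.

    Per (sample, gene), the accepted-hit count is Poisson with mean
    ``rate * prokaryotic_reads / 1e5``. Each hit sits on its own contig
    whose genus is drawn from the gene's genus weight vector (uniform over
    the community when no vector is configured). On top of the accepted
    hits, a ``fail_filter_fraction`` share of extra hits is emitted with
    e-value/score failing the default acceptance thresholds, plus a few
    decoy-model lines that no catalog entry resolves.

    Returns (all hit records incl. failing ones, contig taxonomy records,
    raw domtblout line tuples for the writer).
    """
    catalog = catalog or load_default_catalog()
    rng = config._rng("hits")
    genera = sorted(config.genus_base_frequencies)
    hits: list[HmmHitRecord] = []
    taxonomy: list[ReadClassificationRecord] = []
    raw_lines: list[tuple] = []
    for spec in config.samples:
        counter = 0
        gene_rates = {
            gene: rate
            for (s, gene), rate in sorted(config.hdg_hit_rates.items())
            if s == spec.name
        }
        for gene in sorted(gene_rates):
            rate = gene_rates[gene]
            entry = catalog.entry(gene)
            lam = rate * spec.prokaryotic_read_count / 1e5
            n_ok = int(rng.poisson(lam))
            n_fail = int(rng.binomial(n_ok, config.fail_filter_fraction)) if n_ok else 0
            link = config.genus_gene_links.get(gene)
            if link:
                link_genera = sorted(link)
                w = np.array([link[g] for g in link_genera], dtype=float)
                w = w / w.sum()
            else:
                link_genera, w = genera, None
            for k in range(n_ok + n_fail):
                counter += 1
                genus = str(rng.choice(link_genera, p=w))
                contig = f"{spec.name}_ctg{counter:06d}~g={genus.replace(' ', '.')}"
                failing = k >= n_ok
                if failing:
                    e_val = float(10 ** rng.uniform(-4.5, -1))
                    score = float(rng.uniform(5, 20))
                else:
                    e_val = float(10 ** rng.uniform(-40, -8))
                    score = float(rng.uniform(40, 600))
                span = int(rng.integers(
                    max(20, int(0.4 * entry.model_length_aa)), entry.model_length_aa + 1
                ))
                hit = HmmHitRecord(
                    contig_id=contig,
                    sample_id=spec.name,
                    gene_symbol=gene,
                    model_length=entry.model_length_aa,
                    bit_score=round(score, 1),
                    e_value=e_val,
                    ali_from=1,
                    ali_to=span,
                )
                hits.append(hit)
                query = entry.ko_code or entry.gene_symbol
                raw_lines.append((spec.name, contig, query, entry.model_length_aa,
                                  e_val, round(score, 1), 1, span))
                if rng.random() < config.contig_genus_unassigned_fraction:
                    lineage = lineage_for_genus(genus)[:5]  # down to family only
                else:
                    lineage = lineage_for_genus(genus)
                taxonomy.append(
                    ReadClassificationRecord(contig, "classified", 1, lineage, spec.name)
                )
        for d in range(config.decoy_models_per_sample):
            counter += 1
            contig = f"{spec.name}_ctg{counter:06d}~g=decoy"
            raw_lines.append((spec.name, contig, f"K9{d:04d}", 300,
                              1e-30, 123.0, 1, 250))
    return hits, taxonomy, raw_lines


def _write_domtblout(raw_lines: list[tuple], sample: str, path: Path) -> None:
    header = (
        "#                                                               --- full sequence --- "
        "-------------- this domain -------------   hmm coord   ali coord   env coord\n"
        "# target name        accession   tlen query name           accession   qlen   E-value  "
        "score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    "
        "to  acc description of target\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        for (s, contig, query, qlen, e_val, score, ali_from, ali_to) in raw_lines:
            if s != sample:
                continue
            fh.write(
                f"{contig} - {3 * qlen} {query} - {qlen} "
                f"{e_val:.1e} {score:.1f} 0.0 1 1 {e_val:.1e} {e_val:.1e} "
                f"{score:.1f} 0.0 1 {qlen} {ali_from} {ali_to} {ali_from} {ali_to} "
                f"0.90 -\n"
            )


def generate_mags(
    config: ScenarioConfig,
) -> tuple[list, list, pd.DataFrame, list[ReadClassificationRecord], list[HmmHitRecord]]:
    """Bin membership, QC, ANI matrix, contig taxonomy and planted gene hits.

    Contig taxonomy gives the spec's true taxon a ``vote_share`` fraction
    of classified contigs (the rest are drawn from the community).
    Planted units place filter-passing hits for every structural subunit
    (or the standalone gene) on the bin's contigs. ANI: declared species
    pairs draw in (95.5, 99.5); all other pairs in (76, 89).
    """
    from .io_formats import BinMembership, BinQcRecord

    catalog = load_default_catalog()
    rng = config._rng("mags")
    genera = sorted(config.genus_base_frequencies)
    memberships: list[BinMembership] = []
    qc: list[BinQcRecord] = []
    taxonomy: list[ReadClassificationRecord] = []
    hits: list[HmmHitRecord] = []
    for spec in config.mag_specs:
        contigs = [f"{spec.bin_id}_c{i + 1}" for i in range(spec.contig_count)]
        for c in contigs:
            memberships.append(BinMembership(spec.bin_id, c, spec.sample_id))
        qc.append(BinQcRecord(spec.bin_id, spec.completeness, spec.contamination))
        for c in contigs:
            if rng.random() < spec.vote_share:
                lineage = spec.true_lineage
            else:
                other = str(rng.choice(genera))
                lineage = lineage_for_genus(other)
            taxonomy.append(
                ReadClassificationRecord(c, "classified", 1, lineage, spec.sample_id)
            )
        planted_genes: list[str] = []
        for unit in spec.planted_units:
            if unit in catalog.cluster_ids:
                planted_genes.extend(cluster_members(catalog, unit, "structural"))
            else:
                planted_genes.append(unit)
        for gene in planted_genes:
            entry = catalog.entry(gene)
            contig = str(rng.choice(contigs))
            hits.append(
                HmmHitRecord(
                    contig_id=contig,
                    sample_id=spec.sample_id,
                    gene_symbol=gene,
                    model_length=entry.model_length_aa,
                    bit_score=float(round(rng.uniform(60, 400), 1)),
                    e_value=float(10 ** rng.uniform(-35, -10)),
                    ali_from=1,
                    ali_to=entry.model_length_aa,
                )
            )
    bin_ids = [s.bin_id for s in config.mag_specs]
    n = len(bin_ids)
    ani = np.zeros((n, n))
    pair = {(s.bin_id, s.species_pair_with) for s in config.mag_specs if s.species_pair_with}
    pair |= {(b, a) for a, b in pair}
    for i in range(n):
        for j in range(i, n):
            if i == j:
                ani[i, j] = 100.0
            elif (bin_ids[i], bin_ids[j]) in pair:
                ani[i, j] = ani[j, i] = round(rng.uniform(95.5, 99.5), 2)
            else:
                ani[i, j] = ani[j, i] = round(rng.uniform(76.0, 89.0), 2)
    ani_df = pd.DataFrame(ani, index=bin_ids, columns=bin_ids)
    return memberships, qc, ani_df, taxonomy, hits


def write_scenario(config: ScenarioConfig, outdir: str | Path,
                   catalog: GeneCatalog | None = None) -> dict[str, Path]:
    """Write a complete input directory for the pipeline; returns file map."""
    catalog = catalog or load_default_catalog()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    reads = generate_reads_classification(config)
    for sample, df in reads.items():
        p = outdir / f"{sample}.reads.kaiju.tsv"
        _frame_to_kaiju(df, p)
        paths[f"reads:{sample}"] = p

    _, contig_tax, raw_lines = generate_hdg_hits(config, catalog)
    mag_members, mag_qc, ani_df, mag_tax, mag_hits = generate_mags(config)

    for spec in config.samples:
        p = outdir / f"{spec.name}.hdg.domtblout"
        sample_lines = list(raw_lines)
        for h in mag_hits:
            if h.sample_id == spec.name:
                entry = catalog.entry(h.gene_symbol)
                sample_lines.append(
                    (spec.name, h.contig_id, entry.ko_code or h.gene_symbol,
                     h.model_length, h.e_value, h.bit_score, h.ali_from, h.ali_to)
                )
        _write_domtblout(sample_lines, spec.name, p)
        paths[f"hits:{spec.name}"] = p

        tax_records = [r for r in contig_tax + mag_tax if r.sample_id == spec.name]
        p = outdir / f"{spec.name}.contigs.kaiju.tsv"
        with p.open("w") as fh:
            for rec in tax_records:
                fh.write(
                    f"C\t{rec.read_id}\t{rec.taxon_id}\t"
                    + "; ".join(n for _, n in rec.lineage) + ";\n"
                )
        paths[f"contig_tax:{spec.name}"] = p

    with (outdir / "bins.tsv").open("w") as fh:
        for m in sorted(mag_members, key=lambda m: (m.contig_id, m.bin_id)):
            fh.write(f"{m.contig_id}\t{m.bin_id}\n")
    paths["bins"] = outdir / "bins.tsv"
    with (outdir / "bin_qc.tsv").open("w") as fh:
        fh.write("bin_id\tcompleteness\tcontamination\n")
        for q in sorted(mag_qc, key=lambda q: q.bin_id):
            fh.write(f"{q.bin_id}\t{q.completeness}\t{q.contamination}\n")
    paths["bin_qc"] = outdir / "bin_qc.tsv"
    ani_df.to_csv(outdir / "ani_matrix.tsv", sep="\t", lineterminator="\n")
    paths["ani"] = outdir / "ani_matrix.tsv"

    with (outdir / "sample_scales.tsv").open("w") as fh:
        fh.write("sample_id\tgenome_equivalents\tlibrary_reads\n")
        for spec in config.samples:
            fh.write(
                f"{spec.name}\t{spec.genome_equivalents}\t{spec.prokaryotic_read_count}\n"
            )
    paths["scales"] = outdir / "sample_scales.tsv"

    echo = {
        "seed": config.seed,
        "samples": [dataclasses.asdict(s) for s in config.samples],
    }
    (outdir / "scenario.json").write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
    paths["scenario"] = outdir / "scenario.json"
    return paths


def _bin_sample_map(config: ScenarioConfig) -> dict[str, str]:
    return {s.bin_id: s.sample_id for s in config.mag_specs}


def ofotfjorden_like(seed: int = 0) -> ScenarioConfig:
    """Three-environment preset emulating a fjord oil-in-ice study.

    Samples: seawater (SW), clean sea ice (SI) and crude-oil-encapsulating
    sea ice (SIO), 1.2e5/1.1e5/1.0e5 prokaryotic reads (SIO smallest, as
    in the emulated design). Baseline genus frequencies follow the
    seawater community the study reports (dominant Ca. Pelagibacter;
    degrader genera at their printed percentages); the enrichment factors
    reproduce the reported environment shifts (psychrophilic degraders
    such as Bermanella, Colwellia and Glaciecola strongly enriched in sea
    ice and further under oil), which makes the expected HDO-containing
    proportion ordering SIO > SI > SW. Gene hit rates put the short-chain
    alkane monooxygenase cluster at zero in SIO (undetected sentinel) and
    keep overall gene traffic highest in clean sea ice.
    """
    hdo_extra = [
        "Marinobacter", "Alcanivorax", "Oleispira", "Polaribacter",
        "Psychrobacter", "Octadecabacter", "Loktanella", "Marinomonas",
        "Halomonas", "Alteromonas", "Flavobacterium", "Roseobacter",
        "Thalassospira", "Erythrobacter", "Idiomarina", "Moritella",
        "Photobacterium", "Psychromonas", "Shewanella", "Paraglaciecola",
    ]
    base = {
        "Ca. Pelagibacter": 12.0,
        "Synechococcus": 2.0,
        "Ca. Actinomarina": 1.8,
        "Ca. Thioglobus": 1.0,
        "Nitrosopumilus": 0.051,
        "Planktomarina": 1.58,
        "Pseudomonas": 0.20,
        "Sulfitobacter": 0.19,
        "Pseudoalteromonas": 0.30,
        "Colwellia": 0.01,
        "Bermanella": 0.01,
        "Glaciecola": 0.05,
        "Roseovarius": 0.12,
        "Ruegeria": 0.11,
        "Vibrio": 0.10,
    }
    for i, g in enumerate(hdo_extra):
        base[g] = 0.2575 - 0.004 * i
    base["OtherTaxa"] = 100.0 - sum(base.values())  # non-HDO background mass

    enrich: dict[tuple[str, str], float] = {}
    ice_common = {
        "Colwellia": 37.0, "Bermanella": 35.0, "Glaciecola": 8.4,
        "Pseudomonas": 1.3, "Sulfitobacter": 2.2, "Planktomarina": 0.96,
        "Ca. Pelagibacter": 1.9, "Synechococcus": 0.3, "Ca. Actinomarina": 0.4,
        "Nitrosopumilus": 1.7, "Octadecabacter": 2.0, "Polaribacter": 1.6,
        "Psychrobacter": 2.0, "Moritella": 1.8, "Psychromonas": 2.0,
    }
    for g, f in ice_common.items():
        enrich[("SI", g)] = f
    oil = dict(ice_common)
    oil.update(
        {
            "Colwellia": 174.0, "Bermanella": 60.0, "Glaciecola": 21.0,
            "Pseudomonas": 1.8, "Paraglaciecola": 3.0, "Shewanella": 3.0,
            "Nitrosopumilus": 3.1, "Planktomarina": 0.70,
            "Marinobacter": 2.5, "Alcanivorax": 3.5, "Oleispira": 3.0,
        }
    )
    for g, f in oil.items():
        enrich[("SIO", g)] = f

    catalog = load_default_catalog()
    rates: dict[tuple[str, str], float] = {}
    # Deterministic per-gene base rates spread over [0.5, 12]; sample
    # multipliers keep total gene traffic highest in clean sea ice.
    # Rate multipliers chosen so that, after the reads/genome-equivalent
    # scaling of each sample, expected RPKG group totals order SI > SW > SIO
    # with the roughly +17%/-9% margins of the emulated design.
    sample_factor = {"SW": 1.0, "SI": 1.44, "SIO": 0.87}
    for i, sym in enumerate(catalog.symbols):
        base_rate = 0.5 + (i * 37 % 24) / 2.0
        if sym == "rubB":
            base_rate = 25.0
        for s, f in sample_factor.items():
            rates[(s, sym)] = round(base_rate * f, 3)
    for g in cluster_members(catalog, "bmoBCDXYZ"):
        rates[("SIO", g)] = 0.0  # short-chain alkane cluster absent under oil
        rates[("SI", g)] = rates[("SW", g)] * 2.0
    links = {
        "almA": {"Bermanella": 3.0, "Bradyrhizobium": 3.0, "Colwellia": 2.0,
                 "Ca. Pelagibacter": 1.0, "Planktomarina": 1.0, "Glaciecola": 1.0},
        "alkB1_2": {"Bermanella": 4.0, "Alcanivorax": 2.0, "Marinobacter": 2.0,
                    "Ca. Pelagibacter": 1.0},
        "chnB": {"Ca. Pelagibacter": 5.0, "Planktomarina": 2.0, "Colwellia": 1.0},
        "yaiY": {"Ca. Pelagibacter": 4.0, "Planktomarina": 3.0, "Colwellia": 2.0,
                 "Nitrosopumilus": 0.5},
    }
    base["Bradyrhizobium"] = 0.05
    base["OtherTaxa"] -= 0.05

    rhodo = lineage_for_genus("Planktomarina")[:5]
    mags = [
        MagSpec("SW7b", "SW", lineage_for_genus("Planktomarina"), 40, 82.0, 1.5,
                planted_units=("almA", "rubB", "xylAM"),
                species_pair_with="SI15b"),
        MagSpec("SI15b", "SI", lineage_for_genus("Planktomarina"), 35, 76.0, 2.0,
                planted_units=("almA", "rubB", "xylAM")),
        MagSpec("SW2b", "SW", lineage_for_genus("Sulfitobacter"), 30, 68.0, 3.0,
                planted_units=("rubB", "hcaCDEF"), species_pair_with="SI21b"),
        MagSpec("SI21b", "SI", lineage_for_genus("Sulfitobacter"), 30, 71.0, 4.0,
                planted_units=("rubB", "hcaCDEF")),
        MagSpec("SIO3b", "SIO", lineage_for_genus("Glaciecola"), 25, 64.0, 2.5,
                planted_units=("alkB1_2", "gst")),
        MagSpec("SIO5b", "SIO", lineage_for_genus("Bermanella"), 25, 55.0, 1.0,
                planted_units=("almA", "alkB1_2")),
        MagSpec("SW9b", "SW", rhodo + (("genus", "Octadecabacter"),
                                       ("species", "Octadecabacter synthetica")),
                20, 40.0, 5.0),  # fails the completeness filter
        MagSpec("SI30b", "SI", lineage_for_genus("Colwellia"), 22, 88.0, 12.5),
        # fails the contamination filter
    ]

    return ScenarioConfig(
        seed=seed,
        samples=[
            SampleSpec("SW", 120_000, 55.0),
            SampleSpec("SI", 110_000, 62.0),
            SampleSpec("SIO", 100_000, 48.0),
        ],
        genus_base_frequencies=base,
        enrichment_effects=enrich,
        hdg_hit_rates=rates,
        genus_gene_links=links,
        mag_specs=mags,
    )
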