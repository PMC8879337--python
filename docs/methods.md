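# Methods

This note documents the models, rules and numerical choices behind
`hdgkit`, what the synthetic-data generator does and does not emulate, and
the decisions taken where the design was genuinely open.

## Scope and inputs

The package starts where upstream tools stop. It consumes: per-read (and
per-contig) taxonomic classifications in the common classifier per-read
TSV dialect (status C/U, read id, taxon id, optional semicolon-separated
lineage names mapped positionally onto the seven canonical ranks);
profile-HMM per-domain hit tables (domtblout dialect; per-domain
conditional E-value and domain bit score are the filtering quantities, one
record per domain line); two-column contig→bin membership; CheckM-style
bin QC; square ANI matrices; and a per-sample scale table carrying genome
equivalents and library size. Read QC, assembly, binning, classification,
HMM searching, genome-equivalent estimation and ANI computation are out of
scope by design — their outputs are inputs here.

## Community profiles and HDO accounting

Genus-level proportions use *prokaryotic* reads (classified Bacteria +
Archaea) as the denominator; kingdom-level shares use all classified
reads. Reads classified but lacking the requested rank count only toward
the unclassified-at-rank remainder, so proportions at a rank sum to ≤ 100 %.

The HDO proportion of a sample is the sum of genus proportions over a
reference list of genera containing described hydrocarbon degraders.
Matching is exact string match after whitespace normalisation; "Ca."
prefixes are part of the name. The bundled reference list is a synthetic
stand-in at the documented size (369 names): a curated set of real
degrader genera padded with clearly marked placeholders, to be replaced
with a vetted list for real analyses.

Reported comparison values keep full precision internally and are
reported half-up: 2 decimals for percentage-point differences, 1 decimal
for fold changes. A fold change against a zero denominator is the
explicit `numerator_only` outcome, never infinity. Venn partitions over
samples retain a genus when its proportion strictly exceeds the threshold
(default 0.05 % of prokaryotic reads) and return all 2^k − 1 regions.
Top-N rankings break ties lexicographically — a repository convention,
documented because upstream reports rarely state one.

## Gene catalog

The catalog is data, not code: a TSV with one row per gene (symbol, KO
code, functional group, cluster id, subunit role, general-metabolism
flag, HMM model length). Validation enforces: unique symbols, unique KO
codes, cluster id present exactly for clustered subunits, and at least
one structural subunit per cluster. Functional groups are alkane,
monoaromatic (MAH), polyaromatic (PAH) and various (multi-pathway). The
16-gene general-metabolism exclusion list used by taxon association is
checked to be a subset of the rows flagged general. Rows not individually
attested in the analysis this package operationalises are flagged
`curated` and are replaceable defaults; the KO alias map lets domtblout
query names be either gene symbols or KO codes.

## Quantification

Hit acceptance uses configurable thresholds, default i-E-value ≤ 1e-5 and
domain score ≥ 25 — common practice for KO HMM screens; the defaults are
explicit because results depend on them. Several domains of one gene on
one contig collapse to the best-scoring domain (ties: lower e-value, then
leftmost alignment start), making normalisation idempotent under input
duplication.

RPKG divides the accepted hit count by gene length in kb and genome
equivalents. The length term defaults to 3 × the HMM model length in
amino acids (nt conversion); a per-sample mean alignment-span variant is
available behind `length_from="alignment"` since the field does not agree
on a single convention. Zero-hit genes get explicit zero rows.

Cluster aggregation averages the RPKG of structural subunits only.
Electron-transport and ferredoxin-reductase subunits remain as gene rows
but never enter cluster means or group totals, because such models
recruit homologues from unrelated pathways and inflate counts. Group
totals sum over *quantification units* — clusters once, standalone genes
once, cluster members never.

Ratio flagging: per functional group and axis, ratios are computed for
units with rpkg > 0 in both samples; the band is mean ± 1·SD with the
n−1 SD estimator. The "1·SD" width and the n−1 estimator are package
choices where the operationalised procedure is stated only as "outside
the standard deviation of the ratios". Units detected on one side only
get `undetected_in_numerator` / `undetected_in_denominator` sentinels and
are excluded from the band statistics; groups with fewer than two finite
ratios have undefined SD and their units are flagged `within` with a null
SD recorded.

## Taxon association

Contigs carrying at least one accepted hit to a non-excluded (specific)
HDG are counted once per (contig, gene); exclusion is per gene, so a
contig with both an excluded and a specific gene stays, labelled with the
specific gene only. Contigs without a genus-rank classification fall into
an `unassigned` bucket reported separately — the per-gene partition
invariant (genera + unassigned = distinct contigs) is tested. Counts are
scaled by min(size)/size(sample) with size = classified prokaryotic reads
(the least surprising "value of the smallest metagenome"; any positive
size measure can be passed). Top-genus ranking is pooled across samples
by default (a per-sample variant exists) with lexicographic ties.

Novelty categories per genus: on the HDO reference list →
`known_degrader`; otherwise, against an optional reference-genome gene
profile table: genus absent → `missing_from_brite`; empty gene set →
`not_previously_described_no_brite_hdg`; observed ⊆ reference →
`brite_concordant`; otherwise `brite_discordant` (partial overlap counts
as discordant). The function is total: every queried genus gets exactly
one category.

## MAG analysis

QC pass requires completeness ≥ 50 and contamination ≤ 10 — boundary
values pass because the exclusion rule is "< 50 %" / "> 10 %". Consensus
taxonomy walks species → superkingdom; the vote denominator at a rank is
the MAG's contigs classified at that rank (an open point — all-contig
denominators are the alternative; the classified-contig reading is the
default and documented), votes are per contig (a length-weighted variant
is available), and the winner must strictly exceed 60 % at genus/species
and 90 % above. ANI clusters are single-linkage connected components over
edges strictly > 95 % (scipy's sparse connected components; an
independent union-find oracle checks it in the tests). Cluster gene
presence in a MAG requires ≥ 50 % of structural subunits detected —
exactly half counts as present; standalone genes are plain hit
indicators.

## Synthetic data

The generator states a world and draws from it: multinomial genus labels
per sample (base frequencies × per-sample enrichment factors,
renormalised), Poisson accepted-hit counts per (sample, gene) at
`rate · reads / 1e5`, hits placed on contigs whose genus follows the
gene's weight vector, a configurable fraction of emitted hits failing the
default filters, a couple of decoy model lines per sample (exercising the
skip tally), and MAG specs with a contig-vote share, planted gene units
and declared ANI species pairs. Both models are chosen for analytic
standard errors: recovery tests can assert |estimate − truth| ≤ 3 SE with
SE in closed form. Output is byte-identical under a fixed seed.

The bundled preset emulates a fjord oil-in-ice design: three samples
(seawater SW, clean sea ice SI, oil-encapsulating sea ice SIO) with
1.2/1.1/1.0 × 10^5 prokaryotic reads (the oil sample smallest, as in the
emulated study). Baseline frequencies put the named degrader genera at
their reported seawater percentages (e.g. *Planktomarina* 1.58 %,
*Pseudomonas* 0.20 %, *Sulfitobacter* 0.19 %) and calibrate the remaining
degrader mass so the seawater HDO share is 7.11 %; enrichment factors
encode the reported shifts (*Colwellia* ×37 and *Bermanella* ×35 in clean
ice, stronger under oil; *Planktomarina* slightly down), giving expected
HDO shares ≈ 8.5 % (SI) and ≈ 11.8 % (SIO) — the qualitative ordering
SIO > SI > SW is the tested property. Gene rates are deterministic
per-gene values spread over [0.5, 12.5] hits per 10^5 reads (the
oxidoreductase *rubB* highest at 25), with per-sample multipliers chosen
so expected RPKG totals order SI > SW > SIO; the short-chain alkane
cluster *bmoBCDXYZ* is doubled in SI and zeroed in SIO to exercise the
undetected sentinels.

What the generator does **not** emulate: sequence-level artefacts (no
reads or contig sequences exist), classifier bias and misclassification,
assembly fragmentation or chimerism, correlated hits of neighbouring
genes on one contig, length-dependent binning quality, and overdispersion
beyond Poisson/multinomial noise. A green recovery test therefore
establishes that the pipeline's arithmetic recovers a stated world's
parameters — not that any upstream tool is accurate.

## Numerical conventions

Half-up rounding for reported values (banker's rounding never used for
reporting); deterministic sort keys on all written tables; 1-based
inclusive coordinates preserved from the source dialects; lexicographic
tie-breaks wherever a ranking or winner is selected; random streams
derived from a single seed through named, order-independent substreams.

## Known limitations

The bundled catalog's per-cluster subunit inventories and model lengths
for `curated` rows are plausible defaults, not authoritative annotations;
analyses of real data should supply a project-specific catalog and HDO
list. The ratio-SD rule is scale-sensitive (ratios, not log-ratios), which
mirrors the operationalised procedure but makes the band asymmetric
around 1. Consensus taxonomy ignores classifier confidence scores. The
association stage counts contigs, not reads or coverage, so highly
fragmented genomes are over-weighted relative to well-assembled ones.
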