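"""hdgkit: hydrocarbon-degradation potential profiling for marine metagenomes.

Downstream analysis of short-read metagenomes from seawater and sea ice:
taxonomic community profiles with hydrocarbon-degrader (HDO) genus
accounting, RPKG-normalised hydrocarbon-degradation-gene (HDG)
quantification with ratio-SD flagging, contig-level taxon-gene
association with novelty categorisation, and MAG quality/taxonomy/gene
presence analysis. All stages consume plain-text tables produced by
standard upstream tools (read classifiers, profile-HMM searches, binners,
genome QC) and are exercisable end to end on synthetic data.
"""

from importlib import resources

__version__ = "0.1.0"

CANONICAL_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


def bundled_data_path(name: str):
    """Return a context-managed path to a bundled data file."""
    return resources.as_file(resources.files("hdgkit.data").joinpath(name))


__all__ = ["CANONICAL_RANKS", "bundled_data_path", "__version__"]
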