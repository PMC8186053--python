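"""Packaged reference tables from a published survey of 14 fish genomes.

Three TSVs transcribed from the printed tables of a genome-wide
microsatellite survey of 14 teleost/holostean species (identified by
four-letter abbreviations, e.g. ``Drer`` = *Danio rerio*):

* ``fish_genome_lengths`` — assembly sizes: total Mbp, valid (non-N) Mbp,
  %N per species;
* ``fish_repeat_summary`` — per motif size (1–6 and total): locus counts,
  repeat bp, relative abundance (loci/Mb), relative density (bp/Mb),
  coverage (%), GC bp and GC (%);
* ``fish_region_composition`` — percent motif abundance per genomic
  region (all/intergenic/intron/exon × motif size).

These serve as inputs for recomputing the survey's derived statistics
and as composition templates for the synthetic-genome generator. Where
the printed tables are internally inconsistent (a handful of cells), the
printed values are kept as printed.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

SPECIES_ABBREVS = (
    "Amex", "Ccar", "Drer", "Csem", "Eluc", "Ipun", "Locu",
    "Nfur", "Olat", "Okis", "Omyk", "Onil", "Pret", "Trub",
)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("ssr_atlas").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


@lru_cache(maxsize=None)
def genome_lengths() -> pd.DataFrame:
    """Assembly length accounting, one row per species."""
    return _read("fish_genome_lengths.tsv").set_index("abbrev")


@lru_cache(maxsize=None)
def repeat_summary() -> pd.DataFrame:
    """Counts and derived statistics per (species, motif size | total)."""
    df = _read("fish_repeat_summary.tsv")
    return df.set_index(["abbrev", "motif_size"])


@lru_cache(maxsize=None)
def region_composition() -> pd.DataFrame:
    """Percent motif abundance per (species, region) x motif size."""
    df = _read("fish_region_composition.tsv")
    return df.set_index(["abbrev", "region"])


def valid_length_bp(abbrev: str) -> float:
    """Valid (non-N) assembly length in bp for a species."""
    return float(genome_lengths().loc[abbrev, "valid_mbp"]) * 1e6
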