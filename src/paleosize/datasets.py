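"""Published Disko Bay reference values bundled with the package.

The study system is a West Greenland (Disko Bay) marine sediment core in
which the six most abundant identifiable dinoflagellate cyst taxa were
measured in two contrasting climate intervals: a relatively warm medieval
period (~1270–1460 AD) and the colder Little Ice Age (~1590–1710 AD).
The raw per-cyst measurements were not deposited; what is public are the
per-species summary statistics, the community-level weighted summaries,
the dominant-species assemblage percentages, and the literature size
table. Those published numbers live here, as inputs for worked examples
and for the synthetic-data generator in :mod:`paleosize.synth`.
"""

from __future__ import annotations

from importlib import resources

from .io_model import LiteratureEntry, read_literature

WARM = "warm"
COLD = "cold"
PERIODS = (WARM, COLD)

#: The six measured taxa (three heterotrophic, three phototrophic).
SPECIES = (
    "Brigantedinium simplex",
    "Islandinium minutum",
    "Islandinium? cezare",
    "Pentapharsodinium dalei",
    "Spiniferites elongatus",
    "Spiniferites ramosus",
)

#: Published per-species diameter summaries: (species, period) -> (mean μm, SD μm, n).
SPECIES_SUMMARIES: dict[tuple[str, str], tuple[float, float, int]] = {
    ("Brigantedinium simplex", WARM): (47.75, 5.75, 30),
    ("Brigantedinium simplex", COLD): (51.68, 7.28, 30),
    ("Islandinium minutum", WARM): (34.08, 4.35, 52),
    ("Islandinium minutum", COLD): (37.96, 4.34, 51),
    ("Islandinium? cezare", WARM): (24.55, 3.39, 34),
    ("Islandinium? cezare", COLD): (26.89, 5.54, 55),
    ("Pentapharsodinium dalei", WARM): (25.85, 3.30, 57),
    ("Pentapharsodinium dalei", COLD): (27.31, 2.71, 55),
    ("Spiniferites elongatus", WARM): (39.65, 4.22, 27),
    ("Spiniferites elongatus", COLD): (39.17, 4.41, 21),
    ("Spiniferites ramosus", WARM): (37.33, 3.59, 19),
    ("Spiniferites ramosus", COLD): (36.84, 4.01, 17),
}

#: Published community-level weighted summaries:
#: (level, period) -> (weighted mean μm, weighted SD μm, n used for SE).
#: At the interspecific levels n is the number of species (6), not cysts.
COMMUNITY_SUMMARIES: dict[tuple[str, str], tuple[float, float, int]] = {
    ("intra+inter", WARM): (31.80, 5.97, 219),
    ("intra+inter", COLD): (36.24, 6.20, 229),
    ("inter", WARM): (33.30, 6.60, 6),
    ("inter", COLD): (34.53, 6.76, 6),
    ("inter-literature", WARM): (34.85, 5.76, 6),
    ("inter-literature", COLD): (36.19, 4.70, 6),
}

#: Published relative abundances of the dominant taxa (fractions of the
#: assemblage, rare/unidentifiable cysts excluded).
DOMINANT_FRACTIONS: dict[str, dict[str, float]] = {
    WARM: {
        "Islandinium minutum": 0.50,
        "Pentapharsodinium dalei": 0.20,
        "Islandinium? cezare": 0.04,
    },
    COLD: {
        "Islandinium minutum": 0.65,
        "Pentapharsodinium dalei": 0.08,
        "Islandinium? cezare": 0.06,
    },
}

#: Total counted cysts behind the assemblage percentages, per period.
ASSEMBLAGE_TOTALS: dict[str, int] = {WARM: 613, COLD: 680}


def load_default_literature() -> list[LiteratureEntry]:
    """Load the bundled literature size table for the six measured taxa.

    Diameter ranges come from the Modern Dinocyst Key; the two
    *Spiniferites* species carry length and width ranges only, with the
    diameter range derived downstream by endpoint averaging.
    """
    ref = resources.files("paleosize.data") / "literature_sizes.csv"
    with resources.as_file(ref) as path:
        return read_literature(path)
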