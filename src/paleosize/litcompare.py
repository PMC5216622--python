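"""Literature size-range conversion, midpoints and measured-vs-literature flags.

Published cyst size tables report either a diameter range directly or,
for elongate taxa measured as length × width, separate length and width
ranges. The conversion averages length and width endpoint-wise:
d_min = round((l_min + w_min)/2), d_max = round((l_max + w_max)/2). The
midpoint of a range is round((min + max)/2). All rounding is half away
from zero to the nearest integer — the rule that reproduces published
integer tables (50.5 → 51, 23.5 → 24, 34.5 → 35); banker's rounding
would not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .decomp import CommunityMean, SpeciesWeights, community_mean_inter
from .io_model import LiteratureEntry, SpeciesSummary

__all__ = [
    "RangeComparison",
    "round_half_away",
    "lw_to_diameter",
    "midpoint",
    "resolve_diameter_range",
    "compare_species",
    "literature_community_mean",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def lw_to_diameter(
    length_range: Sequence[float], width_range: Sequence[float]
) -> tuple[int, int]:
    """Convert length and width ranges to a diameter range by averaging
    the minimum and the maximum endpoints, respectively."""
    (l_min, l_max), (w_min, w_max) = length_range, width_range
    return (
        round_half_away((l_min + w_min) / 2.0),
        round_half_away((l_max + w_max) / 2.0),
    )


def midpoint(size_range: Sequence[float]) -> int:
    """Midpoint of a size range, rounded half away from zero."""
    lo, hi = size_range
    if lo > hi:
        raise ValueError(f"range minimum {lo} exceeds maximum {hi}")
    return round_half_away((lo + hi) / 2.0)


def resolve_diameter_range(entry: LiteratureEntry) -> tuple[int, int]:
    """The entry's diameter range, derived from length/width if absent."""
    if entry.diameter_range is not None:
        return entry.diameter_range
    return lw_to_diameter(entry.length_range, entry.width_range)


@dataclass(frozen=True)
class RangeComparison:
    """Measured sizes of one species versus its literature range.

    ``measured_means`` maps period to the measured mean; ``flags`` is the
    set of strict-inequality flags that hold: ``mean_below_range`` /
    ``mean_above_range`` (any period mean outside the literature range)
    and ``measured_extends_below`` / ``measured_extends_above`` (the
    measured total size range passes an endpoint).
    """

    species: str
    measured_means: Mapping[str, float]
    measured_range: tuple[float, float]
    literature_range: tuple[int, int]
    midpoint: int
    mean_below_periods: frozenset[str]
    mean_above_periods: frozenset[str]

    @property
    def flags(self) -> frozenset[str]:
        out = set()
        if self.mean_below_periods:
            out.add("mean_below_range")
        if self.mean_above_periods:
            out.add("mean_above_range")
        if self.measured_range[0] < self.literature_range[0]:
            out.add("measured_extends_below")
        if self.measured_range[1] > self.literature_range[1]:
            out.add("measured_extends_above")
        return frozenset(out)


def compare_species(
    summaries: Iterable[SpeciesSummary],
    measured_range: Sequence[float],
    entry: LiteratureEntry,
) -> RangeComparison:
    """Compare one species' measured means and total size range against
    its literature range and midpoint. ``summaries`` holds that species'
    per-period rows."""
    summaries = [s for s in summaries if s.species == entry.species]
    if not summaries:
        raise ValueError(f"no summaries for species {entry.species!r}")
    lit_range = resolve_diameter_range(entry)
    means = {s.period: s.mean for s in summaries}
    return RangeComparison(
        species=entry.species,
        measured_means=means,
        measured_range=(float(measured_range[0]), float(measured_range[1])),
        literature_range=lit_range,
        midpoint=midpoint(lit_range),
        mean_below_periods=frozenset(p for p, m in means.items() if m < lit_range[0]),
        mean_above_periods=frozenset(p for p, m in means.items() if m > lit_range[1]),
    )


def literature_community_mean(
    entries: Iterable[LiteratureEntry], weights: SpeciesWeights
) -> CommunityMean:
    """Interspecific community mean using literature midpoints as the fixed
    species trait values, with the same per-period abundance weights as
    the measured interspecific mean."""
    midpoints = {
        e.species: float(midpoint(resolve_diameter_range(e))) for e in entries
    }
    return community_mean_inter(midpoints, weights, level="inter-literature")
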