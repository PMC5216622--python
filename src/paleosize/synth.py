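"""Seeded generator of synthetic cyst measurement and assemblage tables.

The raw Disko Bay per-cyst measurements were never deposited; what is
public are per-species summary statistics (mean, SD, n per climate
period), dominant-species assemblage percentages and per-period counting
totals. This module turns those published numbers into synthetic data
with the same statistical structure: per-(species, period) diameters are
drawn from a normal distribution (truncated below at 0.1 μm to guard
positivity — numerically irrelevant at realistic parameter values) and
assemblage counts are allocated from relative-abundance fractions.

Randomness is driven by a single integer seed through a splittable
generator: each (species, period) cell gets its own substream, derived in
sorted key order, so output is reproducible regardless of record order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import datasets
from .io_model import AssemblageCount, DiameterObservation

__all__ = [
    "SpeciesPeriodSpec",
    "SynthConfig",
    "default_config",
    "generate_observations",
    "generate_assemblage",
    "sample_with_moments",
]

#: Lower truncation bound for generated diameters (μm).
MIN_DIAMETER = 0.1


@dataclass(frozen=True)
class SpeciesPeriodSpec:
    """Generative parameters for one species in one period.

    ``mean``/``sd`` are the diameter distribution parameters in μm,
    ``n_measured`` the number of cysts measured (≈20 per taxon per sample
    in the study), and ``assemblage_fraction`` the species' relative
    abundance among the included taxa in that period.
    """

    species: str
    period: str
    mean: float
    sd: float
    n_measured: int
    assemblage_fraction: float

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n_measured < 1:
            raise ValueError("n_measured must be >= 1")
        if not (0.0 <= self.assemblage_fraction <= 1.0):
            raise ValueError("assemblage_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SynthConfig:
    """A full generator configuration: one spec per (species, period) cell,
    per-period assemblage totals, and the integer seed."""

    specs: tuple[SpeciesPeriodSpec, ...]
    assemblage_total_per_period: Mapping[str, int]
    seed: int = 0

    def __init__(
        self,
        specs: Sequence[SpeciesPeriodSpec],
        assemblage_total_per_period: Mapping[str, int],
        seed: int = 0,
    ):
        specs = tuple(specs)
        keys = [(s.species, s.period) for s in specs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (species, period) in specs")
        totals = dict(assemblage_total_per_period)
        for period, total in totals.items():
            if total < 1:
                raise ValueError(f"assemblage total for {period!r} must be positive")
        for period in {s.period for s in specs}:
            frac = sum(s.assemblage_fraction for s in specs if s.period == period)
            if abs(frac - 1.0) > 1e-9:
                raise ValueError(
                    f"assemblage fractions for {period!r} sum to {frac}, not 1"
                )
        object.__setattr__(self, "specs", specs)
        object.__setattr__(self, "assemblage_total_per_period", totals)
        object.__setattr__(self, "seed", int(seed))

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=int(seed))

    def periods(self) -> tuple[str, ...]:
        return tuple(sorted({s.period for s in self.specs}))


def default_config(seed: int = 0) -> SynthConfig:
    """The bundled Disko Bay fixture: six species × {warm, cold}.

    Per-species means/SDs/n are the published summaries; assemblage totals
    are 613 (warm) and 680 (cold) counted cysts. Relative abundances of
    the three dominant taxa are the published percentages (I. minutum
    0.50→0.65, P. dalei 0.20→0.08, I.? cezare 0.04→0.06 from warm to
    cold); the remainder is split across B. simplex, S. elongatus and
    S. ramosus proportionally to their measured n in that period, then
    renormalized over the six species. The minor-species split is a
    fixture convention, not a published value.
    """
    fractions: dict[tuple[str, str], float] = {}
    for period in datasets.PERIODS:
        dominant = datasets.DOMINANT_FRACTIONS[period]
        residual = 1.0 - sum(dominant.values())
        minors = [s for s in datasets.SPECIES if s not in dominant]
        minor_n = {s: datasets.SPECIES_SUMMARIES[(s, period)][2] for s in minors}
        total_minor_n = sum(minor_n.values())
        raw = dict(dominant)
        for s in minors:
            raw[s] = residual * minor_n[s] / total_minor_n
        norm = sum(raw.values())
        for s, f in raw.items():
            fractions[(s, period)] = f / norm
    specs = [
        SpeciesPeriodSpec(
            species=species,
            period=period,
            mean=datasets.SPECIES_SUMMARIES[(species, period)][0],
            sd=datasets.SPECIES_SUMMARIES[(species, period)][1],
            n_measured=datasets.SPECIES_SUMMARIES[(species, period)][2],
            assemblage_fraction=fractions[(species, period)],
        )
        for species in datasets.SPECIES
        for period in datasets.PERIODS
    ]
    return SynthConfig(specs, dict(datasets.ASSEMBLAGE_TOTALS), seed=seed)


def _substreams(config: SynthConfig) -> dict[tuple[str, str], np.random.Generator]:
    """One child generator per (species, period), in sorted key order."""
    ordered = sorted(config.specs, key=lambda s: (s.species, s.period))
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(ordered))
    return {
        (spec.species, spec.period): np.random.default_rng(child)
        for spec, child in zip(ordered, children)
    }


def generate_observations(config: SynthConfig) -> list[DiameterObservation]:
    """Draw exactly n_measured diameters per (species, period) cell.

    Diameters follow normal(mean, sd) truncated below at 0.1 μm; a spec
    with sd = 0 yields constant values. Identical seeds give identical
    tables; different cells use independent substreams.
    """
    rngs = _substreams(config)
    records: list[DiameterObservation] = []
    for spec in config.specs:
        rng = rngs[(spec.species, spec.period)]
        if spec.sd == 0:
            values = np.full(spec.n_measured, spec.mean)
        else:
            a = (MIN_DIAMETER - spec.mean) / spec.sd
            values = stats.truncnorm.rvs(
                a, np.inf, loc=spec.mean, scale=spec.sd,
                size=spec.n_measured, random_state=rng,
            )
        records.extend(
            DiameterObservation(spec.species, spec.period, float(v)) for v in values
        )
    return records


def generate_assemblage(config: SynthConfig) -> list[AssemblageCount]:
    """Deterministic assemblage counts from fractions and per-period totals.

    Counts are allocated by largest-remainder apportionment: each species
    gets floor(fraction × total) and the leftover cysts go to the species
    with the largest fractional parts. Per-period counts sum exactly to
    the configured total and every count is within one cyst of
    fraction × total (the quota rule).
    """
    records: list[AssemblageCount] = []
    for period in config.periods():
        specs = sorted(
            (s for s in config.specs if s.period == period), key=lambda s: s.species
        )
        total = config.assemblage_total_per_period[period]
        quotas = {s.species: s.assemblage_fraction * total for s in specs}
        counts = {sp: int(np.floor(q)) for sp, q in quotas.items()}
        leftover = total - sum(counts.values())
        by_remainder = sorted(
            quotas, key=lambda sp: (quotas[sp] - counts[sp], sp), reverse=True
        )
        for sp in by_remainder[:leftover]:
            counts[sp] += 1
        records.extend(AssemblageCount(s.species, period, counts[s.species]) for s in specs)
    return records


def sample_with_moments(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Random normal-shaped sample rescaled to have *exactly* the given
    sample mean and sample SD (ddof=1). Useful for building
    summary-equivalent samples from published statistics."""
    if n < 2:
        raise ValueError("need n >= 2")
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
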