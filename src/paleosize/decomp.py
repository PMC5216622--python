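"""Community-weighted mean cyst size and its intra/interspecific partition.

A shift in the community mean trait between two periods can come from two
sources: species changing their own trait values (intraspecific change,
phenotypic plasticity) and the community changing its species composition
(interspecific change, species turnover). The decomposition computes

* x̄_intra+inter — the community-weighted mean of the raw observations,
  with each observation weighted by w_obs = w_spe / m_spe, where w_spe is
  the species' relative abundance in the assemblage of that period and
  m_spe the number of measured cysts of the species in that period;
* x̄_inter — the community-weighted mean with species trait values frozen
  at their cross-period species means Ø_avg, so it varies between periods
  only through the abundance weights;
* Δ_total = x̄(cmp)_intra+inter − x̄(ref)_intra+inter,
  Δ_inter = x̄(cmp)_inter − x̄(ref)_inter, and
  Δ_intra = Δ_total − Δ_inter (exact by construction).

The reference period is the warm period and the comparison the cold one
in the Disko Bay analysis, so deltas read "cold minus warm".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import DegenerateWeightsError, InsufficientDataError
from .io_model import AssemblageCount, DiameterObservation
from .wstats import WeightedSample, weighted_mean, weighted_sd, weighted_se

__all__ = [
    "SpeciesWeights",
    "CommunityMean",
    "DecompositionResult",
    "species_weights",
    "observation_weights",
    "community_mean_intra_inter",
    "species_pooled_mean",
    "community_mean_inter",
    "decompose",
    "decompose_from_means",
    "linear_change_percent",
    "volume_change_percent",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesWeights:
    """Relative-abundance weights w_spe for one period; they sum to 1."""

    period: str
    weights: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species weights sum to {total}, not 1")
        object.__setattr__(self, "weights", dict(self.weights))

    def __getitem__(self, species: str) -> float:
        return self.weights[species]

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.weights))


@dataclass(frozen=True)
class CommunityMean:
    """A community-weighted mean with its weighted SD and SE.

    ``level`` is one of ``intra+inter`` (observation level),
    ``inter`` (species means) or ``inter-literature`` (literature
    midpoints); at the two interspecific levels ``n_obs`` is the number
    of species, not cysts.
    """

    period: str
    level: str
    mean: float
    sd: float
    se: float
    n_obs: int


@dataclass(frozen=True)
class DecompositionResult:
    """Partition of the community mean change into intra/interspecific parts.

    ``delta_intra + delta_inter == delta_total`` exactly; fractions are
    signed ratios of delta_total and are None when delta_total is zero.
    """

    delta_total: float
    delta_inter: float
    delta_intra: float
    fraction_intra: float | None
    fraction_inter: float | None

    @classmethod
    def from_deltas(cls, delta_total: float, delta_inter: float) -> "DecompositionResult":
        delta_intra = delta_total - delta_inter
        if delta_total == 0:
            return cls(delta_total, delta_inter, delta_intra, None, None)
        return cls(
            delta_total,
            delta_inter,
            delta_intra,
            fraction_intra=delta_intra / delta_total,
            fraction_inter=delta_inter / delta_total,
        )


def species_weights(
    assemblage: Iterable[AssemblageCount],
    period: str,
    included_species: Iterable[str] | None = None,
) -> SpeciesWeights:
    """Relative-abundance weights w_spe = count_spe / Σ counts for a period.

    When ``included_species`` is given, weights are renormalized over that
    set (every included species must have a count for the period).
    """
    counts = {a.species: a.count for a in assemblage if a.period == period}
    if included_species is not None:
        included = set(included_species)
        missing = included - counts.keys()
        if missing:
            raise KeyError(
                f"no assemblage count for {sorted(missing)} in period {period!r}"
            )
        counts = {s: c for s, c in counts.items() if s in included}
    if not counts:
        raise DegenerateWeightsError(f"no assemblage counts for period {period!r}")
    total = sum(counts.values())
    if total == 0:
        raise DegenerateWeightsError(f"zero total count for period {period!r}")
    return SpeciesWeights(period, {s: c / total for s, c in counts.items()})


def observation_weights(
    observations: Sequence[DiameterObservation], weights: SpeciesWeights
) -> list[float]:
    """Per-observation weights w_obs = w_spe / m_spe.

    m_spe is the number of measured observations of the species in this
    period, so Σ w_obs equals Σ w_spe over species that have observations.
    A weighted species without observations is dropped with a warning; an
    observation whose species has no weight is an error.
    """
    m_spe: dict[str, int] = {}
    for obs in observations:
        m_spe[obs.species] = m_spe.get(obs.species, 0) + 1
    unmatched = set(weights.weights) - set(m_spe)
    if unmatched:
        logger.warning(
            "species with assemblage weight but no observations in period %r "
            "excluded from the community mean: %s",
            weights.period,
            sorted(unmatched),
        )
    missing = set(m_spe) - set(weights.weights)
    if missing:
        raise KeyError(f"observations without species weight: {sorted(missing)}")
    return [weights[obs.species] / m_spe[obs.species] for obs in observations]


def community_mean_intra_inter(
    observations: Sequence[DiameterObservation],
    assemblage: Iterable[AssemblageCount],
    period: str,
    sd_correction: bool = True,
) -> CommunityMean:
    """Observation-level community-weighted mean x̄_intra+inter for a period."""
    period_obs = [o for o in observations if o.period == period]
    if len(period_obs) < 2:
        raise InsufficientDataError(
            f"need >= 2 observations in period {period!r}, got {len(period_obs)}"
        )
    w_spe = species_weights(assemblage, period, {o.species for o in period_obs})
    w_obs = observation_weights(period_obs, w_spe)
    sample = WeightedSample([o.diameter for o in period_obs], w_obs)
    sd = weighted_sd(sample, correction=sd_correction)
    return CommunityMean(
        period=period,
        level="intra+inter",
        mean=weighted_mean(sample),
        sd=sd,
        se=weighted_se(sd, sample.n_obs),
        n_obs=sample.n_obs,
    )


def species_pooled_mean(
    observations: Sequence[DiameterObservation],
    species: str,
    pooling: str = "pooled",
) -> float:
    """Cross-period species mean Ø_avg.

    ``pooling="pooled"`` (default) averages all of the species'
    observations pooled over both periods (n-weighted); ``"period_mean"``
    averages the two period means instead.
    """
    per_period: dict[str, list[float]] = {}
    for obs in observations:
        if obs.species == species:
            per_period.setdefault(obs.period, []).append(obs.diameter)
    if not per_period:
        raise InsufficientDataError(f"no observations for species {species!r}")
    if pooling == "pooled":
        values = [v for group in per_period.values() for v in group]
        return sum(values) / len(values)
    if pooling == "period_mean":
        means = [sum(g) / len(g) for g in per_period.values()]
        return sum(means) / len(means)
    raise ValueError(f"unknown pooling mode {pooling!r}")


def community_mean_inter(
    species_means: Mapping[str, float],
    weights: SpeciesWeights,
    level: str = "inter",
    sd_correction: bool = True,
) -> CommunityMean:
    """Species-level community-weighted mean x̄_inter = Σ(Ø_avg · w_spe)/Σ w_spe.

    ``species_means`` maps species to fixed trait values (cross-period
    means, or literature midpoints for level ``inter-literature``); SD and
    SE use n_obs = number of species.
    """
    missing = set(weights.weights) - set(species_means)
    if missing:
        raise KeyError(f"species without a mean value: {sorted(missing)}")
    species = weights.species
    sample = WeightedSample(
        [species_means[s] for s in species],
        [weights[s] for s in species],
        n_obs=len(species),
    )
    # a single-species "community" has no between-species dispersion
    sd = weighted_sd(sample, correction=sd_correction) if len(species) > 1 else 0.0
    return CommunityMean(
        period=weights.period,
        level=level,
        mean=weighted_mean(sample),
        sd=sd,
        se=weighted_se(sd, sample.n_obs),
        n_obs=sample.n_obs,
    )


def decompose(
    observations: Sequence[DiameterObservation],
    assemblage: Iterable[AssemblageCount],
    reference: str,
    comparison: str,
    pooling: str = "pooled",
    sd_correction: bool = True,
) -> DecompositionResult:
    """Partition the community mean change between two periods.

    Deltas read comparison minus reference. The included-species set is
    the intersection of species present in the observation table (either
    period) and the assemblage table; weights are renormalized over it.
    """
    assemblage = list(assemblage)
    obs_species = {o.species for o in observations}
    asm_species = {a.species for a in assemblage}
    included = obs_species & asm_species
    if not included:
        raise InsufficientDataError("no species shared by observations and assemblage")
    obs = [o for o in observations if o.species in included]

    total = {
        p: community_mean_intra_inter(obs, assemblage, p, sd_correction=sd_correction)
        for p in (reference, comparison)
    }
    pooled = {s: species_pooled_mean(obs, s, pooling=pooling) for s in included}
    inter = {
        p: community_mean_inter(
            pooled,
            species_weights(assemblage, p, included),
            sd_correction=sd_correction,
        )
        for p in (reference, comparison)
    }
    return decompose_from_means(
        total_ref=total[reference].mean,
        total_cmp=total[comparison].mean,
        inter_ref=inter[reference].mean,
        inter_cmp=inter[comparison].mean,
    )


def decompose_from_means(
    total_ref: float, total_cmp: float, inter_ref: float, inter_cmp: float
) -> DecompositionResult:
    """Partition from pre-computed community means (comparison − reference)."""
    return DecompositionResult.from_deltas(
        delta_total=total_cmp - total_ref,
        delta_inter=inter_cmp - inter_ref,
    )


def linear_change_percent(mean_ref: float, mean_cmp: float) -> float:
    """Relative change in linear dimension, 100·(cmp − ref)/ref."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_cmp - mean_ref) / mean_ref


def volume_change_percent(mean_ref: float, mean_cmp: float) -> float:
    """Relative change in sphere volume, 100·((cmp/ref)³ − 1).

    Cysts are treated as approximately spherical (V = 4/3·π·r³); the
    radius-versus-diameter factor cancels in the ratio.
    """
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * ((mean_cmp / mean_ref) ** 3 - 1.0)
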