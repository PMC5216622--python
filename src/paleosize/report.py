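"""Pipeline orchestration and tabular outputs.

``run_pipeline`` composes the full analysis — per-species summaries,
community means at three levels, the intra/interspecific decomposition,
the Welch test battery (one unweighted test per species plus one weighted
community test) and the literature comparison — and writes each result as
a CSV table plus a YAML run log recording options, seed and input
checksums. All machine-readable outputs are deterministic given the
inputs (and seed, when simulating).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets, synth
from .decomp import (
    CommunityMean,
    community_mean_inter,
    community_mean_intra_inter,
    decompose_from_means,
    species_pooled_mean,
    species_weights,
    observation_weights,
)
from .errors import InsufficientDataError, PaleosizeError
from .io_model import (
    AssemblageCount,
    DiameterObservation,
    SpeciesSummary,
    read_assemblage,
    read_literature,
    read_observations,
    write_assemblage,
    write_observations,
)
from .litcompare import compare_species, literature_community_mean
from .wstats import WeightedSample, weighted_welch_t_test, welch_t_test

__all__ = ["PipelineConfig", "PipelineResult", "summarize", "histogram_data", "run_pipeline"]

logger = logging.getLogger(__name__)


def summarize(observations: Sequence[DiameterObservation]) -> list[SpeciesSummary]:
    """Per-(species, period) mean, sample SD (ddof=1), SE = SD/√n and n.

    Rows are ordered by (species, period); every group needs >= 2
    observations for the SD to be defined.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for obs in observations:
        groups.setdefault((obs.species, obs.period), []).append(obs.diameter)
    out = []
    for (species, period), values in sorted(groups.items()):
        if len(values) < 2:
            raise InsufficientDataError(
                f"need >= 2 observations for ({species!r}, {period!r})"
            )
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1))
        out.append(
            SpeciesSummary(
                species=species,
                period=period,
                mean=float(arr.mean()),
                sd=sd,
                se=sd / np.sqrt(len(values)),
                n=len(values),
            )
        )
    return out


def histogram_data(
    observations: Sequence[DiameterObservation], bin_width: float = 2.0
) -> pd.DataFrame:
    """Binned diameter counts per (species, period) with normal-curve overlays.

    Bin edges are aligned to multiples of ``bin_width`` (value x falls in
    bin floor(x / bin_width), so halving the width refines the partition
    exactly). ``normal_ordinate`` is n·bin_width·φ(center; mean, sd), the
    expected count under the fitted normal — the smooth curve drawn over a
    count histogram.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    from scipy import stats

    groups: dict[tuple[str, str], list[float]] = {}
    for obs in observations:
        groups.setdefault((obs.species, obs.period), []).append(obs.diameter)
    rows = []
    for (species, period), values in sorted(groups.items()):
        arr = np.asarray(values)
        idx = np.floor(arr / bin_width).astype(int)
        counts = np.bincount(idx - idx.min(), minlength=idx.max() - idx.min() + 1)
        mean = arr.mean()
        sd = arr.std(ddof=1) if len(arr) > 1 else 0.0
        for k, count in enumerate(counts, start=idx.min()):
            center = (k + 0.5) * bin_width
            ordinate = (
                len(arr) * bin_width * stats.norm.pdf(center, mean, sd)
                if sd > 0
                else np.nan
            )
            rows.append(
                (species, period, k * bin_width, (k + 1) * bin_width, int(count), ordinate)
            )
    return pd.DataFrame(
        rows,
        columns=["species", "period", "bin_left", "bin_right", "count", "normal_ordinate"],
    )


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis.

    Either all three input paths are given, or ``simulate=True`` generates
    the observation and assemblage tables from the bundled fixture with
    ``seed`` (the literature path then defaults to the bundled table).
    ``reference``/``comparison`` name the two periods being contrasted
    (deltas read comparison minus reference).
    """

    reference: str = datasets.WARM
    comparison: str = datasets.COLD
    obs_path: str | Path | None = None
    assemblage_path: str | Path | None = None
    literature_path: str | Path | None = None
    out_dir: str | Path = "results"
    simulate: bool = False
    seed: int = 0
    pooling: str = "pooled"
    sd_correction: bool = True
    df_mode: str = "satterthwaite"
    bin_width: float = 2.0

    def __post_init__(self):
        if self.reference == self.comparison:
            raise ValueError("reference and comparison periods must differ")
        if not self.simulate and (self.obs_path is None or self.assemblage_path is None):
            raise ValueError("provide input paths or set simulate=True")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    summaries: list[SpeciesSummary]
    community_means: list[CommunityMean]
    decomposition: object
    tests: pd.DataFrame
    literature: pd.DataFrame
    histograms: pd.DataFrame
    output_files: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _community_tables(
    observations: Sequence[DiameterObservation],
    assemblage: Sequence[AssemblageCount],
    literature,
    config: PipelineConfig,
):
    """Community means at all three levels, the decomposition and the
    weighted community test."""
    periods = (config.reference, config.comparison)
    included = {o.species for o in observations} & {a.species for a in assemblage}
    obs = [o for o in observations if o.species in included]

    total = {
        p: community_mean_intra_inter(obs, assemblage, p, sd_correction=config.sd_correction)
        for p in periods
    }
    pooled = {s: species_pooled_mean(obs, s, pooling=config.pooling) for s in included}
    w_spe = {p: species_weights(assemblage, p, included) for p in periods}
    inter = {
        p: community_mean_inter(pooled, w_spe[p], sd_correction=config.sd_correction)
        for p in periods
    }
    means = [total[p] for p in periods] + [inter[p] for p in periods]
    if literature is not None:
        lit_entries = [e for e in literature if e.species in included]
        means += [literature_community_mean(lit_entries, w_spe[p]) for p in periods]

    decomposition = decompose_from_means(
        total[config.reference].mean,
        total[config.comparison].mean,
        inter[config.reference].mean,
        inter[config.comparison].mean,
    )

    samples = {}
    for p in periods:
        period_obs = [o for o in obs if o.period == p]
        w_obs = observation_weights(period_obs, w_spe[p])
        samples[p] = WeightedSample([o.diameter for o in period_obs], w_obs)
    community_test = weighted_welch_t_test(
        samples[config.reference],
        samples[config.comparison],
        df_mode=config.df_mode,
        sd_correction=config.sd_correction,
    )
    return means, decomposition, community_test


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write result CSVs plus a run log.

    Outputs (under ``config.out_dir``): ``summary.csv`` (one row per
    species × period), ``community.csv`` (community means at all levels),
    ``decomp.csv`` (one row), ``tests.csv`` (six per-species Welch tests
    plus the weighted community test), ``litcmp.csv`` (one row per
    species) and ``histograms.csv``. Any stage error aborts with a
    stage-named message and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "inputs"
        input_paths: dict[str, Path] = {}
        if config.simulate:
            cfg = synth.default_config(seed=config.seed)
            observations = synth.generate_observations(cfg)
            assemblage = synth.generate_assemblage(cfg)
            obs_path = out_dir / "obs.csv"
            asm_path = out_dir / "assemblage.csv"
            write_observations(observations, obs_path)
            write_assemblage(assemblage, asm_path)
            written += [obs_path, asm_path]
            input_paths["observations"] = obs_path
            input_paths["assemblage"] = asm_path
        else:
            input_paths["observations"] = Path(config.obs_path)
            input_paths["assemblage"] = Path(config.assemblage_path)
            observations = read_observations(config.obs_path)
            assemblage = read_assemblage(config.assemblage_path)
        if config.literature_path is not None:
            literature = read_literature(config.literature_path)
            input_paths["literature"] = Path(config.literature_path)
        else:
            literature = datasets.load_default_literature()

        stage = "summaries"
        summaries = summarize(observations)
        summary_df = pd.DataFrame(
            [(s.species, s.period, s.mean, s.sd, s.se, s.n) for s in summaries],
            columns=["species", "period", "mean", "sd", "se", "n"],
        )

        stage = "community"
        means, decomposition, community_test = _community_tables(
            observations, assemblage, literature, config
        )
        community_df = pd.DataFrame(
            [(m.level, m.period, m.mean, m.sd, m.se, m.n_obs) for m in means],
            columns=["level", "period", "mean", "sd", "se", "n"],
        )
        decomp_df = pd.DataFrame(
            [
                (
                    decomposition.delta_total,
                    decomposition.delta_inter,
                    decomposition.delta_intra,
                    decomposition.fraction_intra,
                    decomposition.fraction_inter,
                )
            ],
            columns=[
                "delta_total",
                "delta_inter",
                "delta_intra",
                "fraction_intra",
                "fraction_inter",
            ],
        )

        stage = "tests"
        test_rows = []
        by_species: dict[str, dict[str, list[float]]] = {}
        for obs in observations:
            by_species.setdefault(obs.species, {}).setdefault(obs.period, []).append(
                obs.diameter
            )
        for species in sorted(by_species):
            groups = by_species[species]
            if config.reference in groups and config.comparison in groups:
                res = welch_t_test(groups[config.reference], groups[config.comparison])
                test_rows.append(
                    (species, "welch", res.t_statistic, res.df, res.p_value, res.mean_difference)
                )
        test_rows.append(
            (
                "community",
                "weighted-welch",
                community_test.t_statistic,
                community_test.df,
                community_test.p_value,
                community_test.mean_difference,
            )
        )
        tests_df = pd.DataFrame(
            test_rows, columns=["unit", "test", "t", "df", "p", "mean_difference"]
        )

        stage = "literature"
        lit_rows = []
        for entry in literature:
            species_obs = [o.diameter for o in observations if o.species == entry.species]
            if not species_obs:
                continue
            comparison = compare_species(
                summaries, (min(species_obs), max(species_obs)), entry
            )
            lit_rows.append(
                (
                    entry.species,
                    comparison.literature_range[0],
                    comparison.literature_range[1],
                    comparison.midpoint,
                    comparison.measured_range[0],
                    comparison.measured_range[1],
                    ";".join(sorted(comparison.flags)),
                )
            )
        lit_df = pd.DataFrame(
            lit_rows,
            columns=[
                "species",
                "lit_min",
                "lit_max",
                "midpoint",
                "measured_min",
                "measured_max",
                "flags",
            ],
        )

        stage = "histograms"
        hist_df = histogram_data(observations, bin_width=config.bin_width)

        stage = "write"
        outputs = {
            "summary": (summary_df, out_dir / "summary.csv"),
            "community": (community_df, out_dir / "community.csv"),
            "decomp": (decomp_df, out_dir / "decomp.csv"),
            "tests": (tests_df, out_dir / "tests.csv"),
            "litcmp": (lit_df, out_dir / "litcmp.csv"),
            "histograms": (hist_df, out_dir / "histograms.csv"),
        }
        files: dict[str, Path] = {}
        for name, (frame, path) in outputs.items():
            frame.to_csv(path, index=False)
            written.append(path)
            files[name] = path

        log = {
            "paleosize_version": __version__,
            "reference": config.reference,
            "comparison": config.comparison,
            "simulate": config.simulate,
            "seed": config.seed if config.simulate else None,
            "options": {
                "pooling": config.pooling,
                "sd_correction": config.sd_correction,
                "df_mode": config.df_mode,
                "bin_width": config.bin_width,
            },
            "input_checksums": {k: _sha256(p) for k, p in input_paths.items()},
        }
        log_path = out_dir / "run_log.yaml"
        with open(log_path, "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)
        written.append(log_path)
        files["run_log"] = log_path
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, (PaleosizeError, KeyError, ValueError, FileNotFoundError)):
            raise PaleosizeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        raise
    return PipelineResult(
        summaries=summaries,
        community_means=means,
        decomposition=decomposition,
        tests=tests_df,
        literature=lit_df,
        histograms=hist_df,
        output_files=files,
    )
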