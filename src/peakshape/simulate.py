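"""Hierarchical simulator of two-condition ChIP-Seq peak experiments.

The generative model per peak follows the gamma-Poisson (negative
binomial) hierarchy commonly used for sequencing counts, with an
explicit spatial layer:

1. a *base affinity* (expected read count) is drawn from a heavy-tailed
   distribution (truncated log-normal stand-in for a genome-wide
   occupancy distribution);
2. each sample's affinity is Gamma-distributed around the base value
   (coefficient of variation ``gamma_cv`` = between-replicate biological
   variability);
3. the spatial *profile* is a two-component Gaussian mixture whose base
   means, component sds and mixing weight vary between peaks; each
   sample perturbs them with Gaussian jitter (biological noise);
4. sequencing draws ``N ~ Poisson(sample affinity)`` read midpoints from
   the sample's mixture, re-drawing positions that fall outside the
   region so edge profiles stay smooth.

A treatment condition is derived from control by planting two disjoint
change sets at the *base* level before per-sample noise: affinity
changes (fold change of the base affinity, random direction) and
profile changes (shift of the base mixing weight, random direction).
Ground truth membership and all realized parameters are recorded.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from peakshape.design import ExperimentDesign
from peakshape.errors import InvalidConfigError
from peakshape.io import InMemoryReadSource, PeakRegion

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedExperiment",
    "sample_base_affinities",
    "sample_replicate_affinity",
    "sample_profile_reads",
    "simulate_experiment",
]

LABEL_UNCHANGED = "unchanged"
LABEL_AFFINITY = "affinity_change"
LABEL_PROFILE = "profile_change"

#: Gap left between consecutive simulated peaks on the synthetic chromosome.
_PEAK_GAP = 1000


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    The defaults are the frozen benchmark conditions: 10,000 peaks of
    2,000 bp, two replicates per condition, 100 planted affinity changes
    (fold 8 = near-complete gain or loss, direction random) and 100
    planted profile changes (right-skewed per-peak mixing-weight shift
    magnitude 0.43 * U^1.6, sign random), log-normal base affinities with median 300
    reads truncated to [50, 5000], 15% between-replicate coefficient of
    variation, and bimodal profiles with sub-peaks around 700 and 1300 bp.
    """

    n_peaks: int = 10_000
    n_affinity_changes: int = 100
    n_profile_changes: int = 100
    n_replicates: int = 2
    region_length: float = 2000.0
    # base affinity distribution (truncated log-normal)
    affinity_median: float = 300.0
    affinity_log_sd: float = 0.8
    affinity_min: float = 50.0
    affinity_max: float = 5000.0
    # between-replicate biological variability of the affinity
    gamma_cv: float = 0.15
    # profile hyper-priors (per-peak base parameters)
    mu1_mean: float = 700.0
    mu1_sd: float = 50.0
    mu2_mean: float = 1300.0
    mu2_sd: float = 50.0
    comp_sd_mean: float = 150.0
    comp_sd_sd: float = 20.0
    pi_min: float = 0.35
    pi_max: float = 0.65
    # per-sample biological jitter of the profile parameters
    jitter_mean_sd: float = 20.0
    jitter_comp_sd_sd: float = 10.0
    jitter_pi_sd: float = 0.02
    # planted effect sizes; the per-peak mixing-weight shift magnitude is
    # min + (max - min) * U^power with U ~ U(0,1) (sign random): a
    # right-skewed spectrum — many small, few large effects — so planted
    # profile changes span undetectably subtle to strong
    affinity_fold_change: float = 8.0
    mixing_shift: float = 0.43
    mixing_shift_min: float = 0.0
    mixing_shift_power: float = 1.6
    # benchmark bookkeeping
    n_repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise InvalidConfigError("n_peaks must be >= 1")
        if self.n_affinity_changes < 0 or self.n_profile_changes < 0:
            raise InvalidConfigError("change-set sizes must be >= 0")
        if self.n_affinity_changes + self.n_profile_changes > self.n_peaks:
            raise InvalidConfigError("change sets cannot exceed n_peaks")
        if self.n_replicates < 2:
            raise InvalidConfigError(
                "need at least two replicates per condition (the empirical null "
                "is built from replicate pairs)"
            )
        if not (0 < self.pi_min <= self.pi_max < 1):
            raise InvalidConfigError("mixing-weight prior must lie inside (0, 1)")
        if self.comp_sd_mean <= 0 or self.region_length <= 0:
            raise InvalidConfigError("component sd and region length must be positive")
        if self.gamma_cv < 0 or self.mixing_shift < 0 or self.affinity_fold_change <= 0:
            raise InvalidConfigError("invalid noise/effect parameters")
        if not 0 <= self.mixing_shift_min <= self.mixing_shift:
            raise InvalidConfigError(
                "need 0 <= mixing_shift_min <= mixing_shift"
            )
        if self.mixing_shift_power <= 0:
            raise InvalidConfigError("mixing_shift_power must be positive")
        if not (0 < self.affinity_min <= self.affinity_max):
            raise InvalidConfigError("affinity truncation bounds must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimTruth:
    """Planted ground truth of one simulated experiment.

    ``peaks``: per-peak base parameters, label, and treatment-side base
    values; ``samples``: realized per-sample parameters and read counts.
    """

    peaks: pd.DataFrame
    samples: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.peaks["label"].to_numpy()


@dataclass
class SimulatedExperiment:
    """Simulator output bundle: reads, counts, truth and plumbing."""

    reads: dict
    counts: pd.DataFrame
    truth: SimTruth
    regions: list
    design: ExperimentDesign
    config: SimConfig
    repetition_seed: int

    def read_sources(self) -> dict:
        return {sid: InMemoryReadSource(by_peak) for sid, by_peak in self.reads.items()}


def _rng_for(config: SimConfig, repetition_seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(repetition_seed)])
    )


def sample_base_affinities(config: SimConfig, rng) -> np.ndarray:
    """Heavy-tailed base affinities: truncated log-normal draws.

    ``rng`` may be a Generator or an integer seed.  Values outside
    [affinity_min, affinity_max] are re-drawn (truncation by rejection).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu = math.log(config.affinity_median)
    out = rng.lognormal(mu, config.affinity_log_sd, size=config.n_peaks)
    bad = (out < config.affinity_min) | (out > config.affinity_max)
    while bad.any():
        out[bad] = rng.lognormal(mu, config.affinity_log_sd, size=int(bad.sum()))
        bad = (out < config.affinity_min) | (out > config.affinity_max)
    return out


def sample_replicate_affinity(base, cv: float, rng) -> np.ndarray:
    """Gamma draw with mean ``base`` and sd ``cv * base`` (vectorized).

    shape = 1/cv^2, scale = base * cv^2; cv = 0 returns base exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base = np.asarray(base, dtype=np.float64)
    if cv < 0:
        raise InvalidConfigError("cv must be >= 0")
    if cv == 0:
        return base.copy()
    shape = 1.0 / (cv * cv)
    return rng.gamma(shape, base * cv * cv)


def _truncated_mixture(n, mu1, sd1, mu2, sd2, pi, region_length, rng) -> np.ndarray:
    """n positions from pi*N(mu1,sd1^2) + (1-pi)*N(mu2,sd2^2) on [0, L)."""
    n1 = rng.binomial(n, pi)
    x = np.concatenate(
        [rng.normal(mu1, sd1, n1), rng.normal(mu2, sd2, n - n1)]
    )
    bad = (x < 0) | (x >= region_length)
    while bad.any():
        k = int(bad.sum())
        k1 = rng.binomial(k, pi)
        x[bad] = np.concatenate(
            [rng.normal(mu1, sd1, k1), rng.normal(mu2, sd2, k - k1)]
        )
        bad = (x < 0) | (x >= region_length)
    return x


def sample_profile_reads(
    profile, count_mean: float, region_length: float, rng
) -> np.ndarray:
    """Poisson-many read midpoints from a two-Gaussian mixture profile.

    ``profile`` is ``(mu1, sd1, mu2, sd2, pi)``; ``N ~ Poisson(count_mean)``
    positions are drawn from the mixture, re-drawing any that fall
    outside [0, region_length).  ``count_mean = 0`` yields an empty sample.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu1, sd1, mu2, sd2, pi = profile
    n = int(rng.poisson(count_mean))
    if n == 0:
        return np.empty(0, dtype=np.float64)
    return _truncated_mixture(n, mu1, sd1, mu2, sd2, pi, region_length, rng)


def simulate_experiment(config: SimConfig, repetition_seed: int = 0) -> SimulatedExperiment:
    """Simulate one control/treatment experiment with planted changes.

    Fully deterministic given (config, repetition_seed).  Returns the
    per-sample read sets over all peaks, the raw count table, the ground
    truth, plus ready-made regions/design/read-source plumbing.
    """
    rng = _rng_for(config, repetition_seed)
    n = config.n_peaks
    L = config.region_length

    base_affinity = sample_base_affinities(config, rng)
    mu1 = rng.normal(config.mu1_mean, config.mu1_sd, n)
    mu2 = rng.normal(config.mu2_mean, config.mu2_sd, n)
    sd1 = np.abs(rng.normal(config.comp_sd_mean, config.comp_sd_sd, n))
    sd2 = np.abs(rng.normal(config.comp_sd_mean, config.comp_sd_sd, n))
    sd1 = np.maximum(sd1, 1.0)
    sd2 = np.maximum(sd2, 1.0)
    pi = rng.uniform(config.pi_min, config.pi_max, n)

    perm = rng.permutation(n)
    aff_idx = np.sort(perm[: config.n_affinity_changes])
    prof_idx = np.sort(
        perm[config.n_affinity_changes : config.n_affinity_changes + config.n_profile_changes]
    )
    labels = np.array([LABEL_UNCHANGED] * n, dtype=object)
    labels[aff_idx] = LABEL_AFFINITY
    labels[prof_idx] = LABEL_PROFILE

    treat_affinity = base_affinity.copy()
    aff_dir = rng.choice([-1.0, 1.0], size=aff_idx.size)
    treat_affinity[aff_idx] = base_affinity[aff_idx] * config.affinity_fold_change**aff_dir
    treat_pi = pi.copy()
    pi_dir = rng.choice([-1.0, 1.0], size=prof_idx.size)
    span = config.mixing_shift - config.mixing_shift_min
    pi_mag = config.mixing_shift_min + span * (
        rng.random(prof_idx.size) ** config.mixing_shift_power
    )
    treat_pi[prof_idx] = np.clip(pi[prof_idx] + pi_mag * pi_dir, 0.05, 0.95)

    conditions = {
        "control": (base_affinity, pi),
        "treatment": (treat_affinity, treat_pi),
    }
    reads: dict[str, dict[str, np.ndarray]] = {}
    counts: dict[str, np.ndarray] = {}
    sample_rows = []
    peak_ids = [f"peak{i:05d}" for i in range(n)]
    sample_conditions = []
    for cond, (affinity_c, pi_c) in conditions.items():
        for rep in range(1, config.n_replicates + 1):
            sid = f"{cond}_rep{rep}"
            sample_conditions.append((sid, cond))
            r_affinity = sample_replicate_affinity(affinity_c, config.gamma_cv, rng)
            r_mu1 = rng.normal(mu1, config.jitter_mean_sd)
            r_mu2 = rng.normal(mu2, config.jitter_mean_sd)
            r_sd1 = np.maximum(np.abs(rng.normal(sd1, config.jitter_comp_sd_sd)), 1.0)
            r_sd2 = np.maximum(np.abs(rng.normal(sd2, config.jitter_comp_sd_sd)), 1.0)
            r_pi = np.clip(rng.normal(pi_c, config.jitter_pi_sd), 0.01, 0.99)
            n_reads = rng.poisson(r_affinity)
            by_peak: dict[str, np.ndarray] = {}
            for i in range(n):
                if n_reads[i] == 0:
                    by_peak[peak_ids[i]] = np.empty(0, dtype=np.float64)
                else:
                    by_peak[peak_ids[i]] = _truncated_mixture(
                        int(n_reads[i]), r_mu1[i], r_sd1[i], r_mu2[i], r_sd2[i],
                        r_pi[i], L, rng,
                    )
            reads[sid] = by_peak
            counts[sid] = n_reads
            sample_rows.append(
                pd.DataFrame(
                    {
                        "peak_id": peak_ids,
                        "sample_id": sid,
                        "condition": cond,
                        "affinity": r_affinity,
                        "mu1": r_mu1,
                        "mu2": r_mu2,
                        "sd1": r_sd1,
                        "sd2": r_sd2,
                        "pi": r_pi,
                        "n_reads": n_reads,
                    }
                )
            )

    peaks_df = pd.DataFrame(
        {
            "peak_id": peak_ids,
            "label": labels,
            "base_affinity": base_affinity,
            "mu1": mu1,
            "mu2": mu2,
            "sd1": sd1,
            "sd2": sd2,
            "pi": pi,
            "treat_affinity": treat_affinity,
            "treat_pi": treat_pi,
        }
    ).set_index("peak_id")
    truth = SimTruth(peaks=peaks_df, samples=pd.concat(sample_rows, ignore_index=True))

    count_table = pd.DataFrame(counts, index=peak_ids)
    stride = int(L) + _PEAK_GAP
    regions = [
        PeakRegion("chrSim", i * stride, i * stride + int(L), pid)
        for i, pid in enumerate(peak_ids)
    ]
    design = ExperimentDesign(
        samples=[(sid, cond, None) for sid, cond in sample_conditions],
        contrast=("control", "treatment"),
        null_pairs=[
            (f"{cond}_rep{i}", f"{cond}_rep{j}")
            for cond in conditions
            for i in range(1, config.n_replicates + 1)
            for j in range(i + 1, config.n_replicates + 1)
        ],
    )
    return SimulatedExperiment(
        reads=reads,
        counts=count_table,
        truth=truth,
        regions=regions,
        design=design,
        config=config,
        repetition_seed=int(repetition_seed),
    )
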