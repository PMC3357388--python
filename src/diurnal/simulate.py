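"""Synthetic two-condition diurnal datasets with recorded ground truth.

The generator emulates a 4-timepoint x 3-replicate x 2-condition array
study: a configurable mix of rhythm-change classes (same-phase rhythms,
phase shifts, rhythm loss, baseline shifts, de-novo rhythms, unchanged
genes), uniform control acrophases, a bimodal second-condition acrophase
distribution (von Mises mixture at ZT1/ZT13), plus 8-timepoint hormone
profiles and pyruvate-style tolerance-test curves.

Every gene draws from its own counter-based random stream derived from
one seed, so the per-gene truth is stable when ``n_genes`` changes and
class counts are identical across seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

DEFAULT_CLASS_PROPORTIONS = {
    "I": 0.10,
    "II": 0.10,
    "III": 0.35,
    "IV": 0.05,
    "V": 0.05,
    "VI": 0.10,
    "NC": 0.25,
}
_CLASS_ORDER = ("I", "II", "III", "IV", "V", "VI", "NC")


@dataclass
class HormoneConfig:
    """Cosinor hormone profile per condition (defaults emulate a diurnal
    corticosterone rhythm whose peak is advanced by 6 h in the second
    condition)."""

    analyte: str = "corticosterone"
    timepoints: tuple = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    replicates: int = 4
    mesor: float = 100.0
    amplitude: float = 50.0
    acrophase: dict = field(default_factory=lambda: {"control": 12.0, "TSR": 6.0})
    noise_fraction: float = 0.1  # noise sd as a fraction of amplitude

    def __post_init__(self):
        if len(self.timepoints) < 4:
            raise ConfigError("hormone profile needs >= 4 timepoints")
        if self.noise_fraction < 0:
            raise ConfigError("noise_fraction must be >= 0")


@dataclass
class ToleranceConfig:
    """Glucose excursion after a bolus: b + c*t*exp(-t/tau) + noise."""

    minutes: tuple = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)
    replicates: int = 6
    baseline: float = 100.0  # mg/dl
    tau: float = 30.0  # minutes
    pulse_height: dict = field(default_factory=lambda: {"control": 4.0, "TSR": 2.5})
    noise_sd: float = 5.0

    def __post_init__(self):
        t = np.asarray(self.minutes, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ConfigError("tolerance time grid must start at 0 and increase")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class GeneratorConfig:
    n_genes: int = 300
    timepoints: tuple = (1.0, 7.0, 13.0, 19.0)
    replicates: int = 3
    conditions: tuple = ("control", "TSR")
    period_T: float = 24.0
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    control_phase_distribution: str = "uniform"
    tsr_phase_distribution: str = "bimodal"
    bimodal_centers: tuple = (1.0, 13.0)
    bimodal_kappa: float = 4.0
    phase_shift_delta: float = 6.0  # hours, class II
    amplitude_lognormal: tuple = (np.log(0.8), 0.25)  # (mu, sigma): median 0.8 log2
    baseline_lognormal: tuple = (np.log(8.0), 0.15)  # median 8 log2 units
    baseline_shift: float = 1.0  # log2 LFC for classes IV/V
    noise_sd: float = 0.3  # log2 units
    hormone: HormoneConfig = field(default_factory=HormoneConfig)
    tolerance: ToleranceConfig = field(default_factory=ToleranceConfig)

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(_CLASS_ORDER)
        if unknown:
            raise ConfigError(f"unknown class labels {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if any(not 0 <= t < self.period_T for t in self.timepoints):
            raise ConfigError("timepoints must lie in [0, period)")
        if len(self.conditions) != 2:
            raise ConfigError("exactly two conditions required")
        if isinstance(self.hormone, dict):
            self.hormone = HormoneConfig(**self.hormone)
        if isinstance(self.tolerance, dict):
            self.tolerance = ToleranceConfig(**self.tolerance)


@dataclass
class SyntheticTruth:
    """Per-gene generative parameters plus the config and seed used."""

    genes: pd.DataFrame  # gene, true_class, m/A/phi per condition, noise_sd
    config: GeneratorConfig
    seed: int
    gene_sets: dict = field(default_factory=dict)  # set name -> member list

    def class_members(self, label: str) -> list[str]:
        sel = self.genes["true_class"] == label
        return self.genes.loc[sel, "gene"].tolist()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": _config_dict(self.config),
            "genes": self.genes.to_dict(orient="records"),
            "gene_sets": self.gene_sets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, allow_nan=True, default=float)


def _config_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    for key, value in list(d.items()):
        if isinstance(value, tuple):
            d[key] = list(value)
    return d


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based stream: stable per gene index regardless of n_genes
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _class_quota(proportions: dict, n: int) -> list[str]:
    """Largest-remainder apportionment of n genes over the class labels."""
    labels = [c for c in _CLASS_ORDER if proportions.get(c, 0) > 0]
    raw = np.array([proportions[c] * n for c in labels])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    out = []
    for label, count in zip(labels, counts):
        out.extend([label] * count)
    return out


def _bimodal_phase(rng: np.random.Generator, config: GeneratorConfig) -> float:
    center = config.bimodal_centers[rng.integers(0, len(config.bimodal_centers))]
    angle = rng.vonmises(2 * np.pi * center / config.period_T, config.bimodal_kappa)
    return float(np.mod(angle * config.period_T / (2 * np.pi), config.period_T))


def generate_transcriptome(config: GeneratorConfig | None = None, seed: int = 0):
    """Simulate the expression matrix, sample table and ground truth.

    Returns ``(matrix, samples, truth)`` where ``matrix`` is a log2
    genes x samples DataFrame, ``samples`` the matching sample table and
    ``truth`` a :class:`SyntheticTruth`. Waveforms are single-harmonic
    cosinors ``m + A*cos(2*pi*(t - phi)/T)`` with i.i.d. Gaussian noise.
    """
    config = config or GeneratorConfig()
    cond1, cond2 = config.conditions
    labels = _class_quota(config.class_proportions, config.n_genes)
    half = config.period_T / 2

    sample_rows = []
    for condition in config.conditions:
        for zt in config.timepoints:
            for rep in range(1, config.replicates + 1):
                sample_rows.append(
                    (f"{condition}_ZT{zt:g}_r{rep}", condition, float(zt), rep)
                )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "condition", "zt", "replicate"]
    )
    times = samples["zt"].to_numpy(dtype=float)
    cond_of = samples["condition"].to_numpy()

    truth_rows = []
    matrix = np.empty((config.n_genes, len(samples)))
    class2_count = 0
    for i, label in enumerate(labels):
        rng = _gene_rng(seed, i)
        mu_b, sd_b = config.baseline_lognormal
        mu_a, sd_a = config.amplitude_lognormal
        m1 = float(rng.lognormal(mu_b, sd_b))
        amp = float(rng.lognormal(mu_a, sd_a))
        phi_uniform = float(rng.uniform(0.0, config.period_T))
        phi_bimodal = _bimodal_phase(rng, config)
        m2, a1, a2 = m1, 0.0, 0.0
        phi1, phi2 = np.nan, np.nan
        if label == "I":
            a1 = a2 = amp
            phi1 = phi2 = phi_uniform
        elif label == "II":
            a1 = a2 = amp
            # signs alternate so planted shifts are symmetric (advance/delay)
            sign = 1.0 if class2_count % 2 == 0 else -1.0
            class2_count += 1
            delta = min(config.phase_shift_delta, half)
            phi2 = phi_bimodal
            phi1 = float(np.mod(phi2 - sign * delta, config.period_T))
        elif label == "III":
            a1, phi1 = amp, phi_uniform
        elif label == "VI":
            a2, phi2 = amp, phi_bimodal
        elif label == "IV":
            m2 = m1 + config.baseline_shift
        elif label == "V":
            m2 = m1 - config.baseline_shift
        # NC: flat, identical baselines

        gene_m = {cond1: m1, cond2: m2}
        gene_a = {cond1: a1, cond2: a2}
        gene_phi = {cond1: phi1, cond2: phi2}
        wave = np.empty(len(samples))
        for j, (t, c) in enumerate(zip(times, cond_of)):
            value = gene_m[c]
            if gene_a[c] > 0:
                value += gene_a[c] * np.cos(
                    2 * np.pi * (t - gene_phi[c]) / config.period_T
                )
            wave[j] = value
        noise = rng.normal(0.0, config.noise_sd, len(samples)) if config.noise_sd else 0.0
        matrix[i] = wave + noise
        truth_rows.append(
            (
                f"g{i:05d}",
                label,
                m1,
                m2,
                a1,
                a2,
                phi1,
                phi2,
                config.noise_sd,
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene",
            "true_class",
            f"baseline_{cond1}",
            f"baseline_{cond2}",
            f"amplitude_{cond1}",
            f"amplitude_{cond2}",
            f"acrophase_{cond1}",
            f"acrophase_{cond2}",
            "noise_sd",
        ],
    )
    matrix_df = pd.DataFrame(
        matrix, index=pd.Index(truth["gene"], name="gene_id"), columns=samples["sample_id"]
    )
    return matrix_df, samples, SyntheticTruth(genes=truth, config=config, seed=seed)


def generate_gene_sets(
    truth: SyntheticTruth,
    planting: dict,
    seed: int = 0,
    set_size: int = 40,
) -> dict[str, list[str]]:
    """Sample gene sets with configurable enrichment toward a truth class.

    ``planting`` maps set name to ``(target_class, odds)`` or
    ``(target_class, odds, size)``. Members are drawn without replacement
    with weight ``odds`` for target-class genes and 1 otherwise;
    ``odds=inf`` restricts the set to the target class. Memberships are
    recorded on ``truth.gene_sets``.
    """
    genes = truth.genes["gene"].to_numpy()
    classes = truth.genes["true_class"].to_numpy()
    sets: dict[str, list[str]] = {}
    for set_index, (name, spec) in enumerate(sorted(planting.items())):
        target, odds, *rest = spec
        size = rest[0] if rest else set_size
        if target not in set(classes):
            raise ConfigError(f"target class {target!r} absent from truth")
        if size > len(genes):
            raise ConfigError(f"set size {size} exceeds n_genes {len(genes)}")
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1_000_000 + set_index,))
        )
        in_target = classes == target
        if np.isinf(odds):
            pool = genes[in_target]
            if size > pool.size:
                raise ConfigError(
                    f"set size {size} exceeds class {target!r} size {pool.size}"
                )
            members = rng.choice(pool, size=size, replace=False)
        else:
            if odds <= 0:
                raise ConfigError("enrichment odds must be positive")
            weights = np.where(in_target, float(odds), 1.0)
            weights = weights / weights.sum()
            members = rng.choice(genes, size=size, replace=False, p=weights)
        sets[name] = sorted(members.tolist())
    truth.gene_sets.update(sets)
    return sets


def generate_hormone_profile(
    config: GeneratorConfig | HormoneConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate a two-condition hormone time course (long format)."""
    if config is None:
        config = HormoneConfig()
    if isinstance(config, GeneratorConfig):
        hormone = config.hormone
        conditions = config.conditions
        period = config.period_T
    else:
        hormone = config
        conditions = tuple(hormone.acrophase)
        period = 24.0
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2_000_000,)))
    sd = hormone.noise_fraction * hormone.amplitude
    rows = []
    for condition in conditions:
        phi = hormone.acrophase[condition]
        for zt in hormone.timepoints:
            mean = hormone.mesor + hormone.amplitude * np.cos(
                2 * np.pi * (zt - phi) / period
            )
            for rep in range(1, hormone.replicates + 1):
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                rows.append((hormone.analyte, condition, float(zt), rep, mean + noise))
    return pd.DataFrame(rows, columns=["analyte", "condition", "zt", "replicate", "value"])


def generate_tolerance_test(
    config: GeneratorConfig | ToleranceConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate glucose tolerance-test curves (long format, mg/dl)."""
    if config is None:
        config = ToleranceConfig()
    if isinstance(config, GeneratorConfig):
        tol = config.tolerance
    else:
        tol = config
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3_000_000,)))
    t = np.asarray(tol.minutes, dtype=float)
    rows = []
    for condition, height in tol.pulse_height.items():
        curve = tol.baseline + height * t * np.exp(-t / tol.tau)
        for rep in range(1, tol.replicates + 1):
            noise = (
                rng.normal(0.0, tol.noise_sd, t.size) if tol.noise_sd > 0 else np.zeros(t.size)
            )
            for minute, value in zip(t, curve + noise):
                rows.append((condition, float(minute), rep, float(value)))
    return pd.DataFrame(rows, columns=["condition", "minutes", "replicate", "value"])
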