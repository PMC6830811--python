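"""Synthetic fibre/bundle datasets and relaxation traces.

The generator emulates the statistical structure of a passive-stretch
study on permeabilised human fibres and bundles: a handful of fast and
slow fibres (defaults 4 + 7) and bundles (default 11), each stretched
over an increasing sarcomere-length grid from near slack (2.2 μm) to
the end of filament overlap (4.2 μm), with specimen-level parameter
variability and proportional-plus-floor Gaussian measurement noise
(stresses clipped at zero).

Default truth parameters are the fitted values the analysis is designed
to recover (fast A = 6.64 kPa / L0 = 2.42 μm, slow 7.01 / 2.44,
fractions 0.425/0.425/0.15).  The default ECM scale β = 13.9 kPa is
chosen so that the α_c-weighted ECM stress at 2.5 μm is ≈ 18 kPa, the
magnitude of the measured bundle decomposition at that length; note
that with the bundle stress-free length at its default 1.60 μm the
exponential ECM law then grows much faster with length than measured
bundle decompositions do — a property of the law itself, discussed in
the methods note.

Also included are the cross-sectional-area helpers used to audit
diameter-based area estimates against cryo-section measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError
from .io import MeasurementRecord
from .laws import (
    BundleModel,
    ECMParams,
    FibreLawParams,
    VolumeFractions,
    bundle_uniaxial_stress,
    fibre_stress,
)

__all__ = [
    "GeneratorConfig",
    "generate_fibre_dataset",
    "generate_bundle_dataset",
    "generate_relaxation_trace",
    "csa_from_diameter",
    "bundle_csa",
    "csa_percent_difference",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design and ground truth of the synthetic generator."""

    n_fast: int = 4
    n_slow: int = 7
    n_bundles: int = 11
    points_per_specimen: int = 8
    length_range: tuple = (2.2, 4.2)
    truth_fast: FibreLawParams = field(
        default_factory=lambda: FibreLawParams(A=6.64, L0=2.42))
    truth_slow: FibreLawParams = field(
        default_factory=lambda: FibreLawParams(A=7.01, L0=2.44))
    truth_ecm: ECMParams = field(
        default_factory=lambda: ECMParams(beta=13.9, k_v=0.0, L0b=1.60))
    fractions: VolumeFractions = field(
        default_factory=lambda: VolumeFractions(0.425, 0.425, 0.15))
    specimen_cv: float = 0.10
    noise_rel: float = 0.05
    noise_abs: float = 0.2  # kPa floor of the noise SD
    seed: int = 0

    def __post_init__(self):
        if min(self.n_fast, self.n_slow, self.n_bundles,
               self.points_per_specimen) < 0:
            raise DomainError("counts must be non-negative")
        lo, hi = self.length_range
        if not lo < hi:
            raise DomainError("length_range must be increasing")
        if lo <= 0:
            raise DomainError("lengths must be positive")
        if min(self.specimen_cv, self.noise_rel, self.noise_abs) < 0:
            raise DomainError("cv and noise levels must be >= 0")


def _length_grid(config: GeneratorConfig) -> np.ndarray:
    return np.linspace(*config.length_range, config.points_per_specimen)


def _noisy_stress(clean, config: GeneratorConfig, rng) -> np.ndarray:
    sd = np.maximum(config.noise_rel * np.abs(clean), config.noise_abs)
    return np.clip(clean + rng.standard_normal(clean.shape) * sd, 0.0, None)


def _perturbed_fibre(truth: FibreLawParams, cv: float, rng) -> FibreLawParams:
    """Specimen-level draw: lognormal (mean-preserving) on A, Gaussian on L0."""
    if cv == 0:
        return truth
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    A = truth.A * math.exp(rng.normal(0.0, sigma) - sigma ** 2 / 2.0)
    L0 = truth.L0 * (1.0 + cv * rng.normal())
    return FibreLawParams(A=A, L0=max(L0, 1e-3))


def generate_fibre_dataset(config: GeneratorConfig) -> list:
    """Per-specimen fibre stress-length records under the generator model."""
    rng = np.random.default_rng(config.seed)
    lengths = _length_grid(config)
    records = []
    specimens = ([("fast", config.truth_fast)] * config.n_fast
                 + [("slow", config.truth_slow)] * config.n_slow)
    for i, (ftype, truth) in enumerate(specimens):
        params = _perturbed_fibre(truth, config.specimen_cv, rng)
        stress = _noisy_stress(
            np.asarray(fibre_stress(lengths, params)), config, rng)
        sid = f"{ftype}_fibre_{i + 1:02d}"
        records.extend(
            MeasurementRecord(sid, "fibre", ftype, float(L), float(P))
            for L, P in zip(lengths, stress))
    return records


def _perturbed_fractions(base: VolumeFractions, cv: float, rng) -> VolumeFractions:
    if cv == 0:
        return base
    w = np.array([base.alpha_f, base.alpha_s, base.alpha_c])
    w = w * np.exp(rng.normal(0.0, cv, size=3))
    w = w / w.sum()
    return VolumeFractions(float(w[0]), float(w[1]), float(w[2]))


def generate_bundle_dataset(config: GeneratorConfig) -> list:
    """Bundle records: rule-of-mixtures truth with perturbed fractions."""
    rng = np.random.default_rng(config.seed + 1)  # independent of fibre stream
    lengths = _length_grid(config)
    records = []
    for i in range(config.n_bundles):
        fractions = _perturbed_fractions(config.fractions, config.specimen_cv, rng)
        model = BundleModel(fast=config.truth_fast, slow=config.truth_slow,
                            ecm=config.truth_ecm, fractions=fractions)
        clean = np.asarray(bundle_uniaxial_stress(lengths, model).total)
        stress = _noisy_stress(clean, config, rng)
        sid = f"bundle_{i + 1:02d}"
        records.extend(
            MeasurementRecord(sid, "bundle", "mixed", float(L), float(P))
            for L, P in zip(lengths, stress))
    return records


def generate_relaxation_trace(p_peak: float, p_inf: float, k: float,
                              duration: float, dt: float,
                              noise_rel: float = 0.0, seed: int = 0):
    """Exponential stress-relaxation trace y(t) = p∞ + (p_peak − p∞) e^(−kt).

    Emulates the viscous recovery after a stretch step; used to study
    how truncating the recording (e.g. at 120 s instead of full
    relaxation) biases the raw plateau estimate but not a fitted
    asymptote.  Returns (times s, stresses kPa).
    """
    if duration <= 0 or dt <= 0:
        raise DomainError("duration and dt must be positive")
    if k < 0:
        raise DomainError("rate constant must be >= 0")
    t = np.arange(0.0, duration + dt / 2.0, dt)
    clean = p_inf + (p_peak - p_inf) * np.exp(-k * t)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.standard_normal(t.shape) * noise_rel * np.abs(clean)
    return t, clean


def csa_from_diameter(d0: float) -> float:
    """Circular cross-sectional area π d0²/4 (μm²) from a diameter (μm)."""
    if d0 <= 0:
        raise DomainError("diameter must be positive")
    return math.pi * d0 ** 2 / 4.0


def bundle_csa(diameters) -> float:
    """Bundle area as the sum of per-fibre circular areas (μm²)."""
    diameters = np.asarray(diameters, dtype=float)
    if diameters.size == 0 or np.any(diameters <= 0):
        raise DomainError("need positive fibre diameters")
    return float(np.sum(math.pi * diameters ** 2 / 4.0))


def csa_percent_difference(video_area: float, cryo_area: float) -> float:
    """Percentage difference 100·(cryo − video)/cryo between area estimates."""
    if video_area <= 0 or cryo_area <= 0:
        raise DomainError("areas must be positive")
    return 100.0 * (cryo_area - video_area) / cryo_area
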