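"""Synthetic 9-item ordinal questionnaire data.

The generator emulates the statistical structure the adaptive method relies
on: a unit-level latent severity drives all nine items (so early answers are
informative about later ones and about caseness), each item maps
severity-plus-noise onto the 0-3 scale through increasing cutpoints — a
graded-response-style mechanism.  Default cutpoints are right-skewed (most
mass at 0), as in screening populations, and prevalence of the total>=10
label is controlled by shifting the latent mean, with a bisection calibrator
for hitting a target prevalence such as the 8.8% and 30% regimes reported
for general-population and primary-care samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import (
    DEPRESSION_CUTOFF,
    N_ITEMS,
    PhqDataset,
    RespondentRecord,
    ValidationError,
)

#: Item loadings on the latent severity (all positive; the last item,
#: suicidality, is least aligned with overall severity in screening data).
DEFAULT_DISCRIMINATIONS: tuple[float, ...] = (
    1.3, 1.4, 1.0, 1.1, 0.9, 1.2, 1.0, 0.9, 0.7,
)

#: Per-item increasing cutpoints on the severity+noise scale; higher first
#: cutpoint = less commonly endorsed item (sleep/fatigue low, suicidality high).
DEFAULT_CUTPOINTS: tuple[tuple[float, float, float], ...] = (
    (1.2, 2.4, 3.4),
    (1.3, 2.5, 3.5),
    (0.8, 2.0, 3.0),
    (0.7, 1.9, 3.0),
    (1.2, 2.4, 3.4),
    (1.4, 2.6, 3.6),
    (1.3, 2.5, 3.5),
    (1.7, 2.9, 3.9),
    (2.2, 3.3, 4.3),
)


class CalibrationError(RuntimeError):
    """The bisection bracket does not contain the target prevalence."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the latent-severity ordinal generator."""

    n: int
    latent_mean: float = 0.0
    latent_sd: float = 1.0
    discriminations: tuple[float, ...] = DEFAULT_DISCRIMINATIONS
    cutpoints: tuple[tuple[float, float, float], ...] = DEFAULT_CUTPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.latent_sd <= 0:
            raise ValidationError("latent_sd must be positive")
        if len(self.discriminations) != N_ITEMS:
            raise ValidationError(f"need {N_ITEMS} discriminations")
        if any(a < 0 for a in self.discriminations):
            raise ValidationError("discriminations must be non-negative")
        if len(self.cutpoints) != N_ITEMS:
            raise ValidationError(f"need {N_ITEMS} cutpoint triples")
        for q, cps in enumerate(self.cutpoints, start=1):
            if len(cps) != 3 or not (cps[0] < cps[1] < cps[2]):
                raise ValidationError(
                    f"cutpoints for phq{q} must be 3 strictly increasing values, got {cps}"
                )


def _categorize(z: np.ndarray, cutpoints: Sequence[Sequence[float]]) -> np.ndarray:
    """Map latent values (n, 9) to ordinal responses 0..3 via cutpoints."""
    cuts = np.asarray(cutpoints, dtype=float)  # (9, 3)
    return (z[:, :, None] > cuts[None, :, :]).sum(axis=2).astype(np.int8)


def _simulate_matrix(
    config: GeneratorConfig, theta0: np.ndarray, noise: np.ndarray
) -> np.ndarray:
    theta = config.latent_mean + config.latent_sd * theta0
    a = np.asarray(config.discriminations, dtype=float)
    z = theta[:, None] * a[None, :] + noise
    return _categorize(z, config.cutpoints)


def generate(config: GeneratorConfig) -> PhqDataset:
    """Draw a complete synthetic dataset, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    theta0 = rng.standard_normal(config.n)
    noise = rng.standard_normal((config.n, N_ITEMS))
    responses = _simulate_matrix(config, theta0, noise)
    records = [
        RespondentRecord(id=f"synth-{i:06d}", responses=tuple(int(v) for v in row))
        for i, row in enumerate(responses)
    ]
    return PhqDataset(records)


def _prevalence_of_mean(
    config: GeneratorConfig, mean: float, theta0: np.ndarray, noise: np.ndarray
) -> float:
    responses = _simulate_matrix(replace(config, latent_mean=mean), theta0, noise)
    totals = responses.sum(axis=1, dtype=np.int32)
    return float((totals >= DEPRESSION_CUTOFF).mean())


def calibrate_prevalence(
    config: GeneratorConfig,
    target: float,
    tolerance: float = 0.02,
    n_calib: int = 50_000,
    bracket: tuple[float, float] = (-6.0, 6.0),
    max_iter: int = 100,
) -> GeneratorConfig:
    """Adjust ``latent_mean`` by bisection to hit a target prevalence.

    A single calibration sample of ``n_calib`` standard-normal draws (seeded
    from ``config.seed``) is reused across bisection steps, making prevalence
    a deterministic non-decreasing function of the latent mean.  Returns the
    config with the adjusted mean; raises :class:`CalibrationError` when the
    bracket does not span the target.
    """
    if not (0.0 < target < 1.0):
        raise ValidationError(f"target prevalence must lie in (0, 1), got {target}")
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1717]))
    theta0 = rng.standard_normal(n_calib)
    noise = rng.standard_normal((n_calib, N_ITEMS))

    def prev(mean: float) -> float:
        return _prevalence_of_mean(config, mean, theta0, noise)

    if abs(prev(config.latent_mean) - target) <= tolerance:
        return config
    lo, hi = bracket
    p_lo, p_hi = prev(lo), prev(hi)
    if not (p_lo - tolerance <= target <= p_hi + tolerance):
        raise CalibrationError(
            f"target {target} outside bracket prevalences [{p_lo}, {p_hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = prev(mid)
        if abs(p_mid - target) <= tolerance:
            return replace(config, latent_mean=mid)
        if p_mid < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach prevalence {target} ± {tolerance} in {max_iter} steps"
    )
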