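"""95% confidence intervals for work-based free-energy estimates.

Gaussian (Crooks-normal) estimates get the analytic half-width

    δΔG = z · ( σ/√n + β σ²/√(2n) ),

the sum of the standard error of ⟨W⟩ and the delta-method standard error of
βs²/2 (from Var(s²) ≈ 2σ⁴/n for normal samples), scaled by the z-score of the
requested coverage. Convolution/Jarzynski estimates get a bootstrap interval:
each stage is resampled with replacement, its Jarzynski estimate recomputed B
times, and the two stage errors combined in quadrature — the stages being
independent alchemical processes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import beta as _beta
from .work_io import StageWorkSet, WorkSet

__all__ = ["CIConfig", "gaussian_ci", "bootstrap_ci", "jarzynski_bootstrap_error"]


@dataclass(frozen=True)
class CIConfig:
    """Confidence-interval settings (defaults give two-sided 95% with z=1.96)."""

    alpha: float = 0.05
    z: float = 1.96
    bootstrap_B: int = 1000
    seed: int | None = None
    percentile: bool = False  # percentile bootstrap instead of z·std

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be at least 100")


def gaussian_ci(works: WorkSet, cfg: CIConfig = CIConfig()) -> float:
    """Analytic 95% half-width for the Crooks-Gaussian estimate, kcal/mol."""
    n = len(works)
    if n < 2:
        raise ValueError("need at least 2 work values")
    sigma = float(works.values.std(ddof=1))
    b = works.beta
    return cfg.z * (sigma / math.sqrt(n) + b * sigma ** 2 / math.sqrt(2 * n))


def jarzynski_bootstrap_error(works: WorkSet, cfg: CIConfig = CIConfig(),
                              rng: np.random.Generator | None = None) -> float:
    """Bootstrap half-width of the Jarzynski estimate of one stage, kcal/mol."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(works)
    x = -works.beta * works.values
    idx = rng.integers(0, n, size=(cfg.bootstrap_B, n))
    # Jarzynski replicate per resample, via log-sum-exp along each row
    log_means = logsumexp(x[idx], axis=1) - math.log(n)
    reps = -(1.0 / works.beta) * log_means
    if cfg.percentile:
        lo, hi = np.quantile(reps, [cfg.alpha / 2, 1 - cfg.alpha / 2])
        return float((hi - lo) / 2.0)
    return float(cfg.z * reps.std(ddof=1))


def bootstrap_ci(stage: StageWorkSet, cfg: CIConfig = CIConfig()) -> float:
    """Quadrature-combined bootstrap 95% half-width for the convolution estimate.

    Each stage's Jarzynski estimate is resampled independently; the two stage
    errors add in quadrature. Deterministic for a fixed ``cfg.seed`` and
    symmetric under exchange of the stage labels.
    """
    err_lj = jarzynski_bootstrap_error(stage.lj, cfg, _stage_rng(cfg, stage.lj))
    err_qq = jarzynski_bootstrap_error(stage.qq, cfg, _stage_rng(cfg, stage.qq))
    return math.hypot(err_lj, err_qq)


def _stage_rng(cfg: CIConfig, works: WorkSet) -> np.random.Generator:
    # Seed each stage's stream from (seed, content hash) so the half-width is
    # exactly invariant under exchanging the lj/qq labels.
    digest = zlib.crc32(np.ascontiguousarray(works.values).tobytes())
    return np.random.default_rng([0 if cfg.seed is None else cfg.seed, digest])
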