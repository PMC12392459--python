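"""Synthetic work ensembles and benchmark tables with known ground truth.

Stand-in for the MD stages of a fast-growth campaign: everything downstream of
the simulations (estimators, gating, CIs, LogP, metrics) can be exercised on
ensembles whose exact free energy is available in closed form.

The generative model is a Gaussian mixture over work values. For a mixture
with weights π_k, means μ_k and widths σ_k, the exponential average is
analytic per component (lognormal moment identity E[e^{−βW}] for W ~ N(μ,σ²)
equals e^{−βμ + β²σ²/2}), so

    ΔG_exact = −RT ln Σ_k π_k exp(−βμ_k + β²σ_k²/2).

A single component reproduces the Crooks-normal case, where sampling
N(ΔG* + βσ²/2, σ²) makes ΔG* the exact free energy; two well-separated
components produce the right-skewed, clearly non-normal distributions that
route the decision tree to the convolution branch. Defaults mirror a typical
fast-growth campaign: N = 200 trajectories per solute/solvent leg at 300 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .constants import DEFAULT_TEMPERATURE, beta as _beta, rt
from .work_io import CompoundRecord, StageWorkSet, WorkSet

__all__ = ["MixtureSpec", "exact_free_energy", "gen_normal_works",
           "gen_mixture_works", "gen_stage_works", "gen_benchmark_table",
           "DEFAULT_N_TRAJECTORIES"]

#: Trajectories per solute/solvent leg in a typical fast-growth campaign.
DEFAULT_N_TRAJECTORIES = 200


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian-mixture work distribution with analytic free energy."""

    weights: tuple[float, ...]
    means: tuple[float, ...]      # kcal/mol
    sds: tuple[float, ...]        # kcal/mol
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        k = len(self.weights)
        if k < 1 or len(self.means) != k or len(self.sds) != k:
            raise ValueError("weights, means and sds must have equal length >= 1")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a valid simplex point")
        if any(s < 0 for s in self.sds):
            raise ValueError("sds must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        return _beta(self.temperature)

    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * (stats.norm.cdf(x, m, s) if s > 0 else (x >= m).astype(float))
        return out

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Numerical inverse CDF (used by the copula coupling)."""
        q = np.asarray(q, dtype=float)
        lo = min(m - 10 * s - 1 for m, s in zip(self.means, self.sds))
        hi = max(m + 10 * s + 1 for m, s in zip(self.means, self.sds))
        return np.array([optimize.brentq(lambda x, qi=qi: self.cdf(np.array(x)) - qi,
                                         lo, hi, xtol=1e-12)
                         for qi in np.clip(q, 1e-12, 1 - 1e-12)])


def exact_free_energy(spec: MixtureSpec) -> float:
    """Closed-form ΔG = −RT ln Σ_k π_k exp(−βμ_k + β²σ_k²/2), kcal/mol."""
    b = spec.beta
    # log-sum-exp over components for numerical safety
    terms = [math.log(w) + (-b * m + (b * s) ** 2 / 2.0)
             for w, m, s in zip(spec.weights, spec.means, spec.sds) if w > 0]
    m = max(terms)
    return -rt(spec.temperature) * (m + math.log(sum(math.exp(t - m) for t in terms)))


def gen_normal_works(dG_target: float, sigma: float, n: int = DEFAULT_N_TRAJECTORIES,
                     temperature: float = DEFAULT_TEMPERATURE,
                     seed: int | None = None, label: str = "") -> WorkSet:
    """Normal work ensemble whose exact free energy is ``dG_target``.

    Samples N(dG_target + βσ²/2, σ²): inverting the Crooks-normal relation
    ΔG = ⟨W⟩ − βσ²/2 fixes the population mean so that the exact dissipated
    work is βσ²/2.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    mu = dG_target + _beta(temperature) * sigma ** 2 / 2.0
    values = mu + sigma * rng.standard_normal(n)
    return WorkSet(values, temperature, label or "synthetic-normal")


def gen_mixture_works(spec: MixtureSpec, n: int = DEFAULT_N_TRAJECTORIES,
                      seed: int | None = None, label: str = "") -> WorkSet:
    """Seeded sample from a Gaussian-mixture work distribution."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(spec.weights), size=n, p=spec.weights)
    mu = np.asarray(spec.means)[comp]
    sd = np.asarray(spec.sds)[comp]
    values = mu + sd * rng.standard_normal(n)
    return WorkSet(values, spec.temperature, label or "synthetic-mixture")


def gen_stage_works(spec_lj: MixtureSpec, spec_qq: MixtureSpec,
                    correlation: float = 0.0, n: int = DEFAULT_N_TRAJECTORIES,
                    seed: int | None = None, label: str = "") -> StageWorkSet:
    """Paired Lennard-Jones / recharging works with controlled rank coupling.

    A Gaussian copula couples the two mixture marginals: latent standard
    normals with correlation ``correlation`` are pushed through Φ and then
    through each marginal's inverse CDF, so ``correlation = 0`` yields
    independent stages while the marginal distributions stay exactly as
    specified.
    """
    if not -1.0 < correlation < 1.0:
        raise ValueError("correlation must be in (-1, 1)")
    if spec_lj.temperature != spec_qq.temperature:
        raise ValueError("stage specs must share a temperature")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0.0, 0.0],
                                [[1.0, correlation], [correlation, 1.0]], size=n)
    u = stats.norm.cdf(z)
    lj = WorkSet(spec_lj.ppf(u[:, 0]), spec_lj.temperature, (label or "lj"))
    qq = WorkSet(spec_qq.ppf(u[:, 1]), spec_qq.temperature, (label or "qq"))
    return StageWorkSet(lj, qq)


def gen_benchmark_table(n_compounds: int, noise_w: float = 0.3, noise_o: float = 0.3,
                        bias_w: float = 0.0, bias_o: float = 0.0,
                        seed: int | None = None, protocol: str = "sim",
                        ) -> tuple[list[CompoundRecord], dict[str, float]]:
    """Synthetic experimental/calculated solvation table for metric exercises.

    "Experimental" hydration free energies are uniform on [−12, −1] kcal/mol
    and 1-octanol values on [−18, −3] (the span of typical neutral drug-like
    benchmark sets); "calculated" values add N(bias, noise²) per leg. Returns
    the records plus the generator parameters as ground truth.
    """
    if n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    if noise_w < 0 or noise_o < 0:
        raise ValueError("noise levels must be non-negative")
    rng = np.random.default_rng(seed)
    exp_w = rng.uniform(-12.0, -1.0, size=n_compounds)
    exp_o = rng.uniform(-18.0, -3.0, size=n_compounds)
    calc_w = exp_w + bias_w + noise_w * rng.standard_normal(n_compounds)
    calc_o = exp_o + bias_o + noise_o * rng.standard_normal(n_compounds)
    records = []
    for i in range(n_compounds):
        records.append(CompoundRecord(
            name=f"CPD{i + 1:03d}",
            dg_w_exp=float(exp_w[i]), dg_o_exp=float(exp_o[i]),
            dg_w={protocol: float(calc_w[i])}, dg_o={protocol: float(calc_o[i])}))
    truth = {"noise_w": noise_w, "noise_o": noise_o,
             "bias_w": bias_w, "bias_o": bias_o, "protocol": protocol}
    return records, truth
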