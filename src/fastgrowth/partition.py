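"""Octanol–water partition coefficients from solvation free-energy legs.

LogP = (ΔG_w − ΔG_o) / (RT ln 10): a solute whose hydration free energy lies
above its 1-octanol solvation free energy prefers the organic phase and has
positive LogP. One LogP unit corresponds to RT ln 10 ≈ 1.372 kcal/mol of
octanol→water transfer free energy at 300 K (the factor often quoted as 1.37).
Uncertainties on the two solvation legs are treated as independent and
propagated in quadrature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .constants import rt_ln10
from .work_io import CompoundRecord

logger = logging.getLogger(__name__)

__all__ = ["LogPRecord", "logp", "logp_ci", "transfer_free_energy", "build_logp_table"]


@dataclass(frozen=True)
class LogPRecord:
    """A compound's partition coefficient and octanol→water transfer free energy."""

    name: str
    logp: float
    transfer_dG: float  # kcal/mol, = logp · RT ln10
    ci: float | None = None
    temperature: float = 300.0


def logp(dg_w: float, dg_o: float, temperature: float) -> float:
    """Partition coefficient (ΔG_w − ΔG_o)/(RT ln 10); dimensionless."""
    if not (math.isfinite(dg_w) and math.isfinite(dg_o)):
        raise ValueError("solvation free energies must be finite")
    return (dg_w - dg_o) / rt_ln10(temperature)


def logp_ci(ci_w: float, ci_o: float, temperature: float) -> float:
    """Quadrature-propagated LogP half-width from the two legs' half-widths."""
    if ci_w < 0 or ci_o < 0:
        raise ValueError("half-widths must be non-negative")
    return math.hypot(ci_w, ci_o) / rt_ln10(temperature)


def transfer_free_energy(logp_value: float, temperature: float) -> float:
    """Octanol→water transfer free energy, kcal/mol: LogP · RT ln 10."""
    if not math.isfinite(logp_value):
        raise ValueError("logp must be finite")
    return logp_value * rt_ln10(temperature)


def build_logp_table(records: list[CompoundRecord], protocol: str,
                     temperature: float) -> list[LogPRecord]:
    """Derive one :class:`LogPRecord` per compound for the given protocol.

    ``protocol="exp"`` uses the experimental legs. Compounds missing either
    solvation leg are skipped with a warning; an empty result is an error.
    """
    out: list[LogPRecord] = []
    for rec in records:
        if protocol == "exp":
            dg_w, dg_o = rec.dg_w_exp, rec.dg_o_exp
            ci_w = ci_o = None
        else:
            dg_w = rec.dg_w.get(protocol)
            dg_o = rec.dg_o.get(protocol)
            ci_w = rec.ci_w.get(protocol)
            ci_o = rec.ci_o.get(protocol)
        if dg_w is None or dg_o is None:
            logger.warning("%s: missing %s leg(s) — skipped",
                           rec.name, protocol)
            continue
        lp = logp(dg_w, dg_o, temperature)
        ci = (logp_ci(ci_w, ci_o, temperature)
              if ci_w is not None and ci_o is not None else None)
        out.append(LogPRecord(rec.name, lp, transfer_free_energy(lp, temperature),
                              ci, temperature))
    if not out:
        raise ValueError(f"no compound has both solvation legs for protocol {protocol!r}")
    return out
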