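"""Conformer-charge arithmetic.

Fixed atomic charges fitted on individual solute conformations (e.g. RESP on
frames of a QM/MM trajectory) are turned into a single force-field charge set
by averaging over conformers, or by a population-weighted convex combination
when distinct conformational basins were charged separately (e.g. compact and
extended conformers combined as 0.67·Q_c + 0.33·Q_e). Per-atom-type summaries
support comparison of charge protocols.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .work_io import ChargeSet

__all__ = ["ChargeEnsemble", "ConformerAverage", "average_charges",
           "combine_charge_sets", "average_charge_by_type", "classify_spread"]

#: Relative per-atom charge spread (sd/|mean|) considered unremarkable for
#: conformer-averaged RESP-style charges.
NORMAL_SPREAD_BAND = (0.03, 0.06)


def _check_conformable(sets: Sequence[ChargeSet]) -> None:
    if not sets:
        raise ValueError("need at least one charge set")
    ref = sets[0]
    for cs in sets[1:]:
        if cs.atom_labels != ref.atom_labels:
            raise ValueError("charge sets disagree on atom labels")
        if cs.atom_types != ref.atom_types:
            raise ValueError("charge sets disagree on atom types")


@dataclass(frozen=True)
class ChargeEnsemble:
    """Charge sets for the same molecule across sampled conformers."""

    conformers: tuple[ChargeSet, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        _check_conformable(self.conformers)
        if self.weights is not None:
            if len(self.weights) != len(self.conformers):
                raise ValueError("one weight per conformer required")
            _check_weights(self.weights)

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def charge_matrix(self) -> np.ndarray:
        """(n_conformers, n_atoms) array of charges."""
        return np.vstack([cs.charges for cs in self.conformers])


def _check_weights(weights: Sequence[float], tol: float = 1e-6) -> None:
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError(f"weights must sum to 1 within {tol}, got {w.sum()!r}")


@dataclass(frozen=True)
class ConformerAverage:
    """Conformer-averaged charges plus the per-atom relative spread δq/|q̄|."""

    charges: ChargeSet
    relative_spread: np.ndarray


def average_charges(ens: ChargeEnsemble) -> ConformerAverage:
    """Unweighted per-atom mean over conformers, with relative spread.

    The spread is the per-atom standard deviation across conformers divided by
    the magnitude of the per-atom mean (inf where the mean is exactly zero);
    values around 0.03–0.06 are typical of conformer-averaged charges.
    """
    mat = ens.charge_matrix
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(ens) > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean != 0, sd / np.abs(mean), np.where(sd == 0, 0.0, np.inf))
    ref = ens.conformers[0]
    return ConformerAverage(
        ChargeSet(ref.atom_labels, ref.atom_types, mean, label="conformer-average"),
        rel)


def combine_charge_sets(sets: Sequence[ChargeSet],
                        weights: Sequence[float]) -> ChargeSet:
    """Population-weighted convex combination of conformable charge sets.

    The net charge of the result is the same convex combination of the input
    net charges (exact linearity); no renormalization to integer net charge is
    applied.
    """
    _check_conformable(sets)
    if len(weights) != len(sets):
        raise ValueError("one weight per charge set required")
    _check_weights(weights)
    w = np.asarray(weights, dtype=float)
    combined = np.einsum("k,ki->i", w, np.vstack([cs.charges for cs in sets]))
    ref = sets[0]
    return ChargeSet(ref.atom_labels, ref.atom_types, combined, label="combined")


def average_charge_by_type(cs: ChargeSet) -> pd.DataFrame:
    """Mean charge per force-field atom type, with atom counts.

    Returns a DataFrame indexed by atom type with columns ``mean_charge`` and
    ``n_atoms``, sorted by type.
    """
    df = pd.DataFrame({"type": cs.atom_types, "charge": cs.charges})
    grouped = df.groupby("type")["charge"].agg(mean_charge="mean", n_atoms="size")
    grouped["n_atoms"] = grouped["n_atoms"].astype(int)
    return grouped.sort_index()


def classify_spread(relative_spread: np.ndarray,
                    band: tuple[float, float] = NORMAL_SPREAD_BAND) -> np.ndarray:
    """Label per-atom spreads as 'low', 'normal' (within band) or 'high'."""
    rel = np.asarray(relative_spread, dtype=float)
    lo, hi = band
    return np.where(rel < lo, "low", np.where(rel <= hi, "normal", "high"))
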