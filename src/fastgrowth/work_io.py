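"""Core containers and plain-text / CSV I/O.

The on-disk contracts are deliberately minimal:

* work files — one work value (kcal/mol) per line, ``#`` comments and blank
  lines ignored; a two-stage variant is a two-column TSV with header
  ``W_lj<TAB>W_qq``;
* compound tables — CSV with a ``name`` column, optional experimental columns
  ``exp_w``/``exp_o``, and per-protocol columns ``<protocol>_w``,
  ``<protocol>_o`` plus optional ``<protocol>_w_ci``/``<protocol>_o_ci``
  half-widths;
* charge tables — CSV with ``atom``, ``type``, then one charge column per
  conformer.

Typographic minus signs (en/em dash, U+2212) that survive copy-paste from
published tables are normalized to ASCII ``-`` on input.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import beta as _beta

logger = logging.getLogger(__name__)

_DASHES = str.maketrans({"−": "-", "–": "-", "—": "-"})


def normalize_minus(text: str) -> str:
    """Replace en/em dashes and the Unicode minus with ASCII '-'."""
    return text.translate(_DASHES)


@dataclass(frozen=True)
class WorkSet:
    """An ensemble of per-trajectory alchemical recoupling work values.

    Parameters
    ----------
    values
        Work values in kcal/mol, one per nonequilibrium trajectory.
    temperature
        Bath temperature in kelvin.
    label
        Free-text tag (compound / solvent / protocol).
    """

    values: np.ndarray
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("WorkSet requires a non-empty 1-d value array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("WorkSet values must all be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def beta(self) -> float:
        """1/(RT) in mol/kcal at this set's temperature."""
        return _beta(self.temperature)

    def with_values(self, values: Iterable[float], label: str | None = None) -> "WorkSet":
        return WorkSet(np.asarray(list(values), dtype=float), self.temperature,
                       self.label if label is None else label)


@dataclass(frozen=True)
class StageWorkSet:
    """Paired Lennard-Jones and recharging stage work ensembles.

    Trajectory ``i`` contributes ``lj.values[i] + qq.values[i]`` to the total
    work when the two stages have equal length; pairing is required for the
    total-work distribution and for independence diagnostics, not for the
    convolution estimator.
    """

    lj: WorkSet
    qq: WorkSet

    def __post_init__(self) -> None:
        if self.lj.temperature != self.qq.temperature:
            raise ValueError("stage temperatures differ "
                             f"({self.lj.temperature} K vs {self.qq.temperature} K)")

    @property
    def temperature(self) -> float:
        return self.lj.temperature

    @property
    def paired(self) -> bool:
        return len(self.lj) == len(self.qq)

    def total(self) -> WorkSet:
        """Per-trajectory total work ``W_lj + W_qq`` (requires pairing)."""
        if not self.paired:
            raise ValueError("stages have unequal lengths; cannot form per-trajectory totals")
        label = self.lj.label or self.qq.label
        return WorkSet(self.lj.values + self.qq.values, self.temperature, label)


@dataclass
class CompoundRecord:
    """One compound's experimental and per-protocol solvation free energies.

    ``dg_w``/``dg_o`` map protocol name to the computed solvation free energy
    (kcal/mol) in water and 1-octanol; ``ci_w``/``ci_o`` hold the matching 95%
    half-widths when available.
    """

    name: str
    dg_w_exp: float | None = None
    dg_o_exp: float | None = None
    dg_w: dict[str, float] = field(default_factory=dict)
    dg_o: dict[str, float] = field(default_factory=dict)
    ci_w: dict[str, float] = field(default_factory=dict)
    ci_o: dict[str, float] = field(default_factory=dict)

    def protocols(self) -> list[str]:
        return sorted(set(self.dg_w) | set(self.dg_o))


@dataclass(frozen=True)
class ChargeSet:
    """Fixed atomic charges for one conformer (elementary charge units)."""

    atom_labels: tuple[str, ...]
    atom_types: tuple[str, ...]
    charges: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        charges = np.asarray(self.charges, dtype=float)
        if not (len(self.atom_labels) == len(self.atom_types) == charges.size):
            raise ValueError("atom_labels, atom_types and charges must have equal length")
        if not np.all(np.isfinite(charges)):
            raise ValueError("charges must be finite")
        charges.flags.writeable = False
        object.__setattr__(self, "charges", charges)

    def __len__(self) -> int:
        return int(self.charges.size)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def check_net_charge(self, declared: float, tol: float = 1e-2) -> None:
        if abs(self.net_charge - declared) > tol:
            raise ValueError(
                f"net charge {self.net_charge:.4f} differs from declared "
                f"{declared:.4f} by more than {tol}")


# ---------------------------------------------------------------------------
# work files
# ---------------------------------------------------------------------------

def read_work_file(path: str | Path, temperature: float, label: str = "") -> WorkSet:
    """Read a one-value-per-line work file (kcal/mol) into a :class:`WorkSet`."""
    path = Path(path)
    values: list[float] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = normalize_minus(raw).strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable work value at line {lineno}: "
                                 f"{raw.strip()!r}") from exc
    if not values:
        raise ValueError(f"{path}: no work values")
    logger.info("read %d work values from %s", len(values), path)
    return WorkSet(np.array(values), temperature, label or path.stem)


def write_work_file(works: WorkSet, path: str | Path, fmt: str = "%.10g") -> None:
    path = Path(path)
    lines = [f"# work values (kcal/mol), T = {works.temperature:g} K"]
    lines += [fmt % w for w in works.values]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_stage_files(lj_path: str | Path, qq_path: str | Path,
                     temperature: float, label: str = "") -> StageWorkSet:
    """Read separate Lennard-Jones and recharging work files."""
    return StageWorkSet(read_work_file(lj_path, temperature, label or "lj"),
                        read_work_file(qq_path, temperature, label or "qq"))


def read_stage_table(path: str | Path, temperature: float, label: str = "") -> StageWorkSet:
    """Read a two-column TSV with header ``W_lj<TAB>W_qq``."""
    path = Path(path)
    text = normalize_minus(path.read_text(encoding="utf-8"))
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    for col in ("W_lj", "W_qq"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns 'W_lj' and 'W_qq', got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: no work values")
    return StageWorkSet(
        WorkSet(df["W_lj"].to_numpy(float), temperature, label or "lj"),
        WorkSet(df["W_qq"].to_numpy(float), temperature, label or "qq"))


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

_EXP_COLS = {"exp_w", "exp_o"}


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a per-compound free-energy CSV into :class:`CompoundRecord` rows."""
    path = Path(path)
    text = normalize_minus(path.read_text(encoding="utf-8"))
    df = pd.read_csv(io.StringIO(text), skip_blank_lines=True)
    if "name" not in df.columns:
        raise ValueError(f"{path}: missing required 'name' column")
    if df.empty:
        warnings.warn(f"{path}: compound table has no data rows", stacklevel=2)
        return []
    names = df["name"].astype(str)
    dupes = names[names.duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate compound names: {', '.join(dupes)}")

    records = []
    for _, row in df.iterrows():
        rec = CompoundRecord(name=str(row["name"]))
        for col in df.columns:
            if col == "name" or pd.isna(row[col]):
                continue
            val = float(row[col])
            if col == "exp_w":
                rec.dg_w_exp = val
            elif col == "exp_o":
                rec.dg_o_exp = val
            elif col.endswith("_w_ci"):
                rec.ci_w[col[:-5]] = val
            elif col.endswith("_o_ci"):
                rec.ci_o[col[:-5]] = val
            elif col.endswith("_w"):
                rec.dg_w[col[:-2]] = val
            elif col.endswith("_o"):
                rec.dg_o[col[:-2]] = val
            else:
                logger.debug("ignoring unrecognized column %r", col)
        records.append(rec)
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        logger.info("%s: %d missing cells", path, n_missing)
    return records


def compound_table_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Flatten records back into the CSV column layout."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"name": rec.name}
        if rec.dg_w_exp is not None:
            row["exp_w"] = rec.dg_w_exp
        if rec.dg_o_exp is not None:
            row["exp_o"] = rec.dg_o_exp
        for proto, v in rec.dg_w.items():
            row[f"{proto}_w"] = v
        for proto, v in rec.dg_o.items():
            row[f"{proto}_o"] = v
        for proto, v in rec.ci_w.items():
            row[f"{proto}_w_ci"] = v
        for proto, v in rec.ci_o.items():
            row[f"{proto}_o_ci"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    compound_table_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# charge tables
# ---------------------------------------------------------------------------

def read_charge_sets(path: str | Path) -> list[ChargeSet]:
    """Read per-conformer atomic charges: columns ``atom``, ``type``, conformers."""
    path = Path(path)
    text = normalize_minus(path.read_text(encoding="utf-8"))
    reader = csv.reader(io.StringIO(text))
    header = next(reader, None)
    if header is None or len(header) < 3 or header[0] != "atom" or header[1] != "type":
        raise ValueError(f"{path}: expected header 'atom,type,<conformer>...'")
    n_cols = len(header)
    labels: list[str] = []
    types: list[str] = []
    columns: list[list[float]] = [[] for _ in header[2:]]
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != n_cols:
            raise ValueError(f"{path}: ragged row at line {lineno} "
                             f"({len(row)} fields, expected {n_cols})")
        labels.append(row[0])
        types.append(row[1])
        for j, cell in enumerate(row[2:]):
            try:
                columns[j].append(float(cell))
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric charge at line {lineno}, "
                                 f"column {header[2 + j]!r}: {cell!r}") from exc
    if not labels:
        raise ValueError(f"{path}: no atoms")
    return [ChargeSet(tuple(labels), tuple(types), np.array(col), label=name)
            for name, col in zip(header[2:], columns)]


def write_charge_sets(sets: Sequence[ChargeSet], path: str | Path,
                      fmt: str = "%.6f") -> None:
    if not sets:
        raise ValueError("no charge sets to write")
    ref = sets[0]
    for cs in sets[1:]:
        if cs.atom_labels != ref.atom_labels or cs.atom_types != ref.atom_types:
            raise ValueError("charge sets disagree on atom labels/types")
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["atom", "type"] + [cs.label or f"conf{i+1}"
                                            for i, cs in enumerate(sets)])
        for i, (lab, typ) in enumerate(zip(ref.atom_labels, ref.atom_types)):
            writer.writerow([lab, typ] + [fmt % cs.charges[i] for cs in sets])
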