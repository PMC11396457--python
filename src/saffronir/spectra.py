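"""Spectral data containers and wide-CSV I/O.

The canonical on-disk layout is a wide CSV: one row per sample, first
column ``sample_id``, remaining column headers numeric wavelengths in nm.
Reference values (LD, TCCC, CP — all % w/w) live in a second CSV keyed by
the same sample IDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "ReferenceTable",
    "SetSplit",
    "INDEX_NAMES",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "crop_band",
    "split_sets",
]

#: Quality indices modelled throughout the package, in canonical order.
INDEX_NAMES = ("LD", "TCCC", "CP")

_NM_MIN, _NM_MAX = 100.0, 25000.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid needs at least 2 points")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavelength grid contains non-finite values")
        if np.any(np.diff(v) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if v[0] < _NM_MIN or v[-1] > _NM_MAX:
            raise ValueError(
                f"wavelengths must lie within [{_NM_MIN:g}, {_NM_MAX:g}] nm"
            )

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    @property
    def step(self) -> float:
        """Grid spacing in nm; raises for non-uniform grids."""
        d = np.diff(self.values)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("grid is not uniformly spaced")
        return float(d[0])


@dataclass
class SpectraSet:
    """Absorbance spectra (log 1/R) of a sample set on a shared grid."""

    sample_ids: list[str]
    grid: WavelengthGrid
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if a.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{a.shape[0]} spectra but {len(self.sample_ids)} sample IDs"
            )
        if a.shape[1] != len(self.grid):
            raise ValueError(
                f"{a.shape[1]} columns but grid has {len(self.grid)} wavelengths"
            )
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValueError(f"duplicate sample IDs: {sorted(dupes)}")
        if not np.all(np.isfinite(a)):
            bad = [self.sample_ids[i] for i in np.unique(np.where(~np.isfinite(a))[0])]
            raise ValueError(f"non-finite absorbance in samples: {bad}")
        self.absorbance = a

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(
        self, absorbance: np.ndarray, grid: WavelengthGrid | None = None
    ) -> "SpectraSet":
        """New set with the same IDs but replaced matrix (and optionally grid)."""
        return SpectraSet(list(self.sample_ids), grid or self.grid, absorbance)

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        """Rows for the given IDs, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"sample IDs not in set: {missing}")
        rows = [pos[s] for s in ids]
        return SpectraSet(list(ids), self.grid, self.absorbance[rows])


@dataclass
class ReferenceTable:
    """Measured index values per sample, % w/w; any subset of LD/TCCC/CP."""

    sample_ids: list[str]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValueError(f"duplicate sample IDs: {sorted(dupes)}")
        if not self.values:
            raise ValueError("reference table needs at least one index column")
        clean: dict[str, np.ndarray] = {}
        for name, col in self.values.items():
            if name not in INDEX_NAMES:
                raise ValueError(f"unknown index {name!r}; expected {INDEX_NAMES}")
            v = np.asarray(col, dtype=float)
            if v.shape != (len(self.sample_ids),):
                raise ValueError(f"index {name}: length mismatch with sample IDs")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"index {name}: non-finite values")
            if np.any(v < 0) or np.any(v > 100):
                bad = [self.sample_ids[i] for i in np.where((v < 0) | (v > 100))[0]]
                raise ValueError(f"index {name}: values outside [0, 100] for {bad}")
            clean[name] = v
        self.values = clean

    @property
    def indices(self) -> tuple[str, ...]:
        return tuple(n for n in INDEX_NAMES if n in self.values)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def column(self, index: str, ids: Sequence[str] | None = None) -> np.ndarray:
        """Values for one index, optionally reordered to the given IDs."""
        if index not in self.values:
            raise KeyError(f"index {index!r} not present (have {self.indices})")
        if ids is None:
            return self.values[index].copy()
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"sample IDs not in reference table: {missing}")
        return self.values[index][[pos[s] for s in ids]]

    def subset(self, ids: Sequence[str]) -> "ReferenceTable":
        return ReferenceTable(
            list(ids), {n: self.column(n, ids) for n in self.indices}
        )


@dataclass(frozen=True)
class SetSplit:
    """Seeded disjoint partition into calibration and prediction IDs."""

    calibration_ids: tuple[str, ...]
    prediction_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.calibration_ids) & set(self.prediction_ids)
        if overlap:
            raise ValueError(f"calibration/prediction sets overlap: {sorted(overlap)}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "calibration": list(self.calibration_ids),
                    "prediction": list(self.prediction_ids),
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SetSplit":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["calibration"]), tuple(d["prediction"]), int(d["seed"]))


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for s in ids:
        (dup if s in seen else seen).add(s)
    return dup


# ---------------------------------------------------------------------------
# file I/O


def read_spectra(path: str | Path, dialect: str = "wide_csv") -> SpectraSet:
    """Read a wide-CSV spectra file.

    Columns are reordered if the header wavelengths are not ascending;
    duplicate IDs or wavelengths and non-numeric cells raise ``ValueError``.
    """
    if dialect != "wide_csv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("spectra CSV needs an ID column and >= 2 wavelengths")
    ids = df.iloc[:, 0].tolist()
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {path.name}: {exc}") from exc
    if np.unique(wl).size != wl.size:
        raise ValueError("duplicate wavelength columns; cannot sort uniquely")
    body = df.iloc[:, 1:]
    non_numeric = body.columns[body.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
    if len(non_numeric):
        col = str(non_numeric[0])
        row = int(pd.to_numeric(body[non_numeric[0]], errors="coerce").isna().idxmax())
        raise ValueError(f"non-numeric cell at row {row}, wavelength column {col}")
    order = np.argsort(wl)
    matrix = body.to_numpy(dtype=float)[:, order]
    return SpectraSet(ids, WavelengthGrid(wl[order]), matrix)


def write_spectra(s: SpectraSet, path: str | Path) -> Path:
    """Write a SpectraSet as wide CSV; round-trips through read_spectra."""
    if s.n_samples < 1:
        raise ValueError("cannot write an empty spectra set")
    path = Path(path)
    df = pd.DataFrame(
        s.absorbance,
        index=pd.Index(s.sample_ids, name="sample_id"),
        columns=[_fmt_nm(v) for v in s.grid.values],
    )
    df.to_csv(path)
    return path


def _fmt_nm(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_reference(path: str | Path) -> ReferenceTable:
    """Read a reference CSV (``sample_id`` + any of LD/TCCC/CP columns)."""
    df = pd.read_csv(Path(path), dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("reference CSV must have a 'sample_id' column")
    if df["sample_id"].isna().any():
        raise ValueError("reference CSV has missing sample IDs")
    cols = {c: df[c].to_numpy(dtype=float) for c in df.columns if c in INDEX_NAMES}
    return ReferenceTable(df["sample_id"].tolist(), cols)


def write_reference(r: ReferenceTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"sample_id": r.sample_ids})
    for name in r.indices:
        df[name] = r.values[name]
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# set operations


def crop_band(s: SpectraSet, low_nm: float, high_nm: float) -> SpectraSet:
    """Retain the closed wavelength interval [low_nm, high_nm]."""
    if not low_nm < high_nm:
        raise ValueError("require low_nm < high_nm")
    mask = (s.grid.values >= low_nm) & (s.grid.values <= high_nm)
    if not mask.any():
        raise ValueError(
            f"band [{low_nm:g}, {high_nm:g}] nm contains no grid wavelengths"
        )
    return SpectraSet(
        list(s.sample_ids), WavelengthGrid(s.grid.values[mask]), s.absorbance[:, mask]
    )


def split_sets(s: SpectraSet, n_prediction: int, seed: int) -> SetSplit:
    """Seeded uniform partition into calibration and held-out prediction IDs."""
    n = s.n_samples
    if not 0 <= n_prediction < n:
        raise ValueError(f"n_prediction must be in [0, {n - 1}], got {n_prediction}")
    rng = np.random.default_rng(seed)
    pred_rows = rng.choice(n, size=n_prediction, replace=False)
    pred = set(pred_rows.tolist())
    cal_ids = tuple(s.sample_ids[i] for i in range(n) if i not in pred)
    pred_ids = tuple(s.sample_ids[i] for i in sorted(pred))
    return SetSplit(cal_ids, pred_ids, seed)
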