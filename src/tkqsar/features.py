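"""Molecular descriptor computation, filtering, and parsimony auditing.

Descriptor backends are pluggable: the default computes RDKit's 2D descriptor
set; a ``toy`` backend (heavy-atom and ring counts) exists for fast tests, and
a ``mordred`` backend is registered when that library is importable.
Filtering drops, in order: columns with missing cells, zero-variance columns,
and the later-named member of every pair whose absolute Pearson correlation
exceeds the cutoff (0.97 by default). The Topliss ratio (training chemicals
per descriptor) audits model parsimony; values above 5 are conventionally
considered safe against overfitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemreg import ChemicalRecord
from .errors import AllColumnsRemovedError, BackendUnavailableError

DEFAULT_CORR_CUTOFF = 0.97
TOPLISS_RECOMMENDED_MIN = 5.0


@dataclass
class DescriptorMatrix:
    """Rectangular descriptor table; missing cells are NaN."""

    frame: pd.DataFrame  # index = record ids, columns = descriptor names

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


BackendFn = Callable[[Chem.Mol], dict[str, float]]
_BACKENDS: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    _BACKENDS[name] = fn


def _toy_backend(mol: Chem.Mol) -> dict[str, float]:
    return {
        "heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "rings": float(mol.GetRingInfo().NumRings()),
    }


def _rdkit2d_backend(mol: Chem.Mol) -> dict[str, float]:
    from rdkit.Chem import Descriptors

    vals = Descriptors.CalcMolDescriptors(mol)
    out = {}
    for name, v in vals.items():
        try:
            f = float(v)
        except (TypeError, ValueError):
            f = math.nan
        out[name] = f if math.isfinite(f) else math.nan
    return out


def _mordred_backend(mol: Chem.Mol) -> dict[str, float]:
    try:
        from mordred import Calculator, descriptors  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise BackendUnavailableError("mordred is not installed") from exc
    calc = Calculator(descriptors, ignore_3D=True)
    res = calc(mol)
    out = {}
    for key, v in res.asdict().items():
        try:
            f = float(v)
        except (TypeError, ValueError):
            f = math.nan
        out[key] = f if math.isfinite(f) else math.nan
    return out


register_backend("toy", _toy_backend)
register_backend("rdkit2d", _rdkit2d_backend)
register_backend("mordred", _mordred_backend)


def compute_descriptors(records: Iterable[ChemicalRecord],
                        backend: str = "rdkit2d") -> DescriptorMatrix:
    """One descriptor row per record; per-descriptor failures become NaN cells.

    Raises
    ------
    BackendUnavailableError
        If ``backend`` is not registered (or its library is missing).
    """
    if backend not in _BACKENDS:
        raise BackendUnavailableError(f"unknown descriptor backend {backend!r}")
    fn = _BACKENDS[backend]
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles_std)
        if mol is None:
            rows[rec.record_id] = {}
            continue
        try:
            rows[rec.record_id] = fn(mol)
        except BackendUnavailableError:
            raise
        except Exception:
            rows[rec.record_id] = {}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame.reindex([r.record_id for r in records])
    frame = frame[sorted(frame.columns)]
    return DescriptorMatrix(frame)


def filter_descriptors(
    m: DescriptorMatrix, corr_cutoff: float = DEFAULT_CORR_CUTOFF
) -> tuple[DescriptorMatrix, pd.DataFrame]:
    """Apply the three-stage descriptor filter; returns (matrix, removal log).

    Stages, in order: (1) drop any column with at least one missing cell;
    (2) drop zero-variance columns; (3) for every remaining pair with
    |Pearson r| > ``corr_cutoff``, drop the later column in lexicographic name
    order (deterministic and independent of row order). The removal log has
    columns (name, reason) with reasons HAS_NA / ZERO_VARIANCE / CORR_GT_CUTOFF.

    Raises
    ------
    AllColumnsRemovedError
        If no column survives.
    """
    frame = m.frame
    if frame.shape[1] == 0:
        raise AllColumnsRemovedError("empty descriptor matrix")
    removed: list[tuple[str, str]] = []

    na_cols = [c for c in frame.columns if frame[c].isna().any()]
    removed += [(c, "HAS_NA") for c in na_cols]
    frame = frame.drop(columns=na_cols)

    zv_cols = [c for c in frame.columns if frame[c].nunique() <= 1]
    removed += [(c, "ZERO_VARIANCE") for c in zv_cols]
    frame = frame.drop(columns=zv_cols)

    kept: list[str] = []
    for col in sorted(frame.columns):
        x = frame[col].to_numpy(dtype=float)
        redundant = False
        for prev in kept:
            r = np.corrcoef(frame[prev].to_numpy(dtype=float), x)[0, 1]
            if abs(r) > corr_cutoff:
                redundant = True
                break
        if redundant:
            removed.append((col, "CORR_GT_CUTOFF"))
        else:
            kept.append(col)

    if not kept:
        raise AllColumnsRemovedError("no descriptor survived filtering")
    log = pd.DataFrame(removed, columns=["name", "reason"])
    return DescriptorMatrix(frame[kept]), log


def topliss_ratio(n_train: int, n_descriptors: int) -> tuple[int, bool]:
    """Training-chemicals-per-descriptor ratio, rounded half-up.

    Returns ``(rounded_ratio, compliant)`` where ``compliant`` is True when
    the unrounded ratio exceeds 5.
    """
    if n_train <= 0 or n_descriptors <= 0:
        raise ValueError("counts must be positive")
    ratio = n_train / n_descriptors
    return int(math.floor(ratio + 0.5)), ratio > TOPLISS_RECOMMENDED_MIN
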