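"""Chemical registration: SMILES standardization and duplicate merging.

Curation rules implemented here:

* structures are standardized locally (RDKit cleanup, largest covalently
  connected fragment, canonical SMILES) — salts and counter-ions are dropped;
* replicate measurements of the same standardized structure are merged by
  arithmetic mean of the EQ (equality-qualified) values;
* oral-bioavailability (F%) structures are excluded when the sample standard
  deviation of their replicates exceeds 20 percentage points, or when any
  value lies outside the physical range [0, 100];
* VDss must be strictly positive; non-positive values are excluded;
* inequality-qualified values ("<" / ">") are never averaged with EQ values:
  an EQ value wins, otherwise the structure is kept as qualifier-only (usable
  for classification sets when the qualifier pins the class).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import MixedEndpointsError, UnparseableSmilesError

RDLogger.DisableLog("rdApp.*")

# exclusion reason codes (machine-readable, stable)
STD_GT_20 = "STD_GT_20"
OUT_OF_RANGE = "OUT_OF_RANGE"
UNPARSEABLE = "UNPARSEABLE_SMILES"

F_STD_LIMIT = 20.0  # max sample sd of F% replicates before exclusion


class Endpoint(enum.Enum):
    F_PERCENT = "F_PERCENT"
    VDSS_L_PER_KG = "VDSS_L_PER_KG"
    HALFLIFE_H = "HALFLIFE_H"


class Qualifier(enum.Enum):
    EQ = "EQ"
    LT = "LT"
    GT = "GT"


@dataclass(frozen=True)
class ChemicalRecord:
    """One standardized structure with provenance."""

    record_id: str
    smiles_raw: str
    smiles_std: str
    source: str = ""


@dataclass(frozen=True)
class EndpointValue:
    endpoint: Endpoint
    value: float
    qualifier: Qualifier = Qualifier.EQ


@dataclass
class CuratedDataset:
    records: list[ChemicalRecord] = field(default_factory=list)
    measurements: dict[str, EndpointValue] = field(default_factory=dict)
    exclusions: list[tuple[str, str]] = field(default_factory=list)


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()


def standardize_structure(
    smiles_raw: str, record_id: str = "", source: str = ""
) -> ChemicalRecord:
    """Standardize a raw SMILES into a canonical single-fragment record.

    The largest covalently connected fragment is kept (counter-ions dropped),
    valence/hydrogen normalization is applied, and the canonical SMILES is
    emitted. The operation is idempotent: standardizing ``smiles_std`` returns
    ``smiles_std``.

    Raises
    ------
    UnparseableSmilesError
        If the text cannot be parsed; callers route the record to exclusions.
    """
    if not smiles_raw or not smiles_raw.strip():
        raise UnparseableSmilesError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise UnparseableSmilesError(f"cannot parse {smiles_raw!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _FRAGMENT_CHOOSER.choose(mol)
    smiles_std = Chem.MolToSmiles(mol)
    return ChemicalRecord(
        record_id=record_id or smiles_std,
        smiles_raw=smiles_raw,
        smiles_std=smiles_std,
        source=source,
    )


def _sample_sd(values: list[float]) -> float:
    # n-1 denominator: replicate-measurement semantics
    n = len(values)
    if n < 2:
        return 0.0
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def _out_of_range(endpoint: Endpoint, value: float) -> bool:
    if endpoint is Endpoint.F_PERCENT:
        return value > 100.0 or value < 0.0
    if endpoint is Endpoint.VDSS_L_PER_KG:
        return value <= 0.0
    return False


def merge_duplicates(
    measurements_per_structure: dict[str, list[EndpointValue]],
    records_per_structure: dict[str, ChemicalRecord] | None = None,
) -> CuratedDataset:
    """Merge replicate measurements per standardized structure.

    For each structure with two or more EQ values the retained value is the
    arithmetic mean. F% structures are excluded when any replicate (or the
    merged value) is outside [0, 100] (``OUT_OF_RANGE``) or when the replicate
    sample sd exceeds 20 (``STD_GT_20``); the range rule is applied per
    replicate before the sd rule. VDss replicates are mean-merged on the
    linear scale with no sd rule; non-positive VDss is ``OUT_OF_RANGE``.
    Qualifier-bearing values never enter the average: an EQ value wins,
    otherwise the first qualifier value (sorted for determinism) is retained.

    Raises
    ------
    MixedEndpointsError
        If one structure carries measurements for different endpoints.
    """
    out = CuratedDataset()
    for smiles_std in sorted(measurements_per_structure):
        values = measurements_per_structure[smiles_std]
        endpoints = {v.endpoint for v in values}
        if len(endpoints) > 1:
            raise MixedEndpointsError(
                f"structure {smiles_std} carries endpoints "
                f"{sorted(e.value for e in endpoints)}"
            )
        endpoint = next(iter(endpoints))
        rec = (records_per_structure or {}).get(smiles_std) or ChemicalRecord(
            record_id=smiles_std, smiles_raw=smiles_std, smiles_std=smiles_std
        )

        eq_vals = [v.value for v in values if v.qualifier is Qualifier.EQ]
        if eq_vals:
            if any(_out_of_range(endpoint, v) for v in eq_vals):
                out.exclusions.append((rec.record_id, OUT_OF_RANGE))
                continue
            if endpoint is Endpoint.F_PERCENT and _sample_sd(eq_vals) > F_STD_LIMIT:
                out.exclusions.append((rec.record_id, STD_GT_20))
                continue
            merged = sum(eq_vals) / len(eq_vals)
            if _out_of_range(endpoint, merged):
                out.exclusions.append((rec.record_id, OUT_OF_RANGE))
                continue
            out.records.append(rec)
            out.measurements[rec.record_id] = EndpointValue(endpoint, merged)
        else:
            # qualifier-only structure: keep the first value deterministically
            qv = sorted(values, key=lambda v: (v.qualifier.value, v.value))[0]
            out.records.append(rec)
            out.measurements[rec.record_id] = qv
    return out


def curate(raw: pd.DataFrame) -> CuratedDataset:
    """Full curation: standardize, group by standardized SMILES, merge.

    ``raw`` columns: id, smiles, endpoint, value, qualifier (optional,
    ""/"="/"<"/">"), source (optional).
    """
    per_structure: dict[str, list[EndpointValue]] = {}
    per_structure_rec: dict[str, ChemicalRecord] = {}
    unparseable: list[tuple[str, str]] = []
    qmap = {"": Qualifier.EQ, "=": Qualifier.EQ, "<": Qualifier.LT, ">": Qualifier.GT,
            "EQ": Qualifier.EQ, "LT": Qualifier.LT, "GT": Qualifier.GT}
    for row in raw.itertuples(index=False):
        try:
            rec = standardize_structure(
                str(row.smiles), record_id=str(row.id),
                source=str(getattr(row, "source", "")),
            )
        except UnparseableSmilesError:
            unparseable.append((str(row.id), UNPARSEABLE))
            continue
        qual = qmap[str(getattr(row, "qualifier", "") or "").strip()]
        val = EndpointValue(Endpoint[str(row.endpoint)], float(row.value), qual)
        per_structure.setdefault(rec.smiles_std, []).append(val)
        # first id seen for a structure names the merged record
        per_structure_rec.setdefault(rec.smiles_std, rec)
    ds = merge_duplicates(per_structure, per_structure_rec)
    ds.exclusions.extend(unparseable)
    ds.exclusions.sort()
    return ds


def read_input_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "smiles": str}, keep_default_na=False)
    required = {"id", "smiles", "endpoint", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"input CSV missing columns: {sorted(missing)}")
    return df


def write_curated(ds: CuratedDataset, curated_path: str | Path,
                  exclusions_path: str | Path) -> None:
    """Write curated records + measurements and the exclusion log, id-sorted."""
    rows = []
    for rec in sorted(ds.records, key=lambda r: r.record_id):
        mv = ds.measurements[rec.record_id]
        rows.append({
            "id": rec.record_id, "smiles": rec.smiles_std,
            "endpoint": mv.endpoint.value, "value": mv.value,
            "qualifier": mv.qualifier.value, "source": rec.source,
        })
    pd.DataFrame(rows, columns=["id", "smiles", "endpoint", "value",
                                "qualifier", "source"]).to_csv(curated_path, index=False)
    pd.DataFrame(sorted(ds.exclusions), columns=["id", "reason"]).to_csv(
        exclusions_path, index=False)
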