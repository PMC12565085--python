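"""Synthetic chemical libraries with fragment-linked endpoint values.

Molecules are assembled from a small grammar of drug-like cores and acyclic
substituents, which guarantees chemical validity without a generative model.
Structural fragments ("planted" alerts such as a trifluoromethyl or a
dimethylamino group) are attached to exact-count subsets of the library and
drive the endpoint through additive effects:

* F%  = clip(base + Σ fragment effects + Gaussian noise, 0, 100) — clipping
  reproduces the boundary peaks at 0 % and 100 % seen in real
  bioavailability data;
* VDss = exp(Σ fragment effects on the ln scale + Gaussian noise), which
  keeps values strictly positive and right-skewed like measured VDss
  (real data span roughly 0.035–700 L·kg⁻¹).

The generator also plants curation hazards on disjoint record subsets:
duplicate structures with discordant replicate values, qualifier-only
records (">"/"<"), and F% values outside [0, 100]. A truth table records
which fragments drive which chemicals so recovery tests can check alert
mining and variable selection against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemreg import ChemicalRecord, Endpoint

CORES = (
    "c1ccccc1",      # benzene
    "c1ccncc1",      # pyridine
    "c1ccoc1",       # furan
    "C1CCCCC1",      # cyclohexane
    "C1CCNCC1",      # piperidine
    "C1CCOCC1",      # tetrahydropyran
    "CCCC",          # butane chain
    "CC(C)C",        # isobutane chain
)

# acyclic substituents; fluorine- and sulfur-free so that planted fragments
# can use those elements without accidental matches
SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC",
    "CO", "CN", "CCO", "CCN", "C(C)C", "C(C)O", "C(C)N",
)

#: fragments safe to append at the end of an assembled SMILES chain
DEFAULT_FRAGMENTS = (
    ("C(F)(F)F", -40.0, 0.3),   # trifluoromethyl lowers F%
    ("N(C)C", 25.0, 0.3),       # dimethylamino raises F%
)


@dataclass(frozen=True)
class PlantedFragment:
    smiles: str       # attachable, terminal fragment; also its SMARTS pattern
    effect: float     # additive effect (F% points, or ln-units for VDss)
    rate: float       # fraction of the library carrying the fragment


@dataclass
class GeneratorConfig:
    n_chemicals: int
    seed: int
    planted_fragments: list[PlantedFragment] = field(
        default_factory=lambda: [PlantedFragment(*f) for f in DEFAULT_FRAGMENTS]
    )
    endpoint: Endpoint = Endpoint.F_PERCENT
    f_base: float = 70.0          # baseline F% before fragment effects
    noise_sd: float = 5.0         # F% points, or ln-units for VDss
    duplicate_rate: float = 0.05
    qualifier_rate: float = 0.05
    out_of_range_rate: float = 0.02

    def __post_init__(self):
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be positive")
        frag_rates = sum(f.rate for f in self.planted_fragments)
        if frag_rates > 1.0 + 1e-9:
            raise ValueError("fragment rates must sum to <= 1")
        hazards = self.duplicate_rate + self.qualifier_rate + self.out_of_range_rate
        if hazards > 1.0 + 1e-9:
            raise ValueError("hazard rates must sum to <= 1")


def _assemble(rng: np.random.Generator, fragment: str | None) -> str:
    core = CORES[rng.integers(len(CORES))]
    n_subs = int(rng.integers(1, 3))
    subs = [SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for _ in range(n_subs)]
    return core + "".join(subs) + (fragment or "")


def generate_library(cfg: GeneratorConfig) -> tuple[list[ChemicalRecord], dict]:
    """Generate ``n_chemicals`` unique, parseable records plus a truth table.

    Each planted fragment is carried by exactly ``round(rate * n)`` chemicals
    (disjoint subsets, chosen by a seeded shuffle); non-carriers are verified
    not to match any planted pattern. Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    patterns = {f.smiles: Chem.MolFromSmarts(f.smiles)
                for f in cfg.planted_fragments}

    # exact-count disjoint fragment assignment
    order = rng.permutation(cfg.n_chemicals)
    assignment: dict[int, PlantedFragment | None] = dict.fromkeys(
        range(cfg.n_chemicals))
    pos = 0
    for frag in cfg.planted_fragments:
        n_carriers = round(frag.rate * cfg.n_chemicals)
        for idx in order[pos:pos + n_carriers]:
            assignment[int(idx)] = frag
        pos += n_carriers

    records: list[ChemicalRecord] = []
    seen: set[str] = set()
    truth: dict[str, dict] = {}
    for i in range(cfg.n_chemicals):
        frag = assignment[i]
        for _attempt in range(200):
            smiles = _assemble(rng, frag.smiles if frag else None)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            # a non-carrier must not match any planted pattern
            if frag is None and any(
                mol.HasSubstructMatch(p) for p in patterns.values()
            ):
                continue
            break
        else:  # pragma: no cover - grammar guarantees termination
            raise RuntimeError("could not assemble a unique valid molecule")
        seen.add(canon)
        rid = f"SYN{i:05d}"
        records.append(ChemicalRecord(rid, smiles, canon, source="synthetic"))
        truth[rid] = {"fragment": frag.smiles if frag else None,
                      "effect": frag.effect if frag else 0.0}
    return records, truth


def assign_endpoints(records: list[ChemicalRecord], cfg: GeneratorConfig,
                     truth: dict) -> tuple[pd.DataFrame, dict]:
    """Raw measurement rows (chemreg input schema) with known ground truth.

    Clean values follow the fragment-additive model; curation hazards
    (duplicates with discordant replicates, qualifier-only records,
    out-of-range F%) are then applied to disjoint record subsets. The
    returned truth table gains per-record clean values and hazard tags.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(records)
    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)

    clean = np.empty(n)
    for i, rec in enumerate(records):
        effect = truth[rec.record_id]["effect"]
        if cfg.endpoint is Endpoint.F_PERCENT:
            clean[i] = float(np.clip(cfg.f_base + effect + noise[i], 0.0, 100.0))
        else:
            clean[i] = float(np.exp(effect + noise[i]))

    # disjoint hazard subsets
    order = rng.permutation(n)
    n_oor = round(cfg.out_of_range_rate * n) if cfg.endpoint is Endpoint.F_PERCENT else 0
    n_qual = round(cfg.qualifier_rate * n)
    n_dup = round(cfg.duplicate_rate * n)
    oor = set(order[:n_oor].tolist())
    qual = set(order[n_oor:n_oor + n_qual].tolist())
    dup = set(order[n_oor + n_qual:n_oor + n_qual + n_dup].tolist())

    rows = []
    for i, rec in enumerate(records):
        t = truth[rec.record_id]
        t["clean_value"] = clean[i]
        t["hazard"] = None
        base_row = {"id": rec.record_id, "smiles": rec.smiles_raw,
                    "endpoint": cfg.endpoint.name, "value": clean[i],
                    "qualifier": "", "source": "synthetic"}
        if i in oor:
            t["hazard"] = "out_of_range"
            base_row["value"] = 100.0 + float(rng.uniform(1.0, 25.0))
            rows.append(base_row)
        elif i in qual:
            t["hazard"] = "qualifier_only"
            base_row["qualifier"] = ">" if rng.random() < 0.5 else "<"
            if cfg.endpoint is Endpoint.F_PERCENT:
                base_row["value"] = 80.0 if base_row["qualifier"] == ">" else 20.0
            else:
                base_row["value"] = 5.0 if base_row["qualifier"] == ">" else 0.6
            rows.append(base_row)
        elif i in dup:
            t["hazard"] = "duplicate"
            jitter = float(rng.uniform(2.0, 10.0))
            rows.append(base_row)
            rows.append({**base_row, "id": rec.record_id + "_dup",
                         "value": base_row["value"] + jitter})
        else:
            rows.append(base_row)
    frame = pd.DataFrame(rows, columns=["id", "smiles", "endpoint", "value",
                                        "qualifier", "source"])
    return frame, truth


def generate_dataset(cfg: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Library + endpoint assignment in one call."""
    records, truth = generate_library(cfg)
    return assign_endpoints(records, cfg, truth)


def make_informative_matrix(
    n_rows: int, n_informative: int, n_noise: int, effect: float,
    noise_sd: float, seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric fixture for variable-selection recovery tests.

    Standard-normal descriptor columns; the response is
    ``effect * (sum of informative columns) + N(0, noise_sd)``. Informative
    columns are named ``inf_00…``, noise columns ``noise_00…``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_rows, n_informative + n_noise))
    names = [f"inf_{i:02d}" for i in range(n_informative)] + [
        f"noise_{i:02d}" for i in range(n_noise)]
    y = effect * x[:, :n_informative].sum(axis=1) + rng.normal(
        0.0, noise_sd, size=n_rows)
    return pd.DataFrame(x, columns=names), y
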