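"""Similarity-based applicability domain (AD).

A query chemical is scored by the mean Tanimoto similarity of its Morgan
fingerprint (radius 2, 2048 bits by default) to its three nearest training-set
neighbors. The in-domain cutoff is Dc = ⟨y⟩ − Z·σ, where ⟨y⟩ and σ are the
mean and (population) standard deviation of the per-chemical 3-NN scores and
Z (default 0.5) controls the significance level; subtracting adapts the
classical distance formula to the similarity scale where 1 means identical.
A PLUS mode (⟨y⟩ + Z·σ) is exposed as well, since both sign conventions occur
in practice. Coverage–performance curves trace how a validation metric evolves
as the threshold tightens, and a leverage (hat-matrix) scorer is provided as
an alternative descriptor-space AD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chemreg import ChemicalRecord
from .errors import (
    LengthMismatchError,
    SingularMatrixError,
    TrainTooSmallError,
    UnparseableSmilesError,
)
from .features import DescriptorMatrix

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048
DEFAULT_K = 3
DEFAULT_Z = 0.5


class DcMode(enum.Enum):
    MINUS = "MINUS"
    PLUS = "PLUS"


@dataclass(frozen=True)
class FingerprintSet:
    ids: tuple[str, ...]
    bits: np.ndarray  # (n, n_bits) uint8
    radius: int = DEFAULT_RADIUS
    n_bits: int = DEFAULT_N_BITS


@dataclass(frozen=True)
class ADScore:
    query_id: str
    mean_knn_tanimoto: float
    neighbors: tuple[tuple[str, float], ...]  # (train id, similarity), sim desc
    in_domain: bool | None = None


def morgan_fingerprints(records: Iterable[ChemicalRecord],
                        radius: int = DEFAULT_RADIUS,
                        n_bits: int = DEFAULT_N_BITS) -> FingerprintSet:
    """Morgan (ECFP-like) bit fingerprints for standardized records."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ids, rows = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles_std)
        if mol is None:
            raise UnparseableSmilesError(rec.smiles_std)
        fp = gen.GetFingerprintAsNumPy(mol)
        ids.append(rec.record_id)
        rows.append(fp.astype(np.uint8))
    bits = np.vstack(rows) if rows else np.zeros((0, n_bits), dtype=np.uint8)
    return FingerprintSet(tuple(ids), bits, radius, n_bits)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a∧b| / |a∨b| on equal-length bit vectors; 0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise LengthMismatchError(f"{a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return int(np.sum(a & b)) / union


def knn_ad_score(query: np.ndarray, train: FingerprintSet, k: int = DEFAULT_K,
                 query_id: str = "") -> ADScore:
    """Mean Tanimoto similarity of the k most similar training chemicals.

    Ties in similarity are broken by training id, ascending.
    """
    n = len(train.ids)
    if n < k:
        raise TrainTooSmallError(f"need >= {k} training fingerprints, have {n}")
    q = np.asarray(query, dtype=bool)
    t = train.bits.astype(bool)
    if q.shape[0] != t.shape[1]:
        raise LengthMismatchError("query/train fingerprint length mismatch")
    inter = (t & q).sum(axis=1)
    union = (t | q).sum(axis=1)
    sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    order = sorted(range(n), key=lambda i: (-sims[i], train.ids[i]))[:k]
    neighbors = tuple((train.ids[i], float(sims[i])) for i in order)
    return ADScore(
        query_id=query_id,
        mean_knn_tanimoto=float(np.mean([s for _, s in neighbors])),
        neighbors=neighbors,
    )


def score_set(queries: FingerprintSet, train: FingerprintSet,
              k: int = DEFAULT_K) -> list[ADScore]:
    return [
        knn_ad_score(queries.bits[i], train, k=k, query_id=queries.ids[i])
        for i in range(len(queries.ids))
    ]


def dc_threshold(mean_scores: Sequence[float], z: float = DEFAULT_Z,
                 mode: DcMode = DcMode.MINUS) -> float:
    """In-domain cutoff Dc = ⟨y⟩ ∓ Z·σ from per-chemical k-NN mean scores.

    σ is the population (n-denominator) standard deviation; for set sizes in
    the hundreds the difference from the sample form is below reporting
    precision.
    """
    scores = np.asarray(list(mean_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("mean_scores must be non-empty")
    mean = float(np.mean(scores))
    sigma = float(np.std(scores))
    return mean - z * sigma if mode is DcMode.MINUS else mean + z * sigma


def apply_domain(scores: Iterable[ADScore], dc: float) -> list[ADScore]:
    """Mark each score in/out of domain: in iff mean 3-NN Tanimoto >= Dc."""
    return [
        ADScore(s.query_id, s.mean_knn_tanimoto, s.neighbors,
                in_domain=s.mean_knn_tanimoto >= dc)
        for s in scores
    ]


def coverage_performance_curve(
    scores: Sequence[ADScore],
    y_true: Sequence[float],
    y_pred: Sequence[float],
    eval_fn: Callable[[np.ndarray, np.ndarray], float],
    thresholds: Sequence[float],
) -> list[dict]:
    """Metric vs coverage as the similarity threshold tightens.

    For each threshold t: coverage = fraction of chemicals whose mean k-NN
    score is >= t; the metric is evaluated on that retained subset. Empty
    subsets are flagged with a null metric. Rows are ordered by threshold.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    s = np.asarray([sc.mean_knn_tanimoto for sc in scores], dtype=float)
    if not (len(s) == len(y_true) == len(y_pred)):
        raise LengthMismatchError("scores, y_true, y_pred must align")
    rows = []
    for t in sorted(thresholds):
        mask = s >= t
        n_ret = int(mask.sum())
        row = {"threshold": float(t), "n_retained": n_ret,
               "coverage": n_ret / len(s), "metric": None, "empty": n_ret == 0}
        if n_ret:
            row["metric"] = float(eval_fn(y_true[mask], y_pred[mask]))
        rows.append(row)
    return rows


def leverage_ad(x_train: DescriptorMatrix | np.ndarray,
                x_query: np.ndarray) -> tuple[np.ndarray, float]:
    """Hat-matrix leverages of query rows with the 3(p+1)/n warning cutoff.

    The design is augmented with an intercept column, so a query at the
    training centroid has the minimal leverage 1/n. Raises SINGULAR_MATRIX for
    rank-deficient designs.
    """
    xt = x_train.values if isinstance(x_train, DescriptorMatrix) else np.asarray(
        x_train, dtype=float)
    xq = np.atleast_2d(np.asarray(x_query, dtype=float))
    n, p = xt.shape
    xt1 = np.hstack([np.ones((n, 1)), xt])
    xq1 = np.hstack([np.ones((xq.shape[0], 1)), xq])
    gram = xt1.T @ xt1
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise SingularMatrixError("descriptor matrix is rank-deficient")
    ginv = np.linalg.inv(gram)
    h = np.einsum("ij,jk,ik->i", xq1, ginv, xq1)
    h_star = 3.0 * (p + 1) / n
    return h, h_star
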