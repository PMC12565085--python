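"""Fragment-based structural alerts with likelihood-ratio scoring.

Alerts are connected substructures mined from a labeled training library:
every connected subgraph within a heavy-atom window is enumerated per
molecule, deduplicated by canonical fragment SMILES, and scored one class at a
time with a prevalence-normalized likelihood ratio

    LR = (tp / n_target) / (fp / n_nontarget)

so imbalanced classes do not inflate scores. Fragments that never match a
non-target molecule get an infinite LR, later capped at the largest finite LR
in the rule set. Rules are filtered by support and LR, ordered by
(LR desc, support desc, pattern asc), and pruned when a rule's matched
training set is a subset of a higher-ranked same-class rule's. Prediction
assigns the class of the first matching rule, whose (capped) LR doubles as an
applicability-domain score: predictions whose alert LR does not exceed a
threshold — and unmatched chemicals — are out of domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from .chemreg import ChemicalRecord
from .errors import InvalidCountsError

NO_MATCH = "NO_MATCH"

DEFAULT_MIN_ATOMS = 2
DEFAULT_MAX_ATOMS = 18
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MIN_LR = 2.0


@dataclass(frozen=True)
class AlertRule:
    fragment: str  # canonical fragment pattern, usable as SMARTS
    target_class: str
    tp: int
    fp: int
    n_target: int
    n_nontarget: int
    lr: float  # may be math.inf when fp == 0
    capped_lr: float
    matched_ids: frozenset[str]


@dataclass(frozen=True)
class AlertPrediction:
    query_id: str
    predicted_class: str  # class label or NO_MATCH
    matched_alert: AlertRule | None
    lr_of_prediction: float  # 0.0 for NO_MATCH


def _mol_of(record: ChemicalRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles_std)
    if mol is None:
        raise ValueError(f"unparseable standardized SMILES {record.smiles_std!r}")
    return mol


def fragments_of_molecule(mol: Chem.Mol, min_atoms: int,
                          max_atoms: int) -> set[str]:
    """Canonical SMILES of every connected subgraph in the atom window.

    Bond subgraphs of up to ``max_atoms`` bonds are enumerated (enough for one
    ring closure per fragment) and filtered by heavy-atom count.
    """
    if min_atoms > max_atoms:
        return set()
    out: set[str] = set()
    if min_atoms <= 1:
        for atom in mol.GetAtoms():
            out.add(Chem.MolFragmentToSmiles(mol, atomsToUse=[atom.GetIdx()],
                                             canonical=True))
    max_bonds = max_atoms
    min_bonds = max(1, min_atoms - 1)
    if mol.GetNumBonds() == 0:
        return out
    subgraphs = Chem.FindAllSubgraphsOfLengthMToN(mol, min_bonds, max_bonds)
    for by_length in subgraphs:
        for bond_ids in by_length:
            atoms = set()
            for b in bond_ids:
                bond = mol.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            if not (min_atoms <= len(atoms) <= max_atoms):
                continue
            out.add(Chem.MolFragmentToSmiles(
                mol, atomsToUse=sorted(atoms), bondsToUse=list(bond_ids),
                canonical=True))
    return out


def enumerate_fragments(
    training: Sequence[ChemicalRecord],
    min_atoms: int = DEFAULT_MIN_ATOMS,
    max_atoms: int = DEFAULT_MAX_ATOMS,
) -> dict[str, set[str]]:
    """All candidate fragments over a training library.

    Returns a mapping ``fragment -> set of record ids`` whose enumeration
    produced it (exact containment within the window). Deterministic and
    independent of input order.
    """
    candidates: dict[str, set[str]] = {}
    for rec in training:
        for frag in fragments_of_molecule(_mol_of(rec), min_atoms, max_atoms):
            candidates.setdefault(frag, set()).add(rec.record_id)
    return candidates


def score_alert_lr(tp: int, fp: int, n_target: int, n_nontarget: int) -> float:
    """Prevalence-normalized likelihood ratio; fp == 0 yields +inf."""
    if not (0 <= tp <= n_target and 0 <= fp <= n_nontarget):
        raise InvalidCountsError(f"tp={tp}/{n_target}, fp={fp}/{n_nontarget}")
    if n_target <= 0 or n_nontarget <= 0:
        raise InvalidCountsError("class sizes must be positive")
    if fp == 0:
        return math.inf
    return (tp / n_target) / (fp / n_nontarget)


def _rule_sort_key(rule: AlertRule):
    return (-rule.capped_lr, -rule.tp, rule.fragment)


def cap_infinite_lrs(rules: list[AlertRule]) -> list[AlertRule]:
    """Replace infinite LRs by the rule-set maximum finite LR.

    If no finite LR exists, the cap falls back per rule to
    (tp/n_target)·n_nontarget — the LR the rule would have at a single false
    positive, the largest value the sample sizes can resolve.
    """
    finite = [r.lr for r in rules if math.isfinite(r.lr)]
    cap = max(finite) if finite else None
    out = []
    for r in rules:
        if math.isfinite(r.lr):
            out.append(replace(r, capped_lr=r.lr))
        else:
            fallback = (r.tp / r.n_target) * r.n_nontarget
            out.append(replace(r, capped_lr=cap if cap is not None else fallback))
    return out


def select_alerts(candidates: Iterable[AlertRule],
                  min_support: int = DEFAULT_MIN_SUPPORT,
                  min_lr: float = DEFAULT_MIN_LR) -> list[AlertRule]:
    """Filter, cap, order, and prune a scored candidate set.

    Keeps candidates with ``tp >= min_support`` and ``lr >= min_lr``; caps
    infinite LRs; orders by (capped LR desc, tp desc, pattern asc); removes a
    rule whose matched training set is a subset of a higher-ranked rule of the
    same class (the more general or better-scored pattern wins).
    """
    kept = [r for r in candidates if r.tp >= min_support and r.lr >= min_lr]
    kept = cap_infinite_lrs(kept)
    kept.sort(key=_rule_sort_key)
    pruned: list[AlertRule] = []
    for rule in kept:
        redundant = any(
            rule.target_class == prev.target_class
            and rule.matched_ids <= prev.matched_ids
            for prev in pruned
        )
        if not redundant:
            pruned.append(rule)
    return pruned


def mine_alerts(
    training: Sequence[ChemicalRecord],
    labels: Mapping[str, str],
    min_atoms: int = DEFAULT_MIN_ATOMS,
    max_atoms: int = DEFAULT_MAX_ATOMS,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_lr: float = DEFAULT_MIN_LR,
) -> list[AlertRule]:
    """Mine an ordered multi-class rule set from a labeled library.

    Classes are mined one-vs-rest and merged into a single ordered set. Match
    counts are substructure-match counts over the training library, keeping
    training counts consistent with how unseen queries are predicted;
    candidates whose enumeration-origin count (a lower bound on the match
    count) is below ``min_support`` are skipped early.
    """
    training = [r for r in training if r.record_id in labels]
    candidates = enumerate_fragments(training, min_atoms, max_atoms)
    mols = {r.record_id: _mol_of(r) for r in training}
    classes = sorted(set(labels[r.record_id] for r in training))
    by_class_ids = {
        cls: frozenset(r.record_id for r in training if labels[r.record_id] == cls)
        for cls in classes
    }

    rules: list[AlertRule] = []
    for frag in sorted(candidates):
        if len(candidates[frag]) < min_support:
            continue
        query = Chem.MolFromSmarts(frag)
        if query is None:
            continue
        matched = frozenset(
            rid for rid, mol in mols.items() if mol.HasSubstructMatch(query)
        )
        for cls in classes:
            n_target = len(by_class_ids[cls])
            n_nontarget = len(training) - n_target
            if n_target == 0 or n_nontarget == 0:
                continue
            tp = len(matched & by_class_ids[cls])
            fp = len(matched) - tp
            if tp < min_support:
                continue
            lr = score_alert_lr(tp, fp, n_target, n_nontarget)
            rules.append(AlertRule(
                fragment=frag, target_class=cls, tp=tp, fp=fp,
                n_target=n_target, n_nontarget=n_nontarget,
                lr=lr, capped_lr=lr if math.isfinite(lr) else math.nan,
                matched_ids=matched,
            ))
    return select_alerts(rules, min_support=min_support, min_lr=min_lr)


def predict_by_alerts(query: ChemicalRecord, rules: Sequence[AlertRule],
                      default_class: str | None = None) -> AlertPrediction:
    """Class of the first matching rule in the ordered set; else NO_MATCH."""
    mol = _mol_of(query)
    for rule in rules:
        patt = Chem.MolFromSmarts(rule.fragment)
        if patt is not None and mol.HasSubstructMatch(patt):
            return AlertPrediction(query.record_id, rule.target_class, rule,
                                   rule.capped_lr)
    return AlertPrediction(query.record_id, default_class or NO_MATCH, None, 0.0)


def lr_ad_filter(
    predictions: Iterable[AlertPrediction], lr_threshold: float
) -> tuple[list[AlertPrediction], list[AlertPrediction]]:
    """Partition predictions into (in_domain, out_of_domain).

    A prediction is in domain iff its alert's LR strictly exceeds the
    threshold; unmatched chemicals are always out of domain.
    """
    inside, outside = [], []
    for p in predictions:
        if p.matched_alert is not None and p.lr_of_prediction > lr_threshold:
            inside.append(p)
        else:
            outside.append(p)
    return inside, outside
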