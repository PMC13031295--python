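"""Bemis-Murcko scaffold grouping and leakage-free dataset partitioning.

Records are grouped at the chromophore level: every record of a
chromophore, across all solvents, lands in the same subset, and whole
scaffold groups (ring systems + linkers, side chains removed) are
assigned to exactly one of train/validation/test or one CV fold.  This
prevents the leakage that random pair-level splitting introduces when
the same chromophore appears with several solvents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .molecular_data import Dataset, Molecule

__all__ = [
    "EMPTY_SCAFFOLD", "Scaffold", "SplitAssignment",
    "murcko_scaffold", "group_by_scaffold", "scaffold_split",
    "scaffold_kfold", "write_manifest", "read_manifest",
]

EMPTY_SCAFFOLD = "<EMPTY>"
SUBSETS = ("TRAIN", "VAL", "TEST")


@dataclass
class Scaffold:
    key: str
    chromophore_keys: set = field(default_factory=set)
    record_indices: list = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.record_indices)


@dataclass
class SplitAssignment:
    """record index -> subset name (or fold id via 'TEST' marking per fold)."""

    subsets: dict                      # int -> str in SUBSETS
    fractions: tuple | None
    seed: int
    scaffold_of: dict = field(default_factory=dict)   # record idx -> scaffold key

    def indices(self, subset: str) -> list:
        return sorted(i for i, s in self.subsets.items() if s == subset)

    def validate(self) -> None:
        by_subset: dict = {}
        for i, s in self.subsets.items():
            by_subset.setdefault(s, set()).add(self.scaffold_of.get(i))
        for a in SUBSETS:
            for b in SUBSETS:
                if a < b and by_subset.get(a, set()) & by_subset.get(b, set()):
                    raise AssertionError(
                        f"scaffold overlap between {a} and {b}")


def murcko_scaffold(molecule: Molecule | str) -> str:
    """Canonical key of the Bemis-Murcko framework; acyclic -> EMPTY.

    The generic framework keeps ring systems plus linker atoms with
    element and bond identity (exocyclic double-bonded atoms retained),
    matching the common toolkit convention.
    """
    smiles = molecule if isinstance(molecule, str) else molecule.canonical_key
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse {smiles!r}")
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    key = Chem.MolToSmiles(scaf)
    return key if key else EMPTY_SCAFFOLD


def group_by_scaffold(dataset: Dataset) -> list[Scaffold]:
    groups: dict[str, Scaffold] = {}
    for idx, rec in enumerate(dataset.records):
        key = murcko_scaffold(rec.chromophore)
        g = groups.setdefault(key, Scaffold(key=key))
        g.chromophore_keys.add(rec.chromophore.canonical_key)
        g.record_indices.append(idx)
    return [groups[k] for k in sorted(groups)]


def _largest_remainder_quotas(n: int, fractions) -> list[int]:
    raw = [n * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder first
    for j in range(short):
        base[order[j]] += 1
    return base


def scaffold_split(dataset: Dataset, fractions=(0.8, 0.1, 0.1),
                   seed: int = 0) -> SplitAssignment:
    """Whole-scaffold 80/10/10-style split with seeded random ordering.

    Scaffolds are shuffled with the seed and greedily fill TRAIN to its
    record quota, then VAL, then TEST (largest-remainder quotas; a
    scaffold overflowing a quota goes to the next unfilled subset).
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    scaffolds = group_by_scaffold(dataset)
    if len(scaffolds) < 3:
        raise ValueError(
            f"need at least 3 scaffolds for a 3-way split, got {len(scaffolds)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scaffolds))
    quotas = _largest_remainder_quotas(len(dataset), fractions)
    counts = [0, 0, 0]
    assign: dict[int, str] = {}
    scaffold_of: dict[int, str] = {}
    members: list[list[Scaffold]] = [[], [], []]
    for gi in order:
        g = scaffolds[gi]
        placed = None
        for s in range(3):
            if counts[s] + g.n_records <= quotas[s]:
                placed = s
                break
        if placed is None:  # every subset would overflow: least-filled wins
            placed = int(np.argmax([q - c for q, c in zip(quotas, counts)]))
        counts[placed] += g.n_records
        members[placed].append(g)
    # guarantee three nonempty subsets by demoting smallest groups from TRAIN
    for s in (1, 2):
        if not members[s]:
            donor = max(range(3), key=lambda t: len(members[t]))
            g = min(members[donor], key=lambda x: x.n_records)
            members[donor].remove(g)
            members[s].append(g)
    for s, name in enumerate(SUBSETS):
        for g in members[s]:
            for idx in g.record_indices:
                assign[idx] = name
                scaffold_of[idx] = g.key
    split = SplitAssignment(assign, tuple(fractions), seed, scaffold_of)
    split.validate()
    return split


def scaffold_kfold(dataset: Dataset, k: int, seed: int = 0,
                   val_fraction: float = 0.0) -> list[SplitAssignment]:
    """k scaffold-disjoint folds; fold i is TEST, the rest TRAIN.

    With ``val_fraction`` > 0, validation scaffolds are carved out of
    each fold's TRAIN pool, re-drawn per fold with the fold index mixed
    into the seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    scaffolds = group_by_scaffold(dataset)
    if k > len(scaffolds):
        raise ValueError(f"k={k} exceeds scaffold count {len(scaffolds)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scaffolds))
    fold_records = [0] * k
    fold_members: list[list[Scaffold]] = [[] for _ in range(k)]
    for gi in order:                     # greedy: smallest fold takes next group
        g = scaffolds[gi]
        f = int(np.argmin(fold_records))
        fold_records[f] += g.n_records
        fold_members[f].append(g)
    splits = []
    for f in range(k):
        assign, scaffold_of = {}, {}
        train_groups = []
        for ff in range(k):
            for g in fold_members[ff]:
                name = "TEST" if ff == f else "TRAIN"
                for idx in g.record_indices:
                    assign[idx] = name
                    scaffold_of[idx] = g.key
                if ff != f:
                    train_groups.append(g)
        if val_fraction > 0 and train_groups:
            n_train = sum(g.n_records for g in train_groups)
            target = val_fraction * n_train
            sub_rng = np.random.default_rng((seed, f))
            got = 0
            for g in sub_rng.permutation(len(train_groups)):
                if got >= target:
                    break
                grp = train_groups[int(g)]
                for idx in grp.record_indices:
                    assign[idx] = "VAL"
                got += grp.n_records
        split = SplitAssignment(assign, None, seed, scaffold_of)
        split.validate()
        splits.append(split)
    # every record must be TEST exactly once across folds
    counts = np.zeros(len(dataset), dtype=int)
    for sp in splits:
        for i in sp.indices("TEST"):
            counts[i] += 1
    if not np.all(counts == 1):
        raise AssertionError("k-fold TEST sets do not partition the dataset")
    return splits


def write_manifest(split: SplitAssignment, dataset: Dataset, path) -> None:
    path = Path(path)
    rows = []
    for idx in sorted(split.subsets):
        rec = dataset.records[idx]
        rows.append({
            "record_index": idx,
            "chromophore_key": rec.chromophore.canonical_key,
            "scaffold_key": split.scaffold_of.get(idx, ""),
            "subset": split.subsets[idx],
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = {"seed": split.seed, "fractions": split.fractions}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_manifest(path) -> SplitAssignment:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    subsets = dict(zip(df["record_index"], df["subset"]))
    scaffold_of = dict(zip(df["record_index"], df["scaffold_key"]))
    fr = sidecar.get("fractions")
    return SplitAssignment(subsets, tuple(fr) if fr else None,
                           sidecar.get("seed", 0), scaffold_of)
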