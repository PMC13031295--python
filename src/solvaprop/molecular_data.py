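"""Chemical data model, file I/O and curation for chromophore-solvent records.

A record couples a chromophore (2D graph from SMILES), a solvent, a
partially observed target vector (absorption maximum in nm, emission
maximum in nm, log10 PLQY) and a ladder of 3D conformers tagged by the
geometry-optimization fidelity that produced them (force-field, xTB,
DFT in vacuum, DFT in implicit solvent, ...).  Curation removes records
whose 3D connectivity is inconsistent with the SMILES graph, collapses
exact duplicates and flags conflicting labels and protonation variants
for manual review.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem, rdBase
from rdkit.Chem.MolStandardize import rdMolStandardize

__all__ = [
    "Molecule", "Conformer", "LabeledPair", "Dataset", "CurationReport",
    "CurationRules", "StructureParseError", "TopologyError",
    "parse_structure", "read_conformers", "write_conformers",
    "perceive_connectivity", "check_topology_consistency", "curate",
    "load_labels", "register_fidelity", "registered_fidelities",
    "TARGET_NAMES", "COVALENT_RADII",
]

TARGET_NAMES = ("lambda_abs_nm", "lambda_ems_nm", "log10_plqy")
N_TARGETS = 3

# geometry-fidelity registry; extensible, level count is data-driven
_FIDELITY_LEVELS: list[str] = ["RDKIT", "XTB", "DFT_VAC", "DFT_IMP", "REFINED"]


def register_fidelity(tag: str) -> None:
    if tag not in _FIDELITY_LEVELS:
        _FIDELITY_LEVELS.append(tag)


def registered_fidelities() -> tuple[str, ...]:
    return tuple(_FIDELITY_LEVELS)


# Cordero covalent radii, Å (single-bond values for common elements)
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Se": 1.20, "Br": 1.20,
    "I": 1.39,
}


class StructureParseError(ValueError):
    """Raised for syntactically or chemically invalid SMILES input."""


class TopologyError(ValueError):
    """Raised when a conformer cannot be compared to a molecular graph."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Molecule:
    """Heavy-atom 2D chemical graph.

    atoms: (element symbol, formal charge, aromatic flag, attached-H count)
    bonds: (i, j, bond order, aromatic flag) with 0-based indices, i < j
    """

    atoms: list
    bonds: list
    canonical_key: str | None = None

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for (i, j, *_rest) in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i},{j}) for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for idx, (sym, *_r) in enumerate(self.atoms):
            g.add_node(idx, element=sym)
        for (i, j, *_r) in self.bonds:
            g.add_edge(i, j)
        return g

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "Molecule":
        atoms = [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
             b.GetBondTypeAsDouble(), b.GetIsAromatic())
            for b in mol.GetBonds()
        ]
        bonds = [(min(i, j), max(i, j), o, ar) for i, j, o, ar in bonds]
        return cls(atoms=atoms, bonds=bonds, canonical_key=Chem.MolToSmiles(mol))


@dataclass
class Conformer:
    """Cartesian coordinates (Å) for one molecule at a named fidelity level."""

    coordinates: np.ndarray
    elements: list
    fidelity_tag: str
    source_id: str | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N×3")
        if self.coordinates.shape[0] != len(self.elements):
            raise ValueError(
                f"{self.coordinates.shape[0]} coordinate rows for "
                f"{len(self.elements)} elements"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.fidelity_tag not in _FIDELITY_LEVELS:
            raise ValueError(
                f"unknown fidelity tag {self.fidelity_tag!r}; "
                f"registered: {_FIDELITY_LEVELS}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class LabeledPair:
    """One chromophore-solvent record with masked targets and conformers."""

    chromophore: Molecule
    solvent: Molecule
    targets: np.ndarray          # (3,) [λ_abs nm, λ_ems nm, log10 PLQY]; NaN if masked
    mask: np.ndarray             # (3,) bool, True = observed
    conformers: dict = field(default_factory=dict)  # fidelity tag -> Conformer
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.targets.shape != (N_TARGETS,) or self.mask.shape != (N_TARGETS,):
            raise ValueError("targets and mask must have length 3")
        self.targets = np.where(self.mask, self.targets, np.nan)
        if self.mask[0] and not self.targets[0] > 0:
            raise ValueError("observed λ_abs must be strictly positive")
        if self.mask[1] and not self.targets[1] > 0:
            raise ValueError("observed λ_ems must be strictly positive")

    @property
    def pair_key(self) -> tuple:
        return (self.chromophore.canonical_key, self.solvent.canonical_key)

    def add_conformer(self, conf: Conformer) -> None:
        if conf.fidelity_tag in self.conformers:
            raise ValueError(
                f"record already has a conformer at level {conf.fidelity_tag}"
            )
        self.conformers[conf.fidelity_tag] = conf


class Dataset:
    """Container of curated chromophore-solvent records with an access log.

    The access log records every label / conformer read so training code
    can be audited for split hygiene (no TEST label touched before final
    evaluation, no reference-geometry read during coarse inference).
    """

    def __init__(self, records: list | None = None):
        self.records: list[LabeledPair] = list(records or [])
        self.access_log: list[tuple] = []

    def __len__(self):
        return len(self.records)

    def __getitem__(self, i) -> LabeledPair:
        return self.records[i]

    @property
    def fidelity_levels(self) -> tuple:
        present = []
        for r in self.records:
            for t in r.conformers:
                if t not in present:
                    present.append(t)
        return tuple(present)

    def get_targets(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        self.access_log.append(("targets", i))
        r = self.records[i]
        return r.targets, r.mask

    def get_conformer(self, i: int, tag: str) -> Conformer:
        self.access_log.append(("conformer", i, tag))
        r = self.records[i]
        if tag not in r.conformers:
            raise KeyError(
                f"record {i} has no conformer at level {tag!r}; "
                f"available: {sorted(r.conformers)}"
            )
        return r.conformers[tag]

    def clear_log(self):
        self.access_log = []


@dataclass
class CurationReport:
    inspected: int = 0
    removed: int = 0
    retained: int = 0
    corrected: int = 0
    per_rule: Counter = field(default_factory=Counter)
    flagged: list = field(default_factory=list)   # (pair_key, reason)

    def validate(self):
        if self.removed + self.retained != self.inspected:
            raise AssertionError("removed + retained must equal inspected")

    @property
    def total_flags(self) -> int:
        return len(self.flagged)


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

class _RDKitLogCapture(logging.Handler):
    def __init__(self):
        super().__init__()
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def parse_structure(smiles: str) -> Molecule:
    """Parse a SMILES string into a valence-checked heavy-atom Molecule.

    Raises :class:`StructureParseError` naming the offending token or
    atom for syntactically or chemically invalid input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureParseError("empty SMILES string")
    handler = _RDKitLogCapture()
    logger = logging.getLogger("rdkit")
    rdBase.LogToPythonLogger()
    logger.addHandler(handler)
    try:
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
    finally:
        logger.removeHandler(handler)
        rdBase.LogToCppStreams()
    if mol is None:
        detail = "; ".join(handler.messages) or "unparseable"
        raise StructureParseError(f"invalid SMILES {smiles!r}: {detail}")
    problems = Chem.DetectChemistryProblems(mol)
    if problems:
        msgs = "; ".join(p.Message() for p in problems)
        raise StructureParseError(f"invalid structure {smiles!r}: {msgs}")
    Chem.SanitizeMol(mol)
    return Molecule.from_rdkit(mol)


# --------------------------------------------------------------------------
# conformer I/O
# --------------------------------------------------------------------------

def _check_fidelity(tag: str, where: str) -> str:
    if tag not in _FIDELITY_LEVELS:
        raise ValueError(
            f"unknown fidelity token {tag!r} in {where}; "
            f"registered levels: {_FIDELITY_LEVELS}"
        )
    return tag


def _read_xyz(path: Path) -> list[Conformer]:
    lines = path.read_text().splitlines()
    confs, pos, block = [], 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        block += 1
        try:
            natoms = int(lines[pos].strip())
        except ValueError as e:
            raise ValueError(f"malformed atom-count line at block {block}") from e
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        meta = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok
        )
        rows = lines[pos + 2: pos + 2 + natoms]
        if len(rows) < natoms or any(len(r.split()) < 4 for r in rows):
            raise ValueError(f"malformed coordinate block at block {block}")
        elements, coords = [], []
        for r in rows:
            parts = r.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        tag = _check_fidelity(meta.get("fidelity", ""), f"XYZ block {block}")
        confs.append(Conformer(np.array(coords), elements, tag,
                               source_id=meta.get("key")))
        pos += 2 + natoms
    return confs


def _read_sdf(path: Path) -> list[Conformer]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    confs = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"malformed SDF record at block {idx + 1}")
        if mol.GetNumConformers() == 0:
            raise ValueError(f"SDF record {idx + 1} has no coordinates")
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        tag = _check_fidelity(
            mol.GetProp("FIDELITY") if mol.HasProp("FIDELITY") else "",
            f"SDF record {idx + 1}",
        )
        key = (mol.GetProp("CANONICAL_KEY") if mol.HasProp("CANONICAL_KEY")
               else (mol.GetProp("_Name") or None))
        confs.append(Conformer(coords, elements, tag, source_id=key))
    return confs


def read_conformers(path, fmt: str | None = None) -> list[Conformer]:
    """Read conformers from an SDF (V2000) or multi-block XYZ file.

    Fidelity is read from the ``FIDELITY`` SDF property or the
    ``fidelity=<tag>`` token on the XYZ comment line; molecule linkage
    from ``CANONICAL_KEY``/record title or the ``key=<...>`` token.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt == "XYZ":
        return _read_xyz(path)
    if fmt == "SDF":
        return _read_sdf(path)
    raise ValueError(f"unsupported conformer format {fmt!r}")


def write_conformers(conformers: list, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt == "XYZ":
        out = []
        for c in conformers:
            out.append(str(c.n_atoms))
            out.append(f"key={c.source_id or ''} fidelity={c.fidelity_tag}")
            for el, (x, y, z) in zip(c.elements, c.coordinates):
                out.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
        path.write_text("\n".join(out) + "\n")
        return
    if fmt == "SDF":
        blocks = []
        for c in conformers:
            rw = Chem.RWMol()
            for el in c.elements:
                a = Chem.Atom(el)
                a.SetNoImplicit(True)
                rw.AddAtom(a)
            conf = Chem.Conformer(c.n_atoms)
            for i, (x, y, z) in enumerate(c.coordinates):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            m = rw.GetMol()
            m.AddConformer(conf)
            block = Chem.MolToMolBlock(m, kekulize=False)
            props = (f">  <FIDELITY>\n{c.fidelity_tag}\n\n"
                     f">  <CANONICAL_KEY>\n{c.source_id or ''}\n\n$$$$\n")
            blocks.append(block + props)
        path.write_text("".join(blocks))
        return
    raise ValueError(f"unsupported conformer format {fmt!r}")


# --------------------------------------------------------------------------
# connectivity perception and topology checks
# --------------------------------------------------------------------------

def _radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise ValueError(
            f"no tabulated covalent radius for element {element!r}"
        ) from None


def perceive_connectivity(conformer: Conformer, tolerance: float = 0.4) -> Molecule:
    """Heavy-atom connectivity from 3D coordinates (bond orders unset).

    Atoms i, j are bonded iff d(i,j) ≤ r_cov(i) + r_cov(j) + tolerance.
    Hydrogens are folded into attached-H counts of their nearest bonded
    heavy atom.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    radii = np.array([_radius(e) for e in conformer.elements])
    xyz = conformer.coordinates
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    cutoff = radii[:, None] + radii[None, :] + tolerance
    heavy = [i for i, e in enumerate(conformer.elements) if e != "H"]
    hmap = {g: k for k, g in enumerate(heavy)}
    n_h = [0] * len(heavy)
    for i, e in enumerate(conformer.elements):
        if e != "H":
            continue
        partners = [j for j in heavy if d[i, j] <= cutoff[i, j]]
        if partners:
            nearest = min(partners, key=lambda j: d[i, j])
            n_h[hmap[nearest]] += 1
    bonds = []
    for a in range(len(heavy)):
        for b in range(a + 1, len(heavy)):
            i, j = heavy[a], heavy[b]
            if d[i, j] <= cutoff[i, j]:
                bonds.append((a, b, 0.0, False))
    atoms = [(conformer.elements[g], 0, False, n_h[k])
             for k, g in enumerate(heavy)]
    return Molecule(atoms=atoms, bonds=bonds, canonical_key=None)


def check_topology_consistency(
    molecule: Molecule, conformer: Conformer, tolerance: float = 0.4
) -> tuple[bool, dict]:
    """True iff the heavy-atom graph perceived from the conformer is
    element-labelled isomorphic to the molecule's graph (orders ignored)."""
    perceived = perceive_connectivity(conformer, tolerance)
    ref_elems = sorted(sym for sym, *_ in molecule.atoms)
    got_elems = sorted(sym for sym, *_ in perceived.atoms)
    if ref_elems != got_elems:
        raise TopologyError(
            f"element multiset mismatch: molecule {Counter(ref_elems)} vs "
            f"conformer {Counter(got_elems)}"
        )
    g_ref, g_per = molecule.graph(), perceived.graph()
    ok = nx.is_isomorphic(
        g_ref, g_per, node_match=lambda a, b: a["element"] == b["element"]
    )
    report: dict = {"consistent": ok, "missing_edges": [], "extra_edges": []}
    if not ok:
        # identity-mapping diff when atoms line up positionally, else counts
        same_order = [sym for sym, *_ in molecule.atoms] == [
            sym for sym, *_ in perceived.atoms
        ]
        if same_order:
            ref_e = {tuple(sorted(e)) for e in g_ref.edges}
            per_e = {tuple(sorted(e)) for e in g_per.edges}
            report["missing_edges"] = sorted(ref_e - per_e)
            report["extra_edges"] = sorted(per_e - ref_e)
        else:
            report["edge_count"] = (g_ref.number_of_edges(),
                                    g_per.number_of_edges())
    return ok, report


# --------------------------------------------------------------------------
# label loading and curation
# --------------------------------------------------------------------------

def load_labels(path) -> tuple[Dataset, list]:
    """Read the labels CSV into a Dataset (no conformers attached yet).

    Columns: chromophore_smiles, solvent_smiles, lambda_abs_nm,
    lambda_ems_nm, plqy.  Empty cells mean missing (mask 0).  Rows with
    invalid SMILES or PLQY outside (0, 1] are rejected with a report
    entry, not raised.
    """
    df = pd.read_csv(path)
    required = {"chromophore_smiles", "solvent_smiles",
                "lambda_abs_nm", "lambda_ems_nm", "plqy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"labels CSV missing columns: {sorted(missing)}")
    records, issues = [], []
    for idx, row in df.iterrows():
        try:
            chrom = parse_structure(str(row["chromophore_smiles"]))
            solv = parse_structure(str(row["solvent_smiles"]))
        except StructureParseError as e:
            issues.append((idx, f"invalid SMILES: {e}"))
            continue
        vals = np.full(N_TARGETS, np.nan)
        mask = np.zeros(N_TARGETS, dtype=bool)
        for k, col in enumerate(("lambda_abs_nm", "lambda_ems_nm")):
            v = row[col]
            if pd.notna(v) and str(v).strip() != "":
                vals[k], mask[k] = float(v), True
        p = row["plqy"]
        if pd.notna(p) and str(p).strip() != "":
            p = float(p)
            if not (0.0 < p <= 1.0):
                issues.append((idx, f"PLQY {p} outside (0, 1]"))
                continue
            vals[2], mask[2] = math.log10(p), True
        try:
            records.append(LabeledPair(chrom, solv, vals, mask,
                                       provenance=[f"csv_row={idx}"]))
        except ValueError as e:
            issues.append((idx, str(e)))
    return Dataset(records), issues


def _neutral_skeleton(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    try:
        mol = rdMolStandardize.Uncharger().uncharge(mol)
    except Exception:
        pass
    return Chem.MolToSmiles(mol)


@dataclass
class CurationRules:
    check_topology: bool = True
    topology_tolerance: float = 0.4
    # "reference": check the highest-fidelity conformer present (graph
    # consistency is a property of the optimized structure; coarser levels
    # are expected to be geometrically noisy). "all": check every level.
    topology_level: str = "reference"
    drop_duplicates: bool = True
    flag_conflicting_labels: bool = True
    flag_protonation_variants: bool = True


def _topology_targets(rec: "LabeledPair", level: str) -> list:
    tags = [t for t in rec.conformers if t != "REFINED"] or list(rec.conformers)
    if not tags:
        return []
    if level == "all":
        return tags
    best = max(tags, key=_FIDELITY_LEVELS.index)
    return [best]


def _targets_key(r: LabeledPair) -> tuple:
    return tuple(
        round(float(v), 6) if m else None for v, m in zip(r.targets, r.mask)
    )


def curate(dataset: Dataset,
           rules: CurationRules | None = None) -> tuple[Dataset, CurationReport]:
    """Apply automatable curation checks; problems reported, never raised."""
    rules = rules or CurationRules()
    report = CurationReport(inspected=len(dataset.records))
    kept: list[LabeledPair] = []

    for rec in dataset.records:
        bad = None
        if rules.check_topology:
            for tag in _topology_targets(rec, rules.topology_level):
                conf = rec.conformers[tag]
                try:
                    ok, _ = check_topology_consistency(
                        rec.chromophore, conf, rules.topology_tolerance)
                except (TopologyError, ValueError) as e:
                    ok, bad = False, f"topology ({tag}): {e}"
                if not ok:
                    bad = bad or f"topology mismatch at level {tag}"
                    break
        if bad:
            report.removed += 1
            report.per_rule[bad.split(":")[0].split(" at ")[0]] += 1
            report.flagged.append((rec.pair_key, bad))
        else:
            kept.append(rec)

    if rules.drop_duplicates:
        seen, dedup = set(), []
        for rec in kept:
            key = rec.pair_key + _targets_key(rec)
            if key in seen:
                report.removed += 1
                report.per_rule["duplicate"] += 1
            else:
                seen.add(key)
                dedup.append(rec)
        kept = dedup

    if rules.flag_conflicting_labels:
        by_pair: dict = {}
        for rec in kept:
            by_pair.setdefault(rec.pair_key, []).append(rec)
        for pair, recs in by_pair.items():
            if len(recs) > 1 and len({_targets_key(r) for r in recs}) > 1:
                for r in recs:
                    if "flag:conflicting_labels" not in r.provenance:
                        r.provenance.append("flag:conflicting_labels")
                        report.per_rule["conflicting_labels"] += 1
                        report.flagged.append((pair, "conflicting labels"))

    if rules.flag_protonation_variants:
        by_skel: dict = {}
        for rec in kept:
            skel = _neutral_skeleton(rec.chromophore.canonical_key)
            by_skel.setdefault(skel, set()).add(rec.chromophore.canonical_key)
        variant_skels = {s for s, keys in by_skel.items() if len(keys) > 1}
        for rec in kept:
            if _neutral_skeleton(rec.chromophore.canonical_key) in variant_skels:
                if "flag:protonation_variant" not in rec.provenance:
                    rec.provenance.append("flag:protonation_variant")
                    report.per_rule["protonation_variant"] += 1
                    report.flagged.append((rec.pair_key, "protonation variant"))

    report.retained = len(kept)
    report.validate()
    return Dataset(kept), report
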