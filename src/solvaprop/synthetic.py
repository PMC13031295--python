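"""Seeded toy chromophore-solvent datasets with known ground truth.

The generator emulates the statistical structure of a curated
solvatochromism benchmark — NOT the physics: conjugated chain molecules
(two terminal aromatic rings bridged by a polyene linker of L repeat
units, optionally ring-substituted), a closed-form surrogate target
model driven by conjugation length L, solvent polarity P and a backbone
dihedral twist θ, a multi-fidelity geometry-noise ladder over
conformers, and configurable missing-label patterns.

Surrogate target model (spec'd constants, configurable; nm where
dimensioned):

    λ_abs = λ0 + a·L + b·P − c·(1 − cos θ)
    λ_ems = λ_abs + s0 + s1·P
    PLQY  = 1 / (1 + exp(−(k0 − k1·(1 − cos θ))))

The fidelity ladder adds zero-mean Gaussian coordinate noise with
strictly decreasing σ along RDKIT → XTB → DFT_VAC → DFT_IMP; the
implicit-solvent level additionally relaxes the twist toward a
solvent-preferred value (fraction of the gap configurable), emulating
implicit-solvent geometry relaxation.  The descriptor θ that generates
the targets is the twist of the reference (implicit-solvent) geometry.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molecular_data import (Conformer, Dataset, LabeledPair, Molecule,
                             check_topology_consistency)

__all__ = [
    "FixtureSpec", "GroundTruth", "SOLVENT_TABLE", "RING_VARIANTS",
    "make_chromophore", "ground_truth_targets", "perturb_conformer",
    "make_fixture_dataset",
]

# solvent SMILES with an assigned polarity P in [0, 1] (evenly spread)
SOLVENT_TABLE = (
    ("CCCCCC", 0.0),        # hexane
    ("Cc1ccccc1", 1 / 7),   # toluene
    ("ClC(Cl)Cl", 2 / 7),   # chloroform
    ("C1CCOC1", 3 / 7),     # THF
    ("CC(C)=O", 4 / 7),     # acetone
    ("CCO", 5 / 7),         # ethanol
    ("CC#N", 6 / 7),        # acetonitrile
    ("CS(C)=O", 1.0),       # DMSO
)

# terminal ring variants: (name, ring element list, explicit-H map)
RING_VARIANTS = (
    ("benzene", ["C"] * 6, {}),
    ("thiophene", ["C", "C", "C", "S", "C"], {}),
    ("furan", ["C", "C", "C", "O", "C"], {}),
    ("pyrrole", ["C", "C", "C", "N", "C"], {3: 1}),
    ("pyridine", ["C", "C", "C", "N", "C", "C"], {}),
)

# single-atom ring-A substituents (donor / acceptor flags are descriptive)
SUBSTITUENTS = (None, "F", "Cl", "C", "O", "N")

_B_AR = 1.40      # aromatic C-C, Å
_B_SINGLE = 1.45  # conjugated single bond
_B_DOUBLE = 1.35  # conjugated double bond


@dataclass
class FixtureSpec:
    n_chromophores: int = 250
    L_range: tuple = (2, 5)
    solvents: tuple = SOLVENT_TABLE
    lambda0: float = 250.0
    a: float = 25.0
    b: float = 60.0
    c: float = 40.0
    s0: float = 20.0
    s1: float = 30.0
    k0: float = 2.0
    k1: float = 6.0
    sigma_y: float = 5.0            # label noise on wavelengths, nm
    sigma_plqy: float = 0.05        # label noise on log10 PLQY
    geometry_ladder: dict = field(default_factory=lambda: {
        "RDKIT": 0.30, "XTB": 0.15, "DFT_VAC": 0.05, "DFT_IMP": 0.02})
    missing_prob: dict = field(default_factory=lambda: {
        "lambda_abs_nm": 0.05, "lambda_ems_nm": 0.35, "log10_plqy": 0.50})
    twist_max_deg: float = 60.0
    imp_relax: float = 0.2          # fraction of twist gap closed at DFT_IMP
    seed: int = 0

    def __post_init__(self):
        if self.L_range[0] < 1:
            raise ValueError("minimal conjugation length is 1")
        if any(s < 0 for s in self.geometry_ladder.values()):
            raise ValueError("geometry noise must be non-negative")
        if any(not 0 <= p <= 1 for p in self.missing_prob.values()):
            raise ValueError("missing-label probabilities must be in [0, 1]")
        ladder = [self.geometry_ladder[t]
                  for t in ("RDKIT", "XTB", "DFT_VAC", "DFT_IMP")
                  if t in self.geometry_ladder]
        if any(x <= y for x, y in zip(ladder, ladder[1:])):
            raise ValueError(
                "geometry noise must strictly decrease along the ladder "
                "RDKIT -> XTB -> DFT_VAC -> DFT_IMP")

    @property
    def reference_fidelity(self) -> str:
        return min(self.geometry_ladder, key=self.geometry_ladder.get)


@dataclass
class GroundTruth:
    """Noiseless targets and the descriptors that generated them."""

    L: np.ndarray
    P: np.ndarray
    theta_deg: np.ndarray           # reference-geometry twist
    targets: np.ndarray             # (n, 3): λ_abs, λ_ems, log10 PLQY
    chromophore_index: np.ndarray
    spec_seed: int = 0


def ground_truth_targets(L: int, P: float, theta_deg: float,
                         spec: FixtureSpec):
    """Closed-form surrogate (λ_abs nm, λ_ems nm, PLQY in (0, 1])."""
    twist = 1.0 - math.cos(math.radians(theta_deg))
    lam_abs = spec.lambda0 + spec.a * L + spec.b * P - spec.c * twist
    lam_ems = lam_abs + spec.s0 + spec.s1 * P
    plqy = 1.0 / (1.0 + math.exp(-(spec.k0 - spec.k1 * twist)))
    return lam_abs, lam_ems, plqy


def _rot_about_axis(points, origin, axis, angle_rad):
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    return (points - origin) @ R.T + origin


def _ring_positions(n, attach_pos, direction):
    """Regular n-gon in the xy-plane, one vertex at attach_pos, ring body
    extending along `direction`.

    Five-membered rings use a longer side so that cross-ring diagonals
    involving the heteroatom stay clear of the covalent-radius
    perception cutoff even under ladder noise.
    """
    side = _B_AR if n >= 6 else 1.55
    R = side / (2 * math.sin(math.pi / n))
    center = attach_pos + R * direction
    phase = math.atan2(*(attach_pos - center)[[1, 0]])
    pts = []
    for k in range(n):
        ang = phase + 2 * math.pi * k / n
        pts.append(center + R * np.array([math.cos(ang), math.sin(ang), 0.0]))
    return np.array(pts), center


def make_chromophore(L: int, substituents=None, seed: int = 0,
                     theta_deg: float | None = None):
    """Build a toy conjugated chromophore and its idealized 3D geometry.

    ``substituents`` is a dict with keys ``terminal_ring`` (a name from
    RING_VARIANTS) and ``ring_a`` (pair of single-atom substituents or
    None at two ring-A positions).  The terminal ring is twisted out of
    plane by ``theta_deg`` (seeded uniform over [0, 60°] by default)
    about the linker bond.  Returns (Molecule, reference Conformer);
    the conformer carries the DFT_IMP tag and exact (noise-free)
    coordinates.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    subs = substituents or {}
    ring_name = subs.get("terminal_ring", "benzene")
    ring_elems, ring_h = dict(
        (n, (e, h)) for n, e, h in RING_VARIANTS)[ring_name]
    sub_a = subs.get("ring_a", (None, None))
    rng = np.random.default_rng(seed)
    if theta_deg is None:
        theta_deg = float(rng.uniform(0.0, 60.0))

    rw = Chem.RWMol()
    coords = []

    def add_atom(sym, aromatic=False, n_h=None):
        a = Chem.Atom(sym)
        a.SetIsAromatic(aromatic)
        if n_h is not None:
            a.SetNumExplicitHs(n_h)
        return rw.AddAtom(a)

    # ring A: benzene hexagon, attach vertex at the origin, body along -x
    ringA_pos, centerA = _ring_positions(6, np.zeros(3), np.array([-1.0, 0, 0]))
    ringA = [add_atom("C", aromatic=True) for _ in range(6)]
    coords.extend(ringA_pos)
    for k in range(6):
        rw.AddBond(ringA[k], ringA[(k + 1) % 6], Chem.BondType.AROMATIC)

    # polyene chain: 2L sp2 carbons, zig-zag along +x
    # zig-zag with 120° internal angles; the first bond bisects the ring
    # angle at the attachment vertex (directions alternate 0° / +60°)
    chain = []
    pos = np.zeros(3)
    for k in range(2 * L):
        ang = math.radians(0.0 if k % 2 == 0 else 60.0)
        length = _B_SINGLE if k % 2 == 0 else _B_DOUBLE
        pos = pos + length * np.array([math.cos(ang), math.sin(ang), 0.0])
        chain.append(add_atom("C"))
        coords.append(pos.copy())
    rw.AddBond(ringA[0], chain[0], Chem.BondType.SINGLE)
    for k in range(2 * L - 1):
        bt = Chem.BondType.DOUBLE if k % 2 == 0 else Chem.BondType.SINGLE
        rw.AddBond(chain[k], chain[k + 1], bt)

    # terminal ring B along the chain direction, then twist by theta
    ang = math.radians(0.0 if (2 * L) % 2 == 0 else 60.0)
    d = np.array([math.cos(ang), math.sin(ang), 0.0])
    attachB = pos + _B_SINGLE * d
    ringB_pos, _ = _ring_positions(len(ring_elems), attachB, d)
    ringB = [add_atom(e, aromatic=True, n_h=ring_h.get(i))
             for i, e in enumerate(ring_elems)]
    twisted = _rot_about_axis(ringB_pos, pos, attachB - pos,
                              math.radians(theta_deg))
    coords.extend(twisted)
    for k in range(len(ringB)):
        rw.AddBond(ringB[k], ringB[(k + 1) % len(ringB)],
                   Chem.BondType.AROMATIC)
    rw.AddBond(chain[-1], ringB[0], Chem.BondType.SINGLE)

    # inert single-atom substituents on ring A (scaffold-neutral diversity)
    for slot, vertex in zip(sub_a, (2, 4)):
        if slot is None:
            continue
        idx = add_atom(slot)
        out = ringA_pos[vertex] - centerA
        out = out / np.linalg.norm(out)
        coords.append(ringA_pos[vertex] + 1.40 * out)
        rw.AddBond(ringA[vertex], idx, Chem.BondType.SINGLE)

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    molecule = Molecule.from_rdkit(mol)
    conformer = Conformer(np.array(coords), [a.GetSymbol() for a in mol.GetAtoms()],
                          "DFT_IMP", source_id=molecule.canonical_key)
    ok, _ = check_topology_consistency(molecule, conformer)
    if not ok:  # constructive guarantee; violation means a geometry bug
        raise AssertionError("idealized geometry inconsistent with graph")
    return molecule, conformer


def perturb_conformer(conformer: Conformer, sigma_geo: float,
                      fidelity_tag: str, seed: int = 0) -> Conformer:
    """Add i.i.d. zero-mean Gaussian noise (std σ per coordinate), retag."""
    if sigma_geo < 0:
        raise ValueError("sigma_geo must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_geo, size=conformer.coordinates.shape) \
        if sigma_geo > 0 else 0.0
    return Conformer(conformer.coordinates + noise, list(conformer.elements),
                     fidelity_tag, source_id=conformer.source_id)


def _chromophore_recipes(spec: FixtureSpec, rng) -> list:
    variants = [v[0] for v in RING_VARIANTS]
    Ls = list(range(spec.L_range[0], spec.L_range[1] + 1))
    # ring-A substituent positions are symmetry-equivalent: unordered pairs
    sub_pairs = list(itertools.combinations_with_replacement(SUBSTITUENTS, 2))
    combos = [(v, L, s2, s4) for v, L in itertools.product(variants, Ls)
              for s2, s4 in sub_pairs]
    if spec.n_chromophores > len(combos):
        raise ValueError(
            f"at most {len(combos)} distinct chromophores available")
    order = rng.permutation(len(combos))
    return [combos[i] for i in order[:spec.n_chromophores]]


def make_fixture_dataset(spec: FixtureSpec) -> tuple[Dataset, GroundTruth]:
    """Sample a full synthetic dataset plus its regenerable ground truth.

    Every chromophore is paired with every solvent in the spec.  The
    reference (lowest-noise) conformer level carries the solvent-relaxed
    twist that also generates the targets; coarser levels corrupt the
    vacuum geometry with ladder noise.
    """
    rng = np.random.default_rng(spec.seed)
    recipes = _chromophore_recipes(spec, rng)
    thetas0 = rng.uniform(0.0, spec.twist_max_deg, size=len(recipes))
    records, gl, gp, gth, gtt, gci = [], [], [], [], [], []
    ref_tag = spec.reference_fidelity
    coarse_tags = [t for t in spec.geometry_ladder if t != ref_tag]
    for ci, ((ring, L, s2, s4), theta0) in enumerate(zip(recipes, thetas0)):
        subs = {"terminal_ring": ring, "ring_a": (s2, s4)}
        mol, base = make_chromophore(L, subs, theta_deg=float(theta0))
        for smiles, P in spec.solvents:
            solv = _parse_solvent(smiles)
            theta_ref = theta0 * (1.0 - spec.imp_relax * P)
            _, ref_clean = make_chromophore(L, subs, theta_deg=float(theta_ref))
            sub_seed = int(rng.integers(0, 2 ** 31))
            lam_abs, lam_ems, plqy = ground_truth_targets(
                L, P, theta_ref, spec)
            noise = np.random.default_rng(sub_seed).normal(
                0.0, [spec.sigma_y, spec.sigma_y, spec.sigma_plqy])
            labels = np.array([lam_abs + noise[0], lam_ems + noise[1],
                               min(math.log10(plqy) + noise[2], 0.0)])
            mask_rng = np.random.default_rng(sub_seed + 1)
            mask = np.array([
                mask_rng.random() >= spec.missing_prob[k]
                for k in ("lambda_abs_nm", "lambda_ems_nm", "log10_plqy")])
            rec = LabeledPair(mol, solv, labels, mask,
                              provenance=[f"fixture chrom={ci}"])
            rec.add_conformer(perturb_conformer(
                ref_clean, spec.geometry_ladder[ref_tag], ref_tag,
                seed=sub_seed + 2))
            for k, tag in enumerate(coarse_tags):
                rec.add_conformer(perturb_conformer(
                    base, spec.geometry_ladder[tag], tag,
                    seed=sub_seed + 3 + k))
            records.append(rec)
            gl.append(L)
            gp.append(P)
            gth.append(theta_ref)
            gtt.append([lam_abs, lam_ems, math.log10(plqy)])
            gci.append(ci)
    dataset = Dataset(records)
    truth = GroundTruth(np.array(gl), np.array(gp), np.array(gth),
                        np.array(gtt), np.array(gci), spec_seed=spec.seed)
    _check_scaffold_diversity(dataset)
    return dataset, truth


_SOLVENT_CACHE: dict = {}


def _parse_solvent(smiles: str) -> Molecule:
    if smiles not in _SOLVENT_CACHE:
        from .molecular_data import parse_structure
        _SOLVENT_CACHE[smiles] = parse_structure(smiles)
    return _SOLVENT_CACHE[smiles]


def _check_scaffold_diversity(dataset: Dataset, minimum: int = 3) -> None:
    from .scaffold_split import group_by_scaffold
    n = len(group_by_scaffold(dataset))
    if n < minimum:
        raise AssertionError(
            f"fixture has only {n} scaffolds; splits require >= {minimum}")
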