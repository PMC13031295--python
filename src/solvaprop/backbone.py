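"""SE(3)-invariant global-attention encoder over (molecule, conformer).

Scalar channels see geometry only through pairwise distances (Gaussian
radial basis expansion projected into per-head attention biases), so
they are invariant to rigid motions by construction.  A virtual node
(row 0) carries the molecule-level representation; it has no
coordinates and receives only learned pair biases to real atoms.  The
coordinate head emits per-atom displacements as sums of scalar pair
weights times unit inter-atomic vectors, which makes them
rotation-equivariant and translation-invariant, again by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .autodiff import Parameter, Tensor, concat
from .molecular_data import Conformer, Molecule, perceive_connectivity
from .solvent_encoder import ELEMENT_VOCAB

__all__ = [
    "PairFeatureSpec", "BackboneParams", "BackboneInput",
    "gaussian_pair_features", "featurize_3d", "backbone_forward",
    "backbone_forward_batch", "refine_coordinates", "kabsch_rmsd",
]

_N_SP_BUCKETS = 8  # 0=self, 1..6=shortest path length (capped), 7=disconnected


@dataclass
class PairFeatureSpec:
    """Gaussian radial basis over interatomic distances."""

    n_basis: int = 64
    r_max: float = 12.0
    sigma: float | None = None   # default: basis spacing

    def __post_init__(self):
        if self.n_basis < 1:
            raise ValueError("need at least one basis function")
        self.centers = np.linspace(0.0, self.r_max, self.n_basis)
        if self.sigma is None:
            self.sigma = self.r_max / max(self.n_basis - 1, 1)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def gaussian_pair_features(coordinates: np.ndarray,
                           spec: PairFeatureSpec) -> np.ndarray:
    """(N, N, K) array: exp(-(d_ij - mu_k)^2 / (2 sigma^2)), zero diagonal."""
    xyz = np.asarray(coordinates, dtype=float)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    g = np.exp(-((d[:, :, None] - spec.centers[None, None, :]) ** 2)
               / (2.0 * spec.sigma ** 2))
    idx = np.arange(len(xyz))
    g[idx, idx, :] = 0.0
    return g


def kabsch_rmsd(A: np.ndarray, B: np.ndarray):
    """Minimal RMSD over proper rigid superpositions of B onto A.

    Returns (rmsd, R, t) with the aligned coordinates given by B @ R + t.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must be equal-shape N×3 arrays")
    cA, cB = A.mean(axis=0), B.mean(axis=0)
    H = (B - cB).T @ (A - cA)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = cA - cB @ R
    aligned = B @ R + t
    rmsd = float(np.sqrt(np.mean(np.sum((A - aligned) ** 2, axis=-1))))
    return rmsd, R, t


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

def _init(rng, *shape, scale=None):
    s = scale if scale is not None else 1.0 / np.sqrt(shape[0])
    return Parameter(rng.uniform(-1, 1, size=shape) * s)


@dataclass
class BackboneParams:
    """Learnable state of the invariant attention backbone."""

    width: int
    n_layers: int
    n_heads: int
    pair_spec: PairFeatureSpec
    atom_embed: Tensor            # (n_elements + 1, width)
    vn_token: Tensor              # (width,) virtual-node embedding
    W_size: Tensor = None         # global size features -> virtual node
    layers: list = field(default_factory=list)
    Wc1: Tensor = None            # coordinate head (width, dc)
    Wc2: Tensor = None            # zero-initialized: zero displacement at init
    Wc3: Tensor = None            # distance-basis pair weights (spring-like)
    seed: int = 0
    explosion_threshold: float = 50.0

    @classmethod
    def create(cls, width: int = 128, n_layers: int = 4, n_heads: int = 8,
               pair_spec: PairFeatureSpec | None = None, seed: int = 0,
               ffn_mult: int = 2):
        if width % n_heads:
            raise ValueError("width must be divisible by n_heads")
        spec = pair_spec or PairFeatureSpec()
        rng = np.random.default_rng(seed)
        layers = []
        for _ in range(n_layers):
            layers.append({
                "Wq": _init(rng, width, width),
                "Wk": _init(rng, width, width),
                "Wv": _init(rng, width, width),
                "Wo": _init(rng, width, width),
                "Wf1": _init(rng, width, ffn_mult * width),
                "bf1": Parameter(np.zeros(ffn_mult * width)),
                "Wf2": _init(rng, ffn_mult * width, width),
                "bf2": Parameter(np.zeros(width)),
                "Wg": _init(rng, spec.n_basis, n_heads),
                "sp_bias": Parameter(np.zeros((_N_SP_BUCKETS, n_heads))),
                "vn_bias": Parameter(np.zeros(n_heads)),
            })
        dc = max(width // 2, 1)
        return cls(
            width=width, n_layers=n_layers, n_heads=n_heads, pair_spec=spec,
            atom_embed=_init(rng, len(ELEMENT_VOCAB) + 1, width, scale=0.5),
            vn_token=Parameter(rng.uniform(-0.5, 0.5, size=width)),
            W_size=_init(rng, 6, width),
            layers=layers,
            Wc1=_init(rng, width, dc),
            Wc2=Parameter(np.zeros((width, dc))),
            Wc3=Parameter(np.zeros(spec.n_basis)),
            seed=seed,
        )

    def parameters(self):
        ps = [self.atom_embed, self.vn_token, self.W_size, self.Wc1, self.Wc2,
              self.Wc3]
        for lay in self.layers:
            ps.extend(lay.values())
        return ps

    def set_frozen(self, flag: bool):
        for p in self.parameters():
            p.frozen = flag

    def snapshot(self):
        return [p.data.copy() for p in self.parameters()]


# --------------------------------------------------------------------------
# featurization
# --------------------------------------------------------------------------

def _sp_buckets(molecule: Molecule | None, conformer: Conformer) -> np.ndarray:
    """Shortest-path buckets on the bond graph (capped at 6)."""
    n = conformer.n_atoms
    if molecule is not None and molecule.n_atoms == n:
        g = molecule.graph()
    else:
        # explicit hydrogens or unknown graph: perceive from geometry
        g = perceive_connectivity(conformer).graph() if n > 1 else nx.Graph()
        if g.number_of_nodes() != n:
            g = nx.empty_graph(n)
    buckets = np.full((n, n), 7, dtype=np.intp)
    for i, dists in nx.all_pairs_shortest_path_length(g, cutoff=6):
        for j, d in dists.items():
            buckets[i, j] = min(d, 6)
    np.fill_diagonal(buckets, 0)
    return buckets


@dataclass
class BackboneInput:
    """Precomputed per-record geometric features (no gradients)."""

    elem_idx: np.ndarray    # (N,)
    sp: np.ndarray          # (N, N)
    gauss: np.ndarray       # (N, N, K)
    unit: np.ndarray        # (N, N, 3) unit vectors (r_i - r_j)/d_ij, 0 diag
    coords: np.ndarray      # (N, 3)


def featurize_3d(molecule: Molecule | None, conformer: Conformer,
                 spec: PairFeatureSpec) -> BackboneInput:
    elems = conformer.elements
    elem_idx = np.array(
        [ELEMENT_VOCAB.index(e) if e in ELEMENT_VOCAB else len(ELEMENT_VOCAB)
         for e in elems], dtype=np.intp)
    xyz = conformer.coordinates
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, :, None] > 1e-12, diff / np.maximum(d, 1e-12)[:, :, None], 0.0)
    return BackboneInput(
        elem_idx=elem_idx,
        sp=_sp_buckets(molecule, conformer),
        gauss=gaussian_pair_features(xyz, spec),
        unit=unit,
        coords=xyz.copy(),
    )


# --------------------------------------------------------------------------
# forward pass
# --------------------------------------------------------------------------

def _ones(shape):
    return Tensor(np.ones(shape))


def backbone_forward_batch(inputs: list, params: BackboneParams,
                           inject: Tensor | None = None,
                           compute_displacement: bool = True):
    """Run the backbone on a batch of equal-size records.

    inputs: list of BackboneInput with identical atom counts.
    inject: optional (B, width) tensor added to the virtual node before
    the first attention block (solvent injection).

    Returns (virtual-node embeddings (B, width), atom embeddings
    (B, N, width), displacements (B, N, 3)).
    """
    B = len(inputs)
    N = len(inputs[0].elem_idx)
    H, d = params.n_heads, params.width
    dh = d // H
    T = N + 1

    elem = np.stack([x.elem_idx for x in inputs])          # (B, N)
    gauss = np.stack([x.gauss for x in inputs])            # (B, N, N, K)
    sp = np.stack([x.sp for x in inputs])                  # (B, N, N)
    unit = np.stack([x.unit for x in inputs])              # (B, N, N, 3)

    atom0 = params.atom_embed.gather(elem.reshape(-1)).reshape(B, N, d)
    vn0 = _ones((B, 1, 1)) * params.vn_token.reshape(1, 1, d)
    # global invariant descriptors on the virtual token: attention pooling
    # is scale-normalized, so atom count, molecular extent and shape
    # anisotropy (gyration-tensor spectrum; its smallest eigenvalue is a
    # planarity measure) must enter explicitly
    coords_np = np.stack([x.coords for x in inputs])
    cen = coords_np - coords_np.mean(axis=1, keepdims=True)
    gyr = np.einsum("bni,bnj->bij", cen, cen) / N
    eig = np.sort(np.linalg.eigvalsh(gyr), axis=-1)[:, ::-1]  # desc
    mean_d = np.linalg.norm(
        coords_np[:, :, None, :] - coords_np[:, None, :, :], axis=-1
    ).sum(axis=(1, 2)) / max(N * (N - 1), 1)
    size_feat = np.column_stack([
        np.full(B, N / 10.0), np.full(B, np.log(N)),
        np.sqrt(eig.sum(axis=-1)) / 5.0, mean_d / 5.0,
        eig[:, 1], eig[:, 2]])
    vn0 = vn0 + (Tensor(size_feat) @ params.W_size).reshape(B, 1, d)
    if inject is not None:
        vn0 = vn0 + inject.reshape(B, 1, d)
    x = concat([vn0, atom0], axis=1)                       # (B, T, d)

    gauss_t = Tensor(gauss.reshape(B * N * N, -1))
    for li, lay in enumerate(params.layers):
        # pair bias: Gaussian-distance projection + graph (shortest-path) bias
        rr = (gauss_t @ lay["Wg"]).reshape(B, N, N, H)
        rr = rr + lay["sp_bias"].gather(sp.reshape(-1)).reshape(B, N, N, H)
        vrow = _ones((B, 1, N, 1)) * lay["vn_bias"].reshape(1, 1, 1, H)
        vcol = _ones((B, N, 1, 1)) * lay["vn_bias"].reshape(1, 1, 1, H)
        vself = Tensor(np.zeros((B, 1, 1, H)))
        top = concat([vself, vrow], axis=2)                # (B, 1, T, H)
        rest = concat([vcol, rr], axis=2)                  # (B, N, T, H)
        bias = concat([top, rest], axis=1).transpose(0, 3, 1, 2)  # (B,H,T,T)

        q = (x @ lay["Wq"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        k = (x @ lay["Wk"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        v = (x @ lay["Wv"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)) + bias
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        x = x + ctx @ lay["Wo"]
        x = x + ((x @ lay["Wf1"]) + lay["bf1"]).relu() @ lay["Wf2"] + lay["bf2"]
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError(f"non-finite activation in layer {li}")

    vn = x[:, 0, :]                                        # (B, d)
    atoms = x[:, 1:, :]                                    # (B, N, d)

    if not compute_displacement:
        return vn, atoms, Tensor(np.zeros((B, N, 3)))
    if N > 1:
        p = atoms @ params.Wc1                             # (B, N, dc)
        qc = atoms @ params.Wc2
        w = (p @ qc.transpose(0, 2, 1)) * (1.0 / N)        # (B, N, N)
        # direct distance-driven (spring-like) pair term; both terms are
        # zero-initialized so an untrained head moves nothing
        w = w + (gauss_t @ params.Wc3.reshape(-1, 1)).reshape(B, N, N)
        disp = (w.reshape(B, N, N, 1) * Tensor(unit)).sum(axis=2)
    else:
        disp = Tensor(np.zeros((B, N, 3)))
    return vn, atoms, disp


def backbone_forward(molecule: Molecule | None, conformer: Conformer,
                     params: BackboneParams,
                     inject: Tensor | None = None):
    """Single-record forward: (virtual-node embedding, atom embeddings,
    predicted coordinate displacement N×3)."""
    inp = featurize_3d(molecule, conformer, params.pair_spec)
    vn, atoms, disp = backbone_forward_batch(
        [inp], params, inject=None if inject is None else inject.reshape(1, -1))
    return vn[0], atoms[0], disp[0]


def refine_coordinates(molecule: Molecule | None, conformer: Conformer,
                       params: BackboneParams, iterations: int = 1) -> Conformer:
    """Iteratively add predicted displacements to the coordinates.

    Each iteration re-featurizes the updated geometry.  The result is
    tagged REFINED.  A displacement whose per-atom norm exceeds the
    explosion threshold raises (training-instability guard).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    current = conformer
    for _ in range(iterations):
        _, _, disp = backbone_forward(molecule, current, params)
        step = disp.data
        if np.max(np.linalg.norm(step, axis=-1)) > params.explosion_threshold:
            raise FloatingPointError("coordinate update exceeded explosion threshold")
        current = Conformer(current.coordinates + step, current.elements,
                            "REFINED", source_id=current.source_id)
    return current
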