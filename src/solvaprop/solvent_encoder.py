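"""Directed edge-message-passing (D-MPNN) encoder over 2D molecular graphs.

Edge states live on directed bonds; T update rounds combine each edge's
initial state with the sum of incoming edge states at its source atom,
excluding the reverse edge.  Atom states are read out from incoming edge
states and mean-pooled into a fixed-width molecule embedding.  A dual
chromophore/solvent encoder with a shared regression head forms the 2D
baseline; after pretraining, the solvent branch is frozen and reused as
a fixed source of solvent embeddings by the 3D models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concat
from .molecular_data import Dataset, Molecule

__all__ = [
    "ELEMENT_VOCAB", "ATOM_FDIM", "BOND_FDIM",
    "EncoderParams", "HeadParams", "GraphBatch", "PretrainConfig",
    "featurize_graph", "build_graph_batch", "encode_batch", "encode_2d",
    "dual_predict", "pretrain_solvent_encoder", "solvent_embeddings",
]

ELEMENT_VOCAB = ("H", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I")
_CHARGES = (-2, -1, 0, 1, 2)
_MAX_H = 4
ATOM_FDIM = len(ELEMENT_VOCAB) + 1 + len(_CHARGES) + 1 + (_MAX_H + 1)
BOND_FDIM = 5  # single / double / triple / other-order + aromatic flag


def featurize_graph(molecule: Molecule):
    """Atom feature matrix and directed bond feature list.

    Unseen elements fall into the OTHER bucket; both directions of every
    bond are emitted.
    """
    n = molecule.n_atoms
    X = np.zeros((n, ATOM_FDIM), dtype=np.float64)
    for i, (sym, charge, aromatic, num_h) in enumerate(molecule.atoms):
        e = ELEMENT_VOCAB.index(sym) if sym in ELEMENT_VOCAB else len(ELEMENT_VOCAB)
        X[i, e] = 1.0
        c = _CHARGES.index(charge) if charge in _CHARGES else _CHARGES.index(0)
        X[i, len(ELEMENT_VOCAB) + 1 + c] = 1.0
        X[i, len(ELEMENT_VOCAB) + 1 + len(_CHARGES)] = float(bool(aromatic))
        X[i, len(ELEMENT_VOCAB) + 2 + len(_CHARGES) + min(int(num_h), _MAX_H)] = 1.0
    src, dst, bf = [], [], []
    for (i, j, order, aromatic) in molecule.bonds:
        f = np.zeros(BOND_FDIM)
        idx = {1.0: 0, 2.0: 1, 3.0: 2}.get(float(order), 3)
        f[idx] = 1.0
        f[4] = float(bool(aromatic))
        for a, b in ((i, j), (j, i)):
            src.append(a)
            dst.append(b)
            bf.append(f)
    B = np.array(bf, dtype=np.float64).reshape(len(src), BOND_FDIM)
    return X, np.array(src, dtype=np.intp), np.array(dst, dtype=np.intp), B


@dataclass
class GraphBatch:
    """One disconnected graph holding a batch of molecules."""

    X: np.ndarray          # (N_atoms, ATOM_FDIM)
    src: np.ndarray        # (E,) directed-edge source atom
    dst: np.ndarray        # (E,) directed-edge target atom
    rev: np.ndarray        # (E,) index of the reverse edge
    B: np.ndarray          # (E, BOND_FDIM)
    mol_ids: np.ndarray    # (N_atoms,) molecule index per atom
    n_mols: int
    atom_counts: np.ndarray


def build_graph_batch(molecules: list) -> GraphBatch:
    Xs, srcs, dsts, Bs, mids = [], [], [], [], []
    offset = 0
    counts = []
    for m_i, mol in enumerate(molecules):
        X, src, dst, B = featurize_graph(mol)
        Xs.append(X)
        srcs.append(src + offset)
        dsts.append(dst + offset)
        Bs.append(B)
        mids.append(np.full(mol.n_atoms, m_i, dtype=np.intp))
        counts.append(mol.n_atoms)
        offset += mol.n_atoms
    E = sum(len(s) for s in srcs)
    rev = np.arange(E, dtype=np.intp)
    rev[0::2], rev[1::2] = rev[1::2].copy(), rev[0::2].copy()
    return GraphBatch(
        X=np.concatenate(Xs) if Xs else np.zeros((0, ATOM_FDIM)),
        src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
        dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
        rev=rev,
        B=np.concatenate(Bs) if Bs else np.zeros((0, BOND_FDIM)),
        mol_ids=np.concatenate(mids) if mids else np.zeros(0, dtype=np.intp),
        n_mols=len(molecules),
        atom_counts=np.array(counts, dtype=np.float64),
    )


def _init(rng, *shape):
    fan_in = shape[0]
    return Parameter(rng.uniform(-1, 1, size=shape) / np.sqrt(fan_in))


@dataclass
class EncoderParams:
    """Weights of one D-MPNN encoder (input, message, atom updates)."""

    width: int
    depth: int
    W_i: Tensor
    W_m: Tensor
    W_a: Tensor
    seed: int = 0
    frozen: bool = False
    cache: dict = field(default_factory=dict)

    @classmethod
    def create(cls, width: int = 128, depth: int = 3, seed: int = 0):
        if depth < 0 or width < 1:
            raise ValueError("depth must be >= 0 and width >= 1")
        rng = np.random.default_rng(seed)
        return cls(
            width=width, depth=depth,
            W_i=_init(rng, ATOM_FDIM + BOND_FDIM, width),
            W_m=_init(rng, width, width),
            W_a=_init(rng, ATOM_FDIM + width, width),
            seed=seed,
        )

    def parameters(self):
        return [self.W_i, self.W_m, self.W_a]

    def set_frozen(self, flag: bool):
        self.frozen = flag
        for p in self.parameters():
            p.frozen = flag
        if not flag:
            self.cache.clear()

    def snapshot(self):
        return [p.data.copy() for p in self.parameters()]


def encode_batch(batch: GraphBatch, params: EncoderParams,
                 return_atom_states: bool = False):
    """Molecule embeddings (n_mols, width) for one batched graph."""
    n_atoms = batch.X.shape[0]
    X = Tensor(batch.X)
    if len(batch.src):
        edge_in = concat([Tensor(batch.X[batch.src]), Tensor(batch.B)], axis=-1)
        h0 = (edge_in @ params.W_i).relu()
        h = h0
        for _ in range(params.depth):
            atom_msg = h.segment_sum(batch.dst, n_atoms)
            m = atom_msg.gather(batch.src) - h.gather(batch.rev)
            h = (h0 + m @ params.W_m).relu()
            if not np.all(np.isfinite(h.data)):
                raise FloatingPointError("non-finite activation in message round")
        incoming = h.segment_sum(batch.dst, n_atoms)
    else:
        incoming = Tensor(np.zeros((n_atoms, params.width)))
    a = (concat([X, incoming], axis=-1) @ params.W_a).relu()
    summed = a.segment_sum(batch.mol_ids, batch.n_mols)
    emb = summed * Tensor(1.0 / batch.atom_counts[:, None])
    return (emb, a) if return_atom_states else emb


def encode_2d(molecule: Molecule, params: EncoderParams) -> Tensor:
    """Fixed-width embedding of one molecule (mean over atom states)."""
    return encode_batch(build_graph_batch([molecule]), params)[0]


def solvent_embeddings(molecules: list, params: EncoderParams) -> Tensor:
    """Embeddings for a list of molecules, cached by canonical key when frozen."""
    if params.frozen:
        missing = [m for m in molecules
                   if m.canonical_key not in params.cache]
        if missing:
            uniq = {m.canonical_key: m for m in missing}
        else:
            uniq = {}
        if uniq:
            mols = list(uniq.values())
            embs = encode_batch(build_graph_batch(mols), params).data
            for m, e in zip(mols, embs):
                params.cache[m.canonical_key] = e
        return Tensor(np.stack([params.cache[m.canonical_key]
                                for m in molecules]))
    # unfrozen: differentiate through unique molecules, gather per record
    keys = [m.canonical_key for m in molecules]
    uniq_keys = list(dict.fromkeys(keys))
    by_key = {k: next(m for m in molecules if m.canonical_key == k)
              for k in uniq_keys}
    embs = encode_batch(build_graph_batch([by_key[k] for k in uniq_keys]), params)
    idx = np.array([uniq_keys.index(k) for k in keys], dtype=np.intp)
    return embs.gather(idx)


@dataclass
class HeadParams:
    """Feed-forward regression head: hidden rectifier layer + linear out."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    @classmethod
    def create(cls, in_dim: int, hidden: int, out_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        return cls(
            W1=_init(rng, in_dim, hidden),
            b1=Parameter(np.zeros(hidden)),
            W2=_init(rng, hidden, out_dim),
            b2=Parameter(np.zeros(out_dim)),
        )

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x: Tensor) -> Tensor:
        return ((x @ self.W1) + self.b1).relu() @ self.W2 + self.b2


def dual_predict(chromophore: Molecule, solvent: Molecule,
                 chrom_params: EncoderParams, solv_params: EncoderParams,
                 head: HeadParams) -> Tensor:
    """2D baseline: head(concat(chromophore embedding, solvent embedding))."""
    if chrom_params.width != solv_params.width:
        raise ValueError(
            f"encoder width mismatch: {chrom_params.width} vs {solv_params.width}")
    ec = encode_2d(chromophore, chrom_params)
    es = encode_2d(solvent, solv_params)
    return head.forward(concat([ec, es], axis=-1))


@dataclass
class PretrainConfig:
    width: int = 128
    depth: int = 3
    head_hidden: int = 128
    targets: tuple = ("lambda_abs_nm",)   # absorption-only by default
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0


def pretrain_solvent_encoder(dataset: Dataset, split, config: PretrainConfig):
    """Train the dual 2D model on TRAIN records; freeze the solvent branch.

    Only TRAIN records are touched (auditable via ``dataset.access_log``).
    Returns (solvent EncoderParams with frozen flag set, diagnostics dict
    with the chromophore branch, head, loss history and target stats).
    """
    from .molecular_data import TARGET_NAMES

    train_idx = split.indices("TRAIN")
    if not train_idx:
        raise ValueError("empty TRAIN subset")
    t_cols = [TARGET_NAMES.index(t) for t in config.targets]

    chrom_params = EncoderParams.create(config.width, config.depth,
                                        seed=config.seed)
    solv_params = EncoderParams.create(config.width, config.depth,
                                       seed=config.seed + 1)
    head = HeadParams.create(2 * config.width, config.head_hidden,
                             len(t_cols), seed=config.seed + 2)

    ys, ms = [], []
    for i in train_idx:
        t, m = dataset.get_targets(i)
        ys.append(t[t_cols])
        ms.append(m[t_cols])
    Y, M = np.array(ys), np.array(ms, dtype=bool)
    if not M.any():
        raise ValueError("no observed targets in TRAIN for pretraining")
    mu = np.nanmean(np.where(M, Y, np.nan), axis=0)
    sd = np.nanstd(np.where(M, Y, np.nan), axis=0)
    sd = np.where(sd > 1e-9, sd, 1.0)

    params = (chrom_params.parameters() + solv_params.parameters()
              + head.parameters())
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    history = []
    recs = [dataset.records[i] for i in train_idx]
    for epoch in range(config.epochs):
        order = rng.permutation(len(recs))
        total, nb = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            chroms = [recs[i].chromophore for i in sel]
            solvs = [recs[i].solvent for i in sel]
            yb = (Y[sel] - mu) / sd
            mb = M[sel]
            if not mb.any():
                continue
            ec = encode_batch(build_graph_batch(chroms), chrom_params)
            es = encode_batch(build_graph_batch(solvs), solv_params)
            pred = head.forward(concat([ec, es], axis=-1))
            diff = (pred - Tensor(np.where(mb, yb, 0.0))).abs() * Tensor(
                mb.astype(float))
            loss = diff.sum() * (1.0 / mb.sum())
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            nb += 1
        history.append(total / max(nb, 1))
    solv_params.set_frozen(True)
    return solv_params, {
        "chromophore_params": chrom_params,
        "head": head,
        "loss_history": history,
        "target_mean": mu,
        "target_std": sd,
        "target_columns": t_cols,
    }
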