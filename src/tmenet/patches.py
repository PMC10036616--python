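"""Patch extraction and patch embedding.

Cores are split into non-overlapping ``patch_size x patch_size x C`` tiles
(border remainders are discarded).  Two embedding routes are provided:

* :func:`handcrafted_embed` — a deterministic featureizer (per-channel mean
  and spread, pairwise channel correlations, gradient energy) capturing
  marker expression, colocalization, and coarse morphology.
* :class:`ContrastiveEncoder` — a small convolutional network trained with
  a normalized-temperature contrastive objective on two augmented views of
  each patch, producing learned embeddings of configurable width.

Both produce ``L x d`` matrices housed in a :class:`PatchSet` per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .io import MultiplexedCore

DEFAULT_PATCH_SIZE = 20
DEFAULT_EMBED_DIM = 256


@dataclass
class Patch:
    tensor: np.ndarray       # patch_size x patch_size x C
    row: int
    col: int
    core_id: str

    def __post_init__(self):
        if self.tensor.ndim != 3:
            raise ValueError("patch tensor must be (p, p, C)")


@dataclass
class PatchSet:
    """Per-patient embeddings aligned with patch grid coordinates."""

    patient_id: str
    embeddings: np.ndarray   # L x d
    coords: np.ndarray       # L x 3: (core index, row, col)
    core_ids: list           # core index -> core_id
    grid_shapes: list        # core index -> (rows, cols)

    def __post_init__(self):
        if len(self.embeddings) != len(self.coords):
            raise ValueError("embeddings and coords must align 1:1")

    @property
    def L(self) -> int:
        return len(self.embeddings)

    @property
    def d(self) -> int:
        return self.embeddings.shape[1]


def extract_patches(core: MultiplexedCore,
                    patch_size: int = DEFAULT_PATCH_SIZE) -> list:
    """Non-overlapping row-major tiling; incomplete border strips dropped."""
    h, w, _ = core.pixels.shape
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"core {core.core_id} ({h}x{w}) smaller than one "
            f"{patch_size}x{patch_size} patch")
    rows, cols = h // patch_size, w // patch_size
    out = []
    for r in range(rows):
        for c in range(cols):
            tile = core.pixels[r * patch_size:(r + 1) * patch_size,
                               c * patch_size:(c + 1) * patch_size, :]
            out.append(Patch(tensor=tile, row=r, col=c, core_id=core.core_id))
    return out


def patch_grid_shape(core: MultiplexedCore,
                     patch_size: int = DEFAULT_PATCH_SIZE) -> tuple:
    h, w, _ = core.pixels.shape
    return h // patch_size, w // patch_size


# ---------------------------------------------------------------------------
# Deterministic handcrafted features
# ---------------------------------------------------------------------------

def handcrafted_feature_count(C: int) -> int:
    """means + sds + pairwise correlations + gradient energies."""
    return 2 * C + C * (C - 1) // 2 + C


def handcrafted_embed(patches: list, d: int = DEFAULT_EMBED_DIM) -> np.ndarray:
    """Deterministic ``L x d`` features (zero-padded / truncated to ``d``).

    Per channel: mean and standard deviation; per channel pair: Pearson
    correlation of pixels (0 when either channel is constant); per channel:
    mean squared finite-difference gradient magnitude.  Identical patches
    map to identical vectors.
    """
    if not patches:
        return np.zeros((0, d))
    C = patches[0].tensor.shape[2]
    n_feat = handcrafted_feature_count(C)
    X = np.stack([p.tensor.reshape(-1, C).astype(np.float64) for p in patches])
    L = X.shape[0]
    means = X.mean(axis=1)                      # L x C
    sds = X.std(axis=1)                         # L x C
    Xc = X - means[:, None, :]
    cov = np.einsum("lpc,lpd->lcd", Xc, Xc) / X.shape[1]
    denom = sds[:, :, None] * sds[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    iu = np.triu_indices(C, k=1)
    corr_feats = corr[:, iu[0], iu[1]]          # L x C(C-1)/2
    tiles = np.stack([p.tensor.astype(np.float64) for p in patches])
    gy = np.diff(tiles, axis=1)
    gx = np.diff(tiles, axis=2)
    grad = (gy ** 2).mean(axis=(1, 2)) + (gx ** 2).mean(axis=(1, 2))
    feats = np.concatenate([means, sds, corr_feats, grad], axis=1)
    assert feats.shape == (L, n_feat)
    out = np.zeros((L, d))
    k = min(d, n_feat)
    out[:, :k] = feats[:, :k]
    return out


# ---------------------------------------------------------------------------
# Contrastive encoder
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Small convolutional encoder trained with an NT-Xent objective."""

    d: int = DEFAULT_EMBED_DIM
    widths: tuple = (16, 32)   # conv channel widths, stride 2 each
    epochs: int = 10           # scaled-down default; configurable upward
    batch_size: int = 80       # image crops per contrastive batch
    temperature: float = 0.1
    lr: float = 1e-3
    jitter: float = 0.2        # channel-intensity jitter amplitude
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch size must be >= 2")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


class ContrastiveEncoder:
    """Conv encoder ``(p, p, C) -> R^d`` with flip/rotation/jitter views."""

    def __init__(self, C: int, config: EncoderConfig):
        self.config = config
        self.C = C
        rng = np.random.default_rng(config.seed)
        self.params = []
        self.layers = []
        cin = C
        for cout in config.widths:
            w = ag.Tensor(rng.normal(0, np.sqrt(2.0 / (9 * cin)),
                                     size=(3, 3, cin, cout)),
                          requires_grad=True)
            b = ag.Tensor(np.zeros(cout), requires_grad=True)
            self.layers.append((w, b))
            self.params += [w, b]
            cin = cout
        self.w_out = ag.Tensor(rng.normal(0, np.sqrt(1.0 / cin),
                                          size=(cin, config.d)),
                               requires_grad=True)
        self.b_out = ag.Tensor(np.zeros(config.d), requires_grad=True)
        self.params += [self.w_out, self.b_out]

    # -- forward ---------------------------------------------------------
    def _forward(self, x: ag.Tensor) -> ag.Tensor:
        h = x
        for w, b in self.layers:
            h = ag.relu(ag.conv2d(h, w, b, stride=2))
        h = h.mean(axis=1).mean(axis=1)          # global average pool
        return h @ self.w_out + self.b_out

    def embed(self, patches: list) -> np.ndarray:
        """Deterministic inference embeddings for a list of patches."""
        if not patches:
            return np.zeros((0, self.config.d))
        x = np.stack([p.tensor.astype(np.float64) for p in patches])
        scale = max(x.max(), 1e-9)
        out = self._forward(ag.Tensor(x / scale))
        return out.data

    # -- training ----------------------------------------------------------
    def _augment(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = x.copy()
        for i in range(out.shape[0]):
            k = rng.integers(0, 4)
            out[i] = np.rot90(out[i], k=int(k), axes=(0, 1))
            if rng.random() < 0.5:
                out[i] = out[i][:, ::-1, :]
            if rng.random() < 0.5:
                out[i] = out[i][::-1, :, :]
        jit = 1.0 + self.config.jitter * rng.uniform(-1, 1,
                                                     size=(out.shape[0], 1, 1,
                                                           out.shape[3]))
        return out * jit

    @staticmethod
    def _normalize_rows(z: ag.Tensor) -> ag.Tensor:
        norm = (z * z).sum(axis=1, keepdims=True).pow(0.5) + 1e-8
        return z / norm

    def _nt_xent(self, za: ag.Tensor, zb: ag.Tensor):
        """NT-Xent over in-batch negatives; returns (loss, top-1 hits)."""
        tau = self.config.temperature
        za = self._normalize_rows(za)
        zb = self._normalize_rows(zb)
        sim = (za @ zb.T) * (1.0 / tau)          # B x B, diagonal = positives
        logp = ag.log_row_softmax(sim)
        b = sim.shape[0]
        eye = ag.Tensor(np.eye(b))
        loss = -(logp * eye).sum() * (1.0 / b)
        hits = int((np.argmax(sim.data, axis=1) == np.arange(b)).sum())
        return loss, hits

    def contrastive_accuracy(self, patches: list, seed: int = 0) -> float:
        """Fraction of patches whose augmented positive outranks all
        in-batch negatives, without touching the weights."""
        rng = np.random.default_rng(seed)
        x = np.stack([p.tensor.astype(np.float64) for p in patches])
        scale = max(x.max(), 1e-9)
        hits = total = 0
        bs = min(self.config.batch_size, len(patches))
        for lo in range(0, len(patches) - bs + 1, bs):
            xa = self._augment(x[lo:lo + bs], rng) / scale
            xb = self._augment(x[lo:lo + bs], rng) / scale
            za = self._forward(ag.Tensor(xa))
            zb = self._forward(ag.Tensor(xb))
            _, h = self._nt_xent(za, zb)
            hits += h
            total += bs
        return hits / max(total, 1)


def train_contrastive_encoder(patches: list, config: EncoderConfig):
    """Train the encoder; returns ``(encoder, history)``.

    ``history`` has per-epoch mean loss and contrastive accuracy (the
    fraction of in-batch positives ranked first).  Seeded and reproducible.
    """
    if len(patches) < 2 * config.batch_size:
        raise ValueError(
            f"need at least {2 * config.batch_size} patches to train, "
            f"got {len(patches)}")
    C = patches[0].tensor.shape[2]
    enc = ContrastiveEncoder(C, config)
    rng = np.random.default_rng(config.seed + 1)
    opt = ag.Adam(enc.params, lr=config.lr)
    x_all = np.stack([p.tensor.astype(np.float64) for p in patches])
    scale = max(x_all.max(), 1e-9)
    history = {"loss": [], "accuracy": []}
    n = len(patches)
    bs = config.batch_size
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, hits, total = [], 0, 0
        for lo in range(0, n - bs + 1, bs):
            idx = order[lo:lo + bs]
            xa = enc._augment(x_all[idx], rng) / scale
            xb = enc._augment(x_all[idx], rng) / scale
            za = enc._forward(ag.Tensor(xa))
            zb = enc._forward(ag.Tensor(xb))
            loss, h = enc._nt_xent(za, zb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            hits += h
            total += bs
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(hits / max(total, 1))
    return enc, history


def save_patchsets(patchsets: dict, directory, stats=None):
    """Persist per-patient embeddings (npz) + a JSON manifest."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": {}, "d": None}
    for pid, ps in patchsets.items():
        np.savez_compressed(directory / f"{pid}.npz",
                            embeddings=ps.embeddings, coords=ps.coords)
        manifest["patients"][pid] = {"core_ids": ps.core_ids,
                                     "grid_shapes": [list(s) for s
                                                     in ps.grid_shapes]}
        manifest["d"] = ps.d
    if stats is not None:
        mu, sd = stats
        np.savez_compressed(directory / "standardizer.npz", mu=mu, sd=sd)
        manifest["standardizer"] = "standardizer.npz"
    (directory / "patchsets.json").write_text(json.dumps(manifest, indent=1))


def load_patchsets(directory):
    """Inverse of :func:`save_patchsets`; returns ``(patchsets, stats)``."""
    import json
    from pathlib import Path

    directory = Path(directory)
    manifest = json.loads((directory / "patchsets.json").read_text())
    out = {}
    for pid, meta in manifest["patients"].items():
        with np.load(directory / f"{pid}.npz") as z:
            out[pid] = PatchSet(patient_id=pid, embeddings=z["embeddings"],
                                coords=z["coords"],
                                core_ids=list(meta["core_ids"]),
                                grid_shapes=[tuple(s) for s
                                             in meta["grid_shapes"]])
    stats = None
    if "standardizer" in manifest:
        with np.load(directory / manifest["standardizer"]) as z:
            stats = (z["mu"], z["sd"])
    return out, stats


def standardize_patchsets(patchsets: dict, fit_patients: list | None = None,
                          stats: tuple | None = None):
    """Z-score embedding columns in place; returns the (mean, sd) used.

    Statistics are computed over ``fit_patients`` (all patients when None),
    so a cross-validation fold can standardize with training-fold statistics
    only; alternatively pass frozen ``stats`` from a previous fit (the
    deployed-model convention).  Constant columns are left unscaled.
    """
    if stats is None:
        fit = fit_patients if fit_patients is not None else list(patchsets)
        stacked = np.concatenate([patchsets[p].embeddings for p in fit])
        mu = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu, sd = stats
    for ps in patchsets.values():
        ps.embeddings = (ps.embeddings - mu) / sd
    return mu, sd


# ---------------------------------------------------------------------------
# Cohort-level assembly
# ---------------------------------------------------------------------------

def build_patchsets(cores: list, table, *, patch_size: int = DEFAULT_PATCH_SIZE,
                    d: int = DEFAULT_EMBED_DIM, encoder=None,
                    restrict_patients: list | None = None) -> dict:
    """Embed every patient's cores into a :class:`PatchSet`.

    Uses ``encoder.embed`` when an encoder is given, otherwise the
    handcrafted featureizer.  With ``restrict_patients`` (fold-safe mode)
    only the listed patients are embedded.
    """
    by_id = {c.core_id: c for c in cores}
    out = {}
    for pid in table.patient_ids:
        if restrict_patients is not None and pid not in restrict_patients:
            continue
        embs, coords, cids, shapes = [], [], [], []
        for k, cid in enumerate(table.cores_of(pid)):
            core = by_id[cid]
            plist = extract_patches(core, patch_size)
            if encoder is not None:
                e = encoder.embed(plist)
                if e.shape[1] != d:
                    raise ValueError("encoder width does not match d")
            else:
                e = handcrafted_embed(plist, d=d)
            embs.append(e)
            coords.extend((k, p.row, p.col) for p in plist)
            cids.append(cid)
            shapes.append(patch_grid_shape(core, patch_size))
        out[pid] = PatchSet(patient_id=pid,
                            embeddings=np.concatenate(embs, axis=0),
                            coords=np.asarray(coords, dtype=int),
                            core_ids=cids, grid_shapes=shapes)
    return out
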