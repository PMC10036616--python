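"""The multilevel weakly supervised assignment network.

Patches are softly assigned to P local phenotypes (pointwise multilayer
perceptron with skip connections), to N cellular neighborhoods (K rounds of
trainable neighbor aggregation on the patch graph), and — via a coarsened
graph of neighborhoods — to A tissue areas.  Each assignment matrix is
row-stochastic.  A max-sum pooling step turns the assignments into a
patient enrichment vector (the abundance of every element), and a one-layer
perceptron on the L-normalized enrichment produces the two-class recurrence
probability.  Training is end-to-end with cross-entropy on patient labels
only; hard-max pooling uses the straight-through gradient convention.

Optional assignment regularizers (row-confidence and element-balance
entropies) are available as hooks and are off by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import autograd as ag
from .autograd import Tensor
from .graphs import PatchGraph, build_patch_graph
from .patches import PatchSet


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    The defaults (P=10 phenotypes, N=8 neighborhoods, A=4 areas, K=2 hops,
    hard-max pooling with softmax assignments) are the selected optimum of
    the architecture search on the endometrial cohort.
    """

    P: int = 10
    N: int = 8
    A: int = 4
    K: int = 2
    hidden: int = 64
    n_mlp_layers: int = 8
    dropout: float = 0.1
    lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 100
    patients_per_batch: int = 8
    seed: int = 0
    pooling: str = "hard-max"          # or "soft" (ablation)
    activation: str = "softmax"        # or "sigmoid" (row-renormalized)
    confidence_weight: float = 0.0     # hook: penalize high row entropy
    balance_weight: float = 0.0        # hook: penalize collapsed element usage
    warmstart_epochs: int = 0          # k-means pretraining of the phenotype head
    classifier_polish_steps: int = 0   # final convex refit of the classifier head

    def __post_init__(self):
        if min(self.P, self.N, self.A) < 1:
            raise ValueError("P, N, A must be >= 1")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.pooling not in ("hard-max", "soft"):
            raise ValueError("pooling must be 'hard-max' or 'soft'")
        if self.activation not in ("softmax", "sigmoid"):
            raise ValueError("activation must be 'softmax' or 'sigmoid'")


@dataclass
class AssignmentBundle:
    """Trained soft assignments for one patient."""

    S_P: np.ndarray        # L x P
    S_N: np.ndarray        # L x N
    S_A_neigh: np.ndarray  # N x A
    S_A_patch: np.ndarray  # L x A  (= S_N @ S_A_neigh)

    def validate(self, atol: float = 1e-5):
        for name in ("S_P", "S_N", "S_A_neigh", "S_A_patch"):
            m = getattr(self, name)
            if np.any(m < -atol) or np.any(m > 1 + atol):
                raise ValueError(f"{name} entries outside [0, 1]")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > atol):
                raise ValueError(f"{name} rows do not sum to 1")
        return self


@dataclass
class EnrichmentVector:
    """Per-patient element abundances from max-sum pooling."""

    phenotypes: np.ndarray     # R^P, raw abundances in [0, L]
    neighborhoods: np.ndarray  # R^N
    areas: np.ndarray          # R^A
    L: int

    @property
    def normalized(self) -> np.ndarray:
        """Concatenated [P, N, A] abundances divided by the patch count."""
        return np.concatenate([self.phenotypes, self.neighborhoods,
                               self.areas]) / self.L

    def feature_names(self) -> list:
        return ([f"P{i + 1}" for i in range(len(self.phenotypes))]
                + [f"N{i + 1}" for i in range(len(self.neighborhoods))]
                + [f"A{i + 1}" for i in range(len(self.areas))])


@dataclass
class PredictionResult:
    p_recurrence: float
    p_no_recurrence: float

    def __post_init__(self):
        if abs(self.p_recurrence + self.p_no_recurrence - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")

    @property
    def label(self) -> int:
        return int(self.p_recurrence >= self.p_no_recurrence)

    @property
    def confidence(self) -> float:
        return max(self.p_recurrence, self.p_no_recurrence)


@dataclass
class PatientDataset:
    """Aligned patch sets, graphs, and labels for a set of patients."""

    patchsets: dict   # patient_id -> PatchSet
    graphs: dict      # patient_id -> PatchGraph
    labels: dict      # patient_id -> 0/1

    @property
    def patient_ids(self) -> list:
        return list(self.patchsets)

    def subset(self, ids) -> "PatientDataset":
        ids = list(ids)
        return PatientDataset(
            patchsets={p: self.patchsets[p] for p in ids},
            graphs={p: self.graphs[p] for p in ids},
            labels={p: self.labels[p] for p in ids})


def assemble_dataset(patchsets: dict, table) -> PatientDataset:
    labels = dict(zip(table.frame["patient_id"],
                      table.frame["label"].astype(int)))
    graphs = {pid: build_patch_graph(ps) for pid, ps in patchsets.items()}
    return PatientDataset(patchsets=patchsets, graphs=graphs,
                          labels={p: labels[p] for p in patchsets})


# ---------------------------------------------------------------------------
# Pooling (public numpy op; the network mirrors it in autograd)
# ---------------------------------------------------------------------------

def max_sum_pool(S: np.ndarray, mode: str = "hard-max") -> np.ndarray:
    """Pool a row-stochastic ``L x E`` matrix into E abundances.

    ``hard-max``: zero all but each row's maximal entry (ties broken by the
    lowest element index), then column-sum.  ``soft``: plain column sum.
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("empty assignment matrix")
    if mode == "soft":
        return S.sum(axis=0)
    if mode != "hard-max":
        raise ValueError(f"unknown pooling mode {mode!r}")
    idx = np.argmax(S, axis=1)  # argmax takes the first maximum: lowest index
    mask = np.zeros_like(S)
    mask[np.arange(S.shape[0]), idx] = 1.0
    return (S * mask).sum(axis=0)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def _linear_init(rng, fan_in, fan_out):
    w = Tensor(rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)),
               requires_grad=True)
    b = Tensor(np.zeros(fan_out), requires_grad=True)
    return w, b


class MultilevelNet:
    """Three assignment heads, pooling, and a one-layer classifier."""

    def __init__(self, d: int, config: ModelConfig):
        self.config = config
        self.d = d
        rng = np.random.default_rng(config.seed)
        h = config.hidden
        self.params = []

        # phenotype head: 8-layer MLP with skip connections + assignment
        self.mlp = []
        fan = d
        for _ in range(config.n_mlp_layers):
            w, b = _linear_init(rng, fan, h)
            self.mlp.append((w, b))
            self.params += [w, b]
            fan = h
        self.w_p, self.b_p = _linear_init(rng, h, config.P)
        self.params += [self.w_p, self.b_p]

        # neighborhood head: K aggregation rounds + assignment
        self.gnn = []
        fan = d
        for _ in range(config.K):
            ws, bs = _linear_init(rng, fan, h)
            wn, _ = _linear_init(rng, fan, h)
            self.gnn.append((ws, wn, bs))
            self.params += [ws, wn, bs]
            fan = h
        n_in = d if config.K == 0 else h
        self.w_n, self.b_n = _linear_init(rng, n_in, config.N)
        self.params += [self.w_n, self.b_n]

        # area head: one aggregation round on the neighborhood graph
        ws, bs = _linear_init(rng, d, h)
        wn, _ = _linear_init(rng, d, h)
        self.area_agg = (ws, wn, bs)
        self.params += [ws, wn, bs]
        self.w_a, self.b_a = _linear_init(rng, h, config.A)
        self.params += [self.w_a, self.b_a]

        # classifier on [P, N, A] / L
        self.w_c, self.b_c = _linear_init(
            rng, config.P + config.N + config.A, 2)
        self.params += [self.w_c, self.b_c]

    # -- assignment activations ------------------------------------------
    def _assign_activation(self, logits: Tensor) -> Tensor:
        if self.config.activation == "softmax":
            return ag.row_softmax(logits)
        sig = Tensor(1.0) / ((-logits).exp() + 1.0)
        return sig / (sig.sum(axis=-1, keepdims=True) + 1e-12)

    # -- heads -------------------------------------------------------------
    def _phenotype_logits(self, E: Tensor, training, rng) -> Tensor:
        hcur = E
        for i, (w, b) in enumerate(self.mlp):
            z = ag.elu(hcur @ w + b)
            hcur = z if i == 0 else z + hcur  # skip connections once widths match
            if training and self.config.dropout > 0:
                hcur = ag.dropout(hcur, self.config.dropout, rng, training)
        return hcur @ self.w_p + self.b_p

    def phenotype_assign(self, embeddings: np.ndarray) -> np.ndarray:
        """Inference-time ``L x P`` phenotype assignment of raw embeddings."""
        embeddings = np.asarray(embeddings, dtype=float)
        if np.isnan(embeddings).any():
            raise ValueError("NaN in embeddings")
        logits = self._phenotype_logits(Tensor(embeddings), False, None)
        return self._assign_activation(logits).data

    def _neighborhood_assign(self, E: Tensor, A_norm, training, rng) -> Tensor:
        hcur = E
        for ws, wn, bs in self.gnn:
            hcur = ag.elu(hcur @ ws + ag.spmm(A_norm, hcur) @ wn + bs)
            if training and self.config.dropout > 0:
                hcur = ag.dropout(hcur, self.config.dropout, rng, training)
        return self._assign_activation(hcur @ self.w_n + self.b_n)

    def neighborhood_assign(self, embeddings: np.ndarray,
                            graph: PatchGraph) -> np.ndarray:
        """Inference-time ``L x N`` neighborhood assignment."""
        E = Tensor(np.asarray(embeddings, dtype=float))
        return self._neighborhood_assign(
            E, graph.normalized_adjacency(), False, None).data

    def _area_assign(self, S_N: Tensor, A_sparse, E: Tensor):
        # weight-normalized neighborhood features
        colsum = S_N.sum(axis=0).reshape(-1, 1) + 1e-8
        X_N = (S_N.T @ E) / colsum                       # N x d
        A_N = S_N.T @ ag.spmm(A_sparse, S_N)             # coarsened adjacency
        A_N_norm = A_N / (A_N.sum(axis=1, keepdims=True) + 1e-8)
        ws, wn, bs = self.area_agg
        H = ag.elu(X_N @ ws + (A_N_norm @ X_N) @ wn + bs)
        S_A_neigh = self._assign_activation(H @ self.w_a + self.b_a)
        S_A_patch = S_N @ S_A_neigh
        return S_A_neigh, S_A_patch

    def area_assign(self, S_N: np.ndarray, graph: PatchGraph,
                    embeddings: np.ndarray):
        """Inference-time neighborhood- and patch-level area assignments."""
        S_N_t = Tensor(np.asarray(S_N, dtype=float))
        if S_N_t.shape[0] != graph.L:
            raise ValueError("S_N rows must match graph nodes")
        E = Tensor(np.asarray(embeddings, dtype=float))
        sa_n, sa_p = self._area_assign(S_N_t, graph.adjacency, E)
        return sa_n.data, sa_p.data

    # -- full forward ------------------------------------------------------
    def _pool(self, S: Tensor) -> Tensor:
        if self.config.pooling == "hard-max":
            return ag.hard_max_rows(S).sum(axis=0)
        return S.sum(axis=0)

    def forward(self, patchset: PatchSet, graph: PatchGraph,
                training: bool = False, rng=None):
        E = Tensor(patchset.embeddings)
        L = patchset.L
        S_P = self._assign_activation(
            self._phenotype_logits(E, training, rng))
        S_N = self._neighborhood_assign(E, graph.normalized_adjacency(),
                                        training, rng)
        S_A_neigh, S_A_patch = self._area_assign(S_N, graph.adjacency, E)
        pooled = ag.concat([self._pool(S_P), self._pool(S_N),
                            self._pool(S_A_patch)], axis=0)
        z = pooled * (1.0 / L)
        logits = z.reshape(1, -1) @ self.w_c + self.b_c
        return {"S_P": S_P, "S_N": S_N, "S_A_neigh": S_A_neigh,
                "S_A_patch": S_A_patch, "pooled": pooled, "logits": logits}

    def predict(self, patchset: PatchSet, graph: PatchGraph):
        """Returns (PredictionResult, EnrichmentVector, AssignmentBundle)."""
        out = self.forward(patchset, graph, training=False)
        probs = ag.row_softmax(out["logits"]).data.ravel()
        pooled = out["pooled"].data
        P, N = self.config.P, self.config.N
        enrich = EnrichmentVector(phenotypes=pooled[:P],
                                  neighborhoods=pooled[P:P + N],
                                  areas=pooled[P + N:], L=patchset.L)
        bundle = AssignmentBundle(S_P=out["S_P"].data, S_N=out["S_N"].data,
                                  S_A_neigh=out["S_A_neigh"].data,
                                  S_A_patch=out["S_A_patch"].data)
        pred = PredictionResult(p_recurrence=float(probs[1]),
                                p_no_recurrence=float(probs[0]))
        return pred, enrich, bundle


    # -- persistence -------------------------------------------------------
    def save(self, path):
        """Checkpoint parameters + config as a compressed npz."""
        import json as _json

        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params)}
        cfg = _json.dumps({**self.config.__dict__})
        np.savez_compressed(path, _config=np.frombuffer(cfg.encode(),
                                                        dtype=np.uint8),
                            _d=np.array([self.d]), **arrays)

    @classmethod
    def load(cls, path) -> "MultilevelNet":
        import json as _json

        with np.load(path) as z:
            cfg = _json.loads(bytes(z["_config"]).decode())
            net = cls(int(z["_d"][0]), ModelConfig(**cfg))
            for i, p in enumerate(net.params):
                p.data = z[f"param_{i}"]
        return net


def classify(enrichment: EnrichmentVector, params) -> PredictionResult:
    """Affine map on the L-normalized enrichment, then a two-way softmax."""
    w, b = params
    z = enrichment.normalized
    if z.shape[0] != w.shape[0]:
        raise ValueError(
            f"enrichment length {z.shape[0]} != classifier input {w.shape[0]}")
    logits = z @ w + b
    logits = logits - logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return PredictionResult(p_recurrence=float(p[1]),
                            p_no_recurrence=float(p[0]))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _entropy_rows(S: Tensor) -> Tensor:
    return -(S * S.log(1e-12)).sum(axis=1).mean()


def _patient_loss(net: MultilevelNet, out: dict, label: int) -> Tensor:
    logp = ag.log_row_softmax(out["logits"])
    onehot = np.zeros((1, 2))
    onehot[0, label] = 1.0
    loss = -(logp * Tensor(onehot)).sum()
    cfg = net.config
    if cfg.confidence_weight > 0:
        conf = (_entropy_rows(out["S_P"]) + _entropy_rows(out["S_N"])
                + _entropy_rows(out["S_A_neigh"]))
        loss = loss + cfg.confidence_weight * conf
    if cfg.balance_weight > 0:
        bal = Tensor(0.0)
        for key, size in (("S_P", cfg.P), ("S_N", cfg.N),
                          ("S_A_patch", cfg.A)):
            m = out[key].mean(axis=0)
            bal = bal + (m * m.log(1e-12)).sum() + np.log(size)
        loss = loss + cfg.balance_weight * bal
    return loss


def evaluate_loss(net: MultilevelNet, dataset: PatientDataset) -> float:
    """Mean cross-entropy (plus active regularizers) without training."""
    total = 0.0
    for pid in dataset.patient_ids:
        out = net.forward(dataset.patchsets[pid], dataset.graphs[pid],
                          training=False)
        total += _patient_loss(net, out, dataset.labels[pid]).item()
    return total / len(dataset.patient_ids)


def _warmstart_phenotype_head(net: MultilevelNet, dataset: PatientDataset,
                              rng: np.random.Generator):
    """Pretrain the phenotype head on k-means pseudo-labels.

    Patient-level labels alone cannot identify the boundaries of elements
    that carry no class signal, so the phenotype head is optionally
    initialized to reproduce a k-means partition (k = P) of the training
    embeddings before joint end-to-end training refines it.
    """
    from sklearn.cluster import KMeans

    cfg = net.config
    E = np.concatenate([ps.embeddings for ps in dataset.patchsets.values()])
    cap = 100_000
    if len(E) > cap:
        E = E[rng.choice(len(E), size=cap, replace=False)]
    km = KMeans(n_clusters=cfg.P, n_init=4, random_state=cfg.seed).fit(E)
    onehot = np.eye(cfg.P)[km.labels_]
    head = [w for pair in net.mlp for w in pair] + [net.w_p, net.b_p]
    opt = ag.Adam(head, lr=1e-3)
    bs = 1024
    for _ in range(cfg.warmstart_epochs):
        order = rng.permutation(len(E))
        for lo in range(0, len(E), bs):
            idx = order[lo:lo + bs]
            logits = net._phenotype_logits(Tensor(E[idx]), False, None)
            logp = ag.log_row_softmax(logits)
            loss = -(logp * Tensor(onehot[idx])).sum() * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()


def train_model(dataset: PatientDataset, config: ModelConfig,
                validation: PatientDataset | None = None):
    """End-to-end training; returns ``(net, history)``.

    ``history`` is a dict of per-epoch train loss (and validation loss when
    a validation set is given).  Seeded runs reproduce final parameters.
    """
    labels = np.array([dataset.labels[p] for p in dataset.patient_ids])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    d = next(iter(dataset.patchsets.values())).d
    net = MultilevelNet(d, config)
    rng = np.random.default_rng(config.seed + 1)
    if config.warmstart_epochs > 0:
        _warmstart_phenotype_head(net, dataset, rng)
        # the pretrained phenotype head is fine-tuned at a reduced rate so
        # joint training refines rather than overwrites its partition
        head = {id(w) for pair in net.mlp for w in pair}
        head |= {id(net.w_p), id(net.b_p)}
        slow = [p for p in net.params if id(p) in head]
        fast = [p for p in net.params if id(p) not in head]
        opts = [ag.Adam(fast, lr=config.lr, weight_decay=config.weight_decay),
                ag.Adam(slow, lr=0.01 * config.lr,
                        weight_decay=config.weight_decay)]
    else:
        opts = [ag.Adam(net.params, lr=config.lr,
                        weight_decay=config.weight_decay)]

    class _MultiOpt:
        def zero_grad(self):
            for o in opts:
                o.zero_grad()

        def step(self):
            for o in opts:
                o.step()

    opt = _MultiOpt()
    ids = list(dataset.patient_ids)
    history = {"train_loss": []}
    if validation is not None:
        history["val_loss"] = []
    bs = max(1, config.patients_per_batch)
    for _epoch in range(config.epochs):
        order = rng.permutation(len(ids))
        epoch_losses = []
        for lo in range(0, len(ids), bs):
            batch = [ids[k] for k in order[lo:lo + bs]]
            opt.zero_grad()
            batch_loss = None
            for pid in batch:
                out = net.forward(dataset.patchsets[pid], dataset.graphs[pid],
                                  training=True, rng=rng)
                loss = _patient_loss(net, out, dataset.labels[pid])
                batch_loss = loss if batch_loss is None else batch_loss + loss
            batch_loss = batch_loss * (1.0 / len(batch))
            batch_loss.backward()
            opt.step()
            epoch_losses.append(batch_loss.item())
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if validation is not None:
            history["val_loss"].append(evaluate_loss(net, validation))
    if config.classifier_polish_steps > 0:
        _polish_classifier(net, dataset, config.classifier_polish_steps)
    return net, history


def _polish_classifier(net: MultilevelNet, dataset: PatientDataset,
                       steps: int):
    """Refit the one-layer classifier head on frozen enrichments.

    With assignments fixed, the head is a convex logistic problem; running
    it to convergence gives every trained model (e.g., every CV fold) a
    consistent probability calibration instead of whatever point the joint
    loop stopped at.  Uses the same cross-entropy and weight decay.
    """
    feats, ys = [], []
    for pid in dataset.patient_ids:
        out = net.forward(dataset.patchsets[pid], dataset.graphs[pid],
                          training=False)
        feats.append(out["pooled"].data / dataset.patchsets[pid].L)
        ys.append(dataset.labels[pid])
    X = Tensor(np.stack(feats))
    onehot = Tensor(np.eye(2)[np.asarray(ys)])
    opt = ag.Adam([net.w_c, net.b_c], lr=0.05,
                  weight_decay=net.config.weight_decay)
    for _ in range(steps):
        logp = ag.log_row_softmax(X @ net.w_c + net.b_c)
        loss = -(logp * onehot).sum() * (1.0 / len(ys))
        opt.zero_grad()
        loss.backward()
        opt.step()


# ---------------------------------------------------------------------------
# Hyperparameter search (random sampling + successive halving)
# ---------------------------------------------------------------------------

PUBLISHED_GRID = {
    "lr": [1e-2, 1e-3, 5e-3, 1e-4, 5e-4],
    "weight_decay": [1e-3, 1e-4, 5e-4, 1e-5, 5e-5, 1e-6],
    "K": [1, 2, 3],
    "hidden": [32, 64, 96, 128],
    "dropout": [0.01, 0.05, 0.1, 0.2, 0.3, 0.4],
    "P": [6, 9, 12, 15],
    "N": [7, 10, 13, 16],
    "A": [8, 11, 14, 17],
}


def grid_cardinality(grid: dict) -> int:
    return int(np.prod([len(v) for v in grid.values()]))


def hyperparameter_search(dataset: PatientDataset, grid: dict,
                          budget: int = 400, seed: int = 0,
                          base_config: ModelConfig | None = None,
                          val_fraction: float = 0.25,
                          min_epochs: int = 2, eta: int = 3):
    """Race up to ``budget`` sampled configs with successive halving.

    Each rung trains the surviving configs for ``eta`` times more epochs and
    keeps the best ``1/eta`` fraction by validation loss.  Returns
    ``(best_config, trials)`` where ``trials`` is a tidy DataFrame of every
    evaluated (config, rung, epochs, validation loss).
    """
    if not grid:
        raise ValueError("empty grid")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    card = grid_cardinality(grid)
    if budget > card:
        warnings.warn(f"budget {budget} exceeds grid size {card}; capped")
        budget = card
    rng = np.random.default_rng(seed)
    keys = sorted(grid)
    if card <= 100_000:
        all_combos = list(itertools.product(*(grid[k] for k in keys)))
        pick = rng.choice(len(all_combos), size=budget, replace=False)
        combos = [all_combos[i] for i in pick]
    else:
        seen, combos = set(), []
        while len(combos) < budget:
            combo = tuple(grid[k][rng.integers(len(grid[k]))] for k in keys)
            if combo not in seen:
                seen.add(combo)
                combos.append(combo)
    base = base_config or ModelConfig()

    # stratified validation split
    ids = np.array(dataset.patient_ids)
    labels = np.array([dataset.labels[p] for p in ids])
    val_ids = []
    for cls in np.unique(labels):
        cls_ids = ids[labels == cls]
        k = max(1, int(round(val_fraction * len(cls_ids))))
        val_ids += list(rng.choice(cls_ids, size=k, replace=False))
    train_ids = [p for p in ids if p not in set(val_ids)]
    train_ds, val_ds = dataset.subset(train_ids), dataset.subset(val_ids)

    candidates = [replace(base, seed=base.seed, **dict(zip(keys, c)))
                  for c in combos]
    rows = []
    epochs = min_epochs
    rung = 0
    while True:
        scored = []
        for cfg in candidates:
            run_cfg = replace(cfg, epochs=epochs)
            _, hist = train_model(train_ds, run_cfg, validation=val_ds)
            vl = hist["val_loss"][-1]
            if not np.isfinite(vl):
                vl = np.inf
            scored.append((vl, cfg))
            rows.append({**{k: getattr(cfg, k) for k in keys},
                         "rung": rung, "epochs": epochs, "val_loss": vl})
        scored.sort(key=lambda t: t[0])
        if len(scored) == 1:
            best = scored[0][1]
            break
        keep = max(1, len(scored) // eta)
        candidates = [cfg for _, cfg in scored[:keep]]
        epochs *= eta
        rung += 1
    trials = pd.DataFrame(rows)
    return best, trials
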