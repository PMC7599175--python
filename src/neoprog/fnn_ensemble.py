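"""Step 2: the cross-validated feed-forward-network voting ensemble.

Subjects that pass the zone screen are classified by single-hidden-layer
feed-forward networks (inputs = the inner low-LD characteristics, one hidden
layer, two softmax outputs giving class probabilities). The member set is
split into four label-stratified folds; for each choice of a held-out fold
("type" k) 100 networks are trained on the other three folds from
independent random initialisations, with the held-out fold used to pick the
best-validation epoch. Prediction is a two-level vote: within a type the 100
networks vote by majority, and the final call is "delayed" when at least
two of the four type votes say so.

All 100 networks of a type are trained simultaneously as one batched tensor
computation (full-batch gradient descent with momentum on a class-weighted
cross-entropy), which makes the 400-network ensemble cheap and exactly
reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ddcrz import INCOMPLETE, MEMBER, RelaxedZoneSet, zone_membership
from .ld_selection import SelectionResult
from .synthetic_cohort import CharacteristicDescriptor, CohortTable

DELAYED = "delayed"
NORMAL = "normal"
EXCLUDED = "excluded_incomplete"


@dataclass(frozen=True)
class FnnSpec:
    """Architecture and trainer settings shared by every network.

    ``n_hidden=None`` means one more hidden unit than inputs. Training is
    full-batch gradient descent with momentum on class-weighted
    cross-entropy; the weights kept are those of the epoch with the lowest
    validation-fold loss.
    """

    n_hidden: int | None = None
    activation: str = "logistic"  # or "tanh"
    max_epochs: int = 200
    learning_rate: float = 0.5
    momentum: float = 0.9
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.activation not in ("logistic", "tanh"):
            raise ValueError("activation must be 'logistic' or 'tanh'")
        if self.n_hidden is not None and self.n_hidden < 1:
            raise ValueError("n_hidden must be positive")


@dataclass
class _TypeModel:
    """The 100 trained networks of one fold-type, as stacked tensors."""

    W1: np.ndarray  # (K, d, h)
    b1: np.ndarray  # (K, h)
    W2: np.ndarray  # (K, h, 2)
    b2: np.ndarray  # (K, 2)
    mu: np.ndarray  # (d,) training-split standardisation mean
    sd: np.ndarray  # (d,)
    activation: str

    @property
    def n_nets(self) -> int:
        return self.W1.shape[0]

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (K, n, 2); rows sum to 1."""
        Xs = (np.atleast_2d(X) - self.mu) / self.sd
        Z1 = np.einsum("nd,kdh->knh", Xs, self.W1) + self.b1[:, None, :]
        H = _activate(Z1, self.activation)
        Z2 = np.einsum("knh,kho->kno", H, self.W2) + self.b2[:, None, :]
        return _softmax(Z2)


@dataclass(frozen=True)
class VoteRecord:
    """Two-level vote for one subject."""

    counts: tuple[int, ...]      # delayed-voting networks per type, 0..K
    type_votes: tuple[bool, ...]  # per-type majority outcome
    final_delayed: bool
    n_nets: int

    def __post_init__(self) -> None:
        assert all(0 <= c <= self.n_nets for c in self.counts)


@dataclass
class EnsemblePredictor:
    """4 fold-types x K networks with the two-level voting rule."""

    fold_assignment: dict[str, int]  # subject_id -> fold index 0..n_folds-1
    types: list[_TypeModel]
    inner_subset: tuple[CharacteristicDescriptor, ...]
    vote_threshold_final: int = 2
    nets_per_type: int = 100

    @property
    def n_folds(self) -> int:
        return len(self.types)


def _activate(Z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-Z))
    return np.tanh(Z)


def _activate_deriv(H: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return H * (1.0 - H)
    return 1.0 - H * H


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=-1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=-1, keepdims=True)


def tally_votes(counts: Sequence[int], n_nets: int,
                vote_threshold_final: int = 2) -> VoteRecord:
    """Apply the two voting rules to per-type delayed counts.

    A type votes "delayed" on a strict majority of its networks, with an
    exact 50/50 split resolved toward delayed (favouring sensitivity for the
    rare class). The final call is delayed when at least
    ``vote_threshold_final`` types vote delayed.
    """
    type_votes = tuple(2 * c >= n_nets for c in counts)
    final = sum(type_votes) >= vote_threshold_final
    return VoteRecord(counts=tuple(int(c) for c in counts),
                      type_votes=type_votes, final_delayed=final,
                      n_nets=n_nets)


def stratified_folds(labels: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Label-stratified fold indices: shuffle each class, deal round-robin."""
    folds = np.empty(len(labels), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def _feature_matrix(table: CohortTable,
                    chars: Sequence[CharacteristicDescriptor]) -> np.ndarray:
    X = np.column_stack([table.values(c) for c in chars])
    if not np.isfinite(X).all():
        raise ValueError("member table has missing inner-subset values; "
                         "incomplete subjects must be routed out at step 1")
    return X


def _train_type(X: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
                val_idx: np.ndarray, spec: FnnSpec, n_nets: int,
                rng: np.random.Generator) -> _TypeModel:
    """Train one fold-type's K networks jointly; keep best-validation weights."""
    d = X.shape[1]
    h = spec.n_hidden if spec.n_hidden is not None else d + 1
    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xtr = (X[train_idx] - mu) / sd
    Xv = (X[val_idx] - mu) / sd
    ytr, yv = y[train_idx], y[val_idx]
    Ytr = np.eye(2)[ytr]

    # delayed class re-weighted inversely to its prevalence in the split
    n_del = int(ytr.sum())
    n_norm = len(ytr) - n_del
    if n_del == 0:
        raise ValueError("a training split has no delayed members; use fewer "
                         "folds or more data")
    w_del = n_norm / n_del if n_norm > 0 else 1.0
    w = np.where(ytr == 1, w_del, 1.0)
    w = w / w.sum()
    wv = np.where(yv == 1, w_del, 1.0)
    wv = wv / wv.sum() if len(yv) else wv

    s = spec.init_scale
    W1 = rng.uniform(-s, s, size=(n_nets, d, h))
    b1 = rng.uniform(-s, s, size=(n_nets, h))
    W2 = rng.uniform(-s, s, size=(n_nets, h, 2))
    b2 = rng.uniform(-s, s, size=(n_nets, 2))
    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)

    best = {"W1": W1.copy(), "b1": b1.copy(), "W2": W2.copy(), "b2": b2.copy()}
    best_loss = np.full(n_nets, np.inf)
    lr, mom = spec.learning_rate, spec.momentum

    for _ in range(spec.max_epochs):
        Z1 = np.einsum("nd,kdh->knh", Xtr, W1) + b1[:, None, :]
        H = _activate(Z1, spec.activation)
        P = _softmax(np.einsum("knh,kho->kno", H, W2) + b2[:, None, :])

        G2 = (P - Ytr[None, :, :]) * w[None, :, None]
        dW2 = np.einsum("knh,kno->kho", H, G2)
        db2 = G2.sum(axis=1)
        dH = np.einsum("kno,kho->knh", G2, W2)
        dZ1 = dH * _activate_deriv(H, spec.activation)
        dW1 = np.einsum("nd,knh->kdh", Xtr, dZ1)
        db1 = dZ1.sum(axis=1)

        vW1 = mom * vW1 - lr * dW1; W1 = W1 + vW1
        vb1 = mom * vb1 - lr * db1; b1 = b1 + vb1
        vW2 = mom * vW2 - lr * dW2; W2 = W2 + vW2
        vb2 = mom * vb2 - lr * db2; b2 = b2 + vb2

        if len(yv):
            Z1v = np.einsum("nd,kdh->knh", Xv, W1) + b1[:, None, :]
            Hv = _activate(Z1v, spec.activation)
            Pv = _softmax(np.einsum("knh,kho->kno", Hv, W2) + b2[:, None, :])
            pv = np.clip(Pv[:, np.arange(len(yv)), yv], 1e-12, None)
            loss = -(wv[None, :] * np.log(pv)).sum(axis=1)
            improved = loss < best_loss
            if improved.any():
                best_loss = np.where(improved, loss, best_loss)
                for name, cur in (("W1", W1), ("b1", b1), ("W2", W2), ("b2", b2)):
                    best[name][improved] = cur[improved]

    if not len(yv):  # no validation fold: keep the final weights
        best = {"W1": W1, "b1": b1, "W2": W2, "b2": b2}
    return _TypeModel(W1=best["W1"], b1=best["b1"], W2=best["W2"],
                      b2=best["b2"], mu=mu, sd=sd, activation=spec.activation)


def train_ensemble(members: CohortTable, selection: SelectionResult,
                   spec: FnnSpec | None = None, seed: int = 0,
                   n_folds: int = 4, nets_per_type: int = 100,
                   vote_threshold_final: int = 2) -> EnsemblePredictor:
    """Train the 4 x ``nets_per_type`` ensemble on the zone-member table.

    ``members`` is the cohort restricted to step-1 members; they must be
    complete on the inner characteristic subset. Folds are stratified by
    label; type k's networks train on the three folds other than k with fold
    k as validation data. Deterministic under (spec, seed).
    """
    spec = spec or FnnSpec()
    labels = members.labels
    n_del = int(labels.sum())
    if len(members) < 2 * n_folds or n_del < n_folds:
        raise ValueError(
            f"need at least {2 * n_folds} members including {n_folds} delayed "
            f"to stratify {n_folds} folds; got {len(members)} members with "
            f"{n_del} delayed — use fewer folds or more data")
    ss = np.random.SeedSequence(seed)
    fold_rng_seed, *type_seeds = ss.spawn(1 + n_folds)
    folds = stratified_folds(labels, n_folds, np.random.default_rng(fold_rng_seed))
    if any((labels[folds == k] == 1).sum() == 0 for k in range(n_folds)):
        raise ValueError("a fold has no delayed members after stratification; "
                         "use fewer folds or more data")
    X = _feature_matrix(members, selection.inner_subset)
    types = []
    for k in range(n_folds):
        types.append(_train_type(
            X, labels, np.flatnonzero(folds != k), np.flatnonzero(folds == k),
            spec, nets_per_type, np.random.default_rng(type_seeds[k])))
    assignment = {sid: int(f) for sid, f in
                  zip(members.df["subject_id"], folds)}
    return EnsemblePredictor(fold_assignment=assignment, types=types,
                             inner_subset=tuple(selection.inner_subset),
                             vote_threshold_final=vote_threshold_final,
                             nets_per_type=nets_per_type)


def _subject_vector(subject_values: Mapping[CharacteristicDescriptor, float],
                    chars: Sequence[CharacteristicDescriptor]) -> np.ndarray:
    x = np.empty(len(chars))
    for j, char in enumerate(chars):
        v = subject_values.get(char)
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing input value for {char}; incomplete "
                             "subjects should be routed out at step 1")
        x[j] = float(v)
    return x


def predict(subject_values: Mapping[CharacteristicDescriptor, float],
            ensemble: EnsemblePredictor) -> VoteRecord:
    """Two-level vote for one subject with complete inner-subset values.

    A network votes delayed when its delayed-class probability is at least
    0.5 (an exact tie counts as delayed).
    """
    x = _subject_vector(subject_values, ensemble.inner_subset)
    counts = []
    for model in ensemble.types:
        p_del = model.probabilities(x[None, :])[:, 0, 1]
        counts.append(int((p_del >= 0.5).sum()))
    return tally_votes(counts, ensemble.nets_per_type,
                       ensemble.vote_threshold_final)


def predict_two_step(subject_values: Mapping[CharacteristicDescriptor, float],
                     zones: RelaxedZoneSet,
                     ensemble: EnsemblePredictor) -> str:
    """Full cascade: zone screen, then the ensemble for zone members."""
    status = zone_membership(subject_values, zones)
    if status == INCOMPLETE:
        return EXCLUDED
    if status != MEMBER:
        return NORMAL
    return DELAYED if predict(subject_values, ensemble).final_delayed else NORMAL


def out_of_fold_votes(members: CohortTable,
                      ensemble: EnsemblePredictor) -> dict[str, bool]:
    """Held-out prediction per member: only the type whose validation fold
    contains the subject votes (100-network majority)."""
    X = _feature_matrix(members, ensemble.inner_subset)
    out: dict[str, bool] = {}
    for i, sid in enumerate(members.df["subject_id"]):
        k = ensemble.fold_assignment[sid]
        p_del = ensemble.types[k].probabilities(X[i][None, :])[:, 0, 1]
        count = int((p_del >= 0.5).sum())
        out[sid] = 2 * count >= ensemble.nets_per_type
    return out


def ensemble_to_dict(ensemble: EnsemblePredictor) -> dict:
    """JSON-serialisable form (weights as nested lists)."""
    return {
        "inner_subset": [c.column for c in ensemble.inner_subset],
        "fold_assignment": ensemble.fold_assignment,
        "vote_threshold_final": ensemble.vote_threshold_final,
        "nets_per_type": ensemble.nets_per_type,
        "types": [
            {
                "activation": t.activation,
                "mu": t.mu.tolist(), "sd": t.sd.tolist(),
                "W1": t.W1.tolist(), "b1": t.b1.tolist(),
                "W2": t.W2.tolist(), "b2": t.b2.tolist(),
            }
            for t in ensemble.types
        ],
    }


def ensemble_from_dict(d: dict) -> EnsemblePredictor:
    types = [
        _TypeModel(W1=np.asarray(t["W1"]), b1=np.asarray(t["b1"]),
                   W2=np.asarray(t["W2"]), b2=np.asarray(t["b2"]),
                   mu=np.asarray(t["mu"]), sd=np.asarray(t["sd"]),
                   activation=t["activation"])
        for t in d["types"]
    ]
    return EnsemblePredictor(
        fold_assignment={k: int(v) for k, v in d["fold_assignment"].items()},
        types=types,
        inner_subset=tuple(CharacteristicDescriptor.from_column(c)
                           for c in d["inner_subset"]),
        vote_threshold_final=int(d["vote_threshold_final"]),
        nets_per_type=int(d["nets_per_type"]),
    )
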