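"""End-to-end training, evaluation, ablation and robustness harnesses.

The training protocol: Adam with cosine-annealed learning rate, weight
decay, label-stratified 80/10/10 pair splits, early stopping on the
validation pair loss with best-parameter restoration, and metrics
(accuracy / recall / F1 at threshold 0.5, rank-based ROC-AUC and
interpolated PR-AUC) averaged over several seeds.

Triplets for the contrastive and margin-ranking terms are mined from the
training pairs (positives = labelled interacting pairs; negatives sampled
uniformly from non-interacting partners), reseeded every epoch.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score,
                             f1_score, recall_score, roc_auc_score)
from sklearn.model_selection import train_test_split

from . import autodiff as ad
from .losses import LossWeights, TripletBatch
from .model import InteractionModel
from .similarity import (build_similarity_stack, context_comembership,
                         coprescription_probabilities, DrugFeatureSet,
                         unified_topology)
from .synthetic import SyntheticCohort

__all__ = [
    "TrainConfig", "MetricsReport", "TrainResult",
    "split_pairs", "train", "evaluate", "run_ablation",
    "attention_report", "reduced_data_harness", "summarize_metrics",
    "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = ("no_msi", "no_gbap", "no_cmrg")


@dataclass
class TrainConfig:
    """Training protocol configuration (defaults follow the reference
    protocol: Adam 1e-3, weight decay 1e-5, cosine annealing, batch 128,
    150 epochs, patience 15, 80/10/10 stratified splits, dropout 0.1,
    8 heads, hidden dim 256, 3 attention layers)."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    schedule: str = "cosine"
    batch_size: int | None = 128
    max_epochs: int = 150
    early_stop_patience: int = 15
    split: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    dropout: float = 0.1
    n_heads: int = 8
    hidden_dim: int = 256
    gnn_layers: int = 3
    top_k: int = 8
    knn_k: int = 10
    epsilon: float | None = None
    graph_refresh: int = 1
    sim_mode: str = "cosine"
    loss_weights: LossWeights = field(default_factory=LossWeights)
    pair_loss_weight: float = 1.0
    kernels: list | None = None
    pairs_per_step: int | None = None
    train_fraction: float = 1.0
    use_molecular_features: bool = False
    molecular_dim: int = 16
    drugwise_split: bool = False
    max_triplets: int = 4000
    disable_multimodal_fusion: bool = False
    disable_attention_propagation: bool = False
    disable_contrastive: bool = False

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not 0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must lie in (0, 1]")

    @staticmethod
    def small_synthetic(**overrides) -> "TrainConfig":
        """Compact preset sized for the ~200-drug synthetic cohorts used
        in the end-to-end experiments: hidden dim 32, 2 heads, 2 layers,
        full-batch updates, 40 epochs."""
        base = dict(hidden_dim=32, n_heads=2, gnn_layers=2, batch_size=None,
                    pairs_per_step=2048, max_triplets=2000,
                    learning_rate=3e-3, max_epochs=60, early_stop_patience=15)
        base.update(overrides)
        return TrainConfig(**base)


@dataclass
class MetricsReport:
    """Threshold-0.5 classification metrics plus ranking AUCs (AUCs are
    None when the evaluated set has a single class)."""

    accuracy: float
    recall: float
    f1: float
    roc_auc: float | None
    pr_auc: float | None
    n_pairs: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainResult:
    model: InteractionModel
    history: list                       # per-epoch dicts of loss components
    best_epoch: int
    metrics: MetricsReport              # on the held-out test pairs
    fusion_weights: np.ndarray
    splits: tuple                       # (train, val, test) pair arrays
    config: TrainConfig


# ---------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------

def split_pairs(pairs: np.ndarray, fractions=(0.8, 0.1, 0.1), seed: int = 0,
                drugwise: bool = False):
    """Label-stratified disjoint (train, val, test) pair splits.

    With ``drugwise=True`` whole drugs are held out instead: drugs are
    partitioned by the fractions and a pair joins a split only when both
    endpoints belong to it (cold-start regime; pairs crossing splits are
    dropped).
    """
    pairs = np.asarray(pairs, dtype=int)
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs to split")
    f_train, f_val, f_test = fractions
    if drugwise:
        drugs = np.unique(pairs[:, :2])
        rng = np.random.default_rng(seed)
        perm = rng.permutation(drugs)
        n = len(drugs)
        n_test = max(1, int(round(f_test * n)))
        n_val = max(1, int(round(f_val * n)))
        test_d = set(perm[:n_test].tolist())
        val_d = set(perm[n_test:n_test + n_val].tolist())
        train_d = set(perm[n_test + n_val:].tolist())

        def members(dset):
            m = np.array([a in dset and b in dset for a, b, _ in pairs])
            return pairs[m]

        out = (members(train_d), members(val_d), members(test_d))
    else:
        labels = pairs[:, 2]
        strat = labels if len(np.unique(labels)) > 1 else None
        rest, test = train_test_split(pairs, test_size=f_test,
                                      random_state=seed, stratify=strat)
        strat_rest = rest[:, 2] if strat is not None else None
        val_frac = f_val / (f_train + f_val)
        tr, val = train_test_split(rest, test_size=val_frac,
                                   random_state=seed, stratify=strat_rest)
        out = (tr, val, test)
    for name, part in zip(("train", "val", "test"), out):
        if len(part) and len(np.unique(part[:, 2])) < 2:
            warnings.warn(f"{name} split has a single class; AUCs will be "
                          "reported as missing")
    return out


# ---------------------------------------------------------------------
# triplet mining
# ---------------------------------------------------------------------

def _mine_triplets(train_pairs: np.ndarray, n_drugs: int,
                   rng: np.random.Generator, cap: int) -> TripletBatch:
    """Anchors/positives from labelled interacting pairs; negatives are
    uniform non-interacting partners of the anchor."""
    pos = train_pairs[train_pairs[:, 2] == 1]
    if len(pos) == 0:
        return TripletBatch(anchors=np.empty(0, int),
                            positives=np.empty(0, int),
                            negatives=np.empty(0, int))
    pos_set = {(int(a), int(b)) for a, b, _ in pos}
    pos_set |= {(b, a) for a, b in pos_set}
    if len(pos) > cap:
        pos = pos[rng.choice(len(pos), size=cap, replace=False)]
    anchors, positives, negatives = [], [], []
    for a, b, _ in pos:
        a, b = int(a), int(b)
        for _ in range(20):
            k = int(rng.integers(n_drugs))
            if k != a and k != b and (a, k) not in pos_set:
                anchors.append(a)
                positives.append(b)
                negatives.append(k)
                break
    return TripletBatch(anchors=np.array(anchors, int),
                        positives=np.array(positives, int),
                        negatives=np.array(negatives, int))


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

def _build_model(cohort: SyntheticCohort, config: TrainConfig,
                 molecular_toys=None) -> InteractionModel:
    features = cohort.feature_matrix
    slices = cohort.modality_slices
    if config.use_molecular_features and molecular_toys is not None:
        # structure-derived embeddings join as one extra modality block
        from .encoders import MolecularEncoderParams, encode_molecule
        mol_params = MolecularEncoderParams.initialize(
            d=config.molecular_dim, seed=config.seed)
        block = np.stack([encode_molecule(t, mol_params)
                          for t in molecular_toys])
        if block.shape[0] != cohort.n_drugs:
            raise ValueError("one molecular graph per drug required")
        slices = slices + [slice(features.shape[1],
                                 features.shape[1] + block.shape[1])]
        features = np.concatenate([features, block], axis=1)
    fs = DrugFeatureSet(features=features,
                        modality_slices=slices,
                        drug_ids=list(cohort.drug_ids))
    stack = build_similarity_stack(fs, kernels=config.kernels)
    context = context_comembership(cohort.context_labels)
    copre = coprescription_probabilities(cohort.coprescription_counts)
    topo = unified_topology(stack, context)
    class_labels = np.array([c[0] for c in cohort.context_labels], dtype=int)
    return InteractionModel(
        features=fs.features, modality_slices=fs.modality_slices,
        sim_matrices=stack.matrices, context=context, coprescription=copre,
        topology=topo, class_labels=class_labels,
        hidden_dim=config.hidden_dim, n_heads=config.n_heads,
        n_layers=config.gnn_layers, dropout=config.dropout,
        top_k=config.top_k, knn_k=config.knn_k, epsilon=config.epsilon,
        sim_mode=config.sim_mode, loss_weights=config.loss_weights,
        pair_loss_weight=config.pair_loss_weight, seed=config.seed,
        disable_multimodal_fusion=config.disable_multimodal_fusion,
        disable_attention_propagation=config.disable_attention_propagation,
        disable_contrastive=config.disable_contrastive)


def _val_loss(model: InteractionModel, val_pairs: np.ndarray) -> float:
    scores = model.predict_pairs(val_pairs[:, :2])
    y = val_pairs[:, 2].astype(float)
    s = np.clip(scores, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


def train(cohort: SyntheticCohort, config: TrainConfig | None = None,
          log=None, molecular_toys=None) -> TrainResult:
    """Train the joint model on a cohort and evaluate on held-out pairs.

    Early stopping restores the parameters of the best-validation epoch;
    the per-epoch ``history`` records every loss component.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    splits = split_pairs(cohort.pair_labels, config.split, config.seed,
                         drugwise=config.drugwise_split)
    train_pairs, val_pairs, test_pairs = splits
    if config.train_fraction < 1.0:
        keep = rng.choice(len(train_pairs),
                          size=max(1, int(round(config.train_fraction
                                                * len(train_pairs)))),
                          replace=False)
        train_pairs = train_pairs[np.sort(keep)]

    model = _build_model(cohort, config, molecular_toys=molecular_toys)
    opt = ad.Adam(model.trainable_params(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    history: list[dict] = []
    best = {"epoch": -1, "val": np.inf, "state": model.state_dict()}
    patience_left = config.early_stop_patience

    for epoch in range(config.max_epochs):
        if config.graph_refresh and epoch % config.graph_refresh == 0:
            model.refresh_graph()
        lr = (ad.cosine_lr(config.learning_rate, epoch, config.max_epochs)
              if config.schedule == "cosine" else config.learning_rate)
        epoch_rng = np.random.default_rng(rng.integers(2 ** 31))
        triplets = _mine_triplets(train_pairs, cohort.n_drugs, epoch_rng,
                                  config.max_triplets)
        rank_triplets = _mine_triplets(train_pairs, cohort.n_drugs,
                                       epoch_rng, config.max_triplets)
        order = epoch_rng.permutation(len(train_pairs))
        if config.batch_size is None and config.pairs_per_step:
            # one stochastic step per epoch on a pair subsample
            order = order[:config.pairs_per_step]
        bs = config.batch_size or len(order)
        comp_sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, len(order), bs):
            batch = train_pairs[order[start:start + bs]]
            opt.zero_grad()
            total, comps = model.objective(batch[:, :2], batch[:, 2],
                                           triplets, rank_triplets,
                                           rng=epoch_rng, train=True)
            total.backward()
            opt.step(lr=lr)
            model.invalidate_cache()
            for k, v in comps.items():
                comp_sums[k] = comp_sums.get(k, 0.0) + v
            n_batches += 1
        record = {k: v / n_batches for k, v in comp_sums.items()}
        record["epoch"] = epoch
        record["lr"] = lr
        record["val_loss"] = _val_loss(model, val_pairs)
        history.append(record)
        if log is not None:
            log(record)
        if record["val_loss"] < best["val"] - 1e-9:
            best = {"epoch": epoch, "val": record["val_loss"],
                    "state": model.state_dict()}
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model.load_state_dict(best["state"])
    metrics = evaluate(model, test_pairs)
    lam = model.fusion_weights()
    return TrainResult(model=model, history=history,
                       best_epoch=best["epoch"], metrics=metrics,
                       fusion_weights=np.array(ad.value(lam)),
                       splits=(train_pairs, val_pairs, test_pairs),
                       config=config)


# ---------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------

def evaluate(model_or_scores, pairs: np.ndarray) -> MetricsReport:
    """Metrics on labelled pairs; accepts a model or precomputed scores."""
    pairs = np.asarray(pairs)
    y = pairs[:, 2].astype(int)
    if isinstance(model_or_scores, InteractionModel):
        scores = model_or_scores.predict_pairs(pairs[:, :2].astype(int))
    else:
        scores = np.asarray(model_or_scores, dtype=float)
    pred = (scores >= 0.5).astype(int)
    single_class = len(np.unique(y)) < 2
    if single_class:
        warnings.warn("single-class pair set: AUCs reported as missing")
    return MetricsReport(
        accuracy=float(accuracy_score(y, pred)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        roc_auc=None if single_class else float(roc_auc_score(y, scores)),
        pr_auc=(None if single_class
                else float(average_precision_score(y, scores))),
        n_pairs=len(y))


def summarize_metrics(reports: list) -> dict:
    """Mean and standard deviation per metric over per-seed reports."""
    out = {}
    for key in ("accuracy", "recall", "f1", "roc_auc", "pr_auc"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if vals:
            out[key] = {"mean": float(np.mean(vals)),
                        "sd": float(np.std(vals)), "n": len(vals)}
    return out


# ---------------------------------------------------------------------
# ablation and robustness harnesses
# ---------------------------------------------------------------------

def run_ablation(cohort: SyntheticCohort, config: TrainConfig,
                 variant: str) -> TrainResult:
    """Train an ablated variant.

    ``no_msi``: fusion weights frozen uniform, cross-attention pair head
    replaced by plain concatenation.  ``no_gbap``: attention propagation
    replaced by plain mean aggregation.  ``no_cmrg``: contrastive weight
    and the distribution/ranking/entropy alignment weights set to zero.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: "
                         f"{', '.join(ABLATION_VARIANTS)}")
    if variant == "no_msi":
        cfg = replace(config, disable_multimodal_fusion=True)
    elif variant == "no_gbap":
        cfg = replace(config, disable_attention_propagation=True)
    else:
        lw = config.loss_weights
        a = list(lw.alignment)
        a[3] = a[4] = a[5] = 0.0
        cfg = replace(config, disable_contrastive=True,
                      loss_weights=replace(lw, alignment=tuple(a)))
    return train(cohort, cfg)


def reduced_data_harness(cohort, config: TrainConfig,
                         fractions=(1.0, 0.6, 0.4), seeds=(0, 1, 2, 3, 4)):
    """Mean test ROC-AUC when training on shrinking fractions of the
    training pairs (validation and test pairs unchanged).

    ``cohort`` may be a single cohort or a callable ``seed -> cohort``;
    the callable form keeps the per-seed cohorts identical across
    fractions so the comparison is paired.
    """
    results = {}
    for frac in fractions:
        aucs = []
        for seed in seeds:
            data = cohort(seed) if callable(cohort) else cohort
            cfg = replace(config, seed=seed, train_fraction=frac)
            res = train(data, cfg)
            if res.metrics.roc_auc is not None:
                aucs.append(res.metrics.roc_auc)
        results[frac] = float(np.mean(aucs))
    return results


def attention_report(model: InteractionModel, pair) -> dict:
    """Exportable attention maps for one drug pair.

    Returns per-layer inter-drug attention rows for both drugs (each row
    sums to 1 over the drug's neighbourhood) and the pair's cross-attention
    matrices over modality tokens (masked entries exactly 0).
    """
    i, j = int(pair[0]), int(pair[1])
    enc = model.encode(train=False)
    report = {"pair": (i, j), "layers": []}
    for k, alpha in enumerate(enc["state"].attention_maps):
        report["layers"].append({"layer": k,
                                 "row_i": np.array(alpha[i]),
                                 "row_j": np.array(alpha[j])})
    ti = model._modality_tokens(enc["z_mod"], np.array([i]))
    tj = model._modality_tokens(enc["z_mod"], np.array([j]))
    if not model.no_msi:
        from .encoders import cross_attention_pair, CrossAttentionParams
        cross = CrossAttentionParams(
            wq=[ad.value(w) for w in model.cross.wq],
            wk=[ad.value(w) for w in model.cross.wk],
            wv=[ad.value(w) for w in model.cross.wv])
        rep = cross_attention_pair(ad.value(ti)[0], ad.value(tj)[0],
                                   min(model.top_k, model.n_modalities),
                                   cross, drug_pair=(i, j))
        report["cross_attention_ij"] = rep.cross_attention_weights
        report["cross_attention_ji"] = rep.cross_attention_weights_ji
    return report
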