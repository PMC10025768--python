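"""Source-free model adaptation on target data.

Only the pre-trained model artifact and the target counts enter here: the
classifier heads stay frozen to preserve the source class structure, and the
encoder (plus, by default, the decoder through the reconstruction term) is
fine-tuned with

    L_t = L_recon + L_neighborhood

where the neighborhood term pushes each "known" target cell's prediction
toward the cached soft labels of its neighbors.  Neighbors are found by
cosine similarity against a gradient-free memory bank of current embeddings
(each cell deliberately includes itself - a self-regularization anchor), and
come in three tiers: bidirectional (mutual) neighbors at full weight,
unidirectional neighbors at weight alpha2, and extensional
(neighbor-of-neighbor) ones at weight alpha3.  Cells in the "unknown" group
are excluded from the affinity term so that genuinely novel cells are never
forced to agree with known-type neighbors.  Bank rows, per-cell E-scores and
the known/unknown partition refresh every mini-batch; the mixup threshold
delta refreshes once per epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor
from .io import PreprocessedData
from .likelihoods import bernoulli_nll, zinb_nll
from .novelty import (
    BimodalityResult,
    EScoreReport,
    Partition,
    detect_novelty,
    escore_report,
    mixup_threshold,
    partition,
)
from .train import SourceModel

UNKNOWN_LABEL = "unknown"


@dataclass
class MemoryBanks:
    """Gradient-free caches of current embeddings and soft predictions."""

    R: np.ndarray  # Nt x d embeddings
    S: np.ndarray  # Nt x K classifier soft labels
    S1: np.ndarray  # Nt x K auxiliary soft labels
    S2: np.ndarray
    e_scores: np.ndarray  # Nt


@dataclass
class NeighborSets:
    """Per-cell neighbor index sets: VM = V1 (mutual) + V2 (one-way);
    V3 holds deduplicated neighbors-of-neighbors outside VM."""

    VM: List[np.ndarray]
    V1: List[np.ndarray]
    V2: List[np.ndarray]
    V3: List[np.ndarray]
    M: int


@dataclass
class AdaptationConfig:
    M: int = 5
    alpha2: float = 0.1
    alpha3: float = 0.1
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-4
    seed: int = 0
    update_decoder: bool = True
    mixup_pairs: object = "auto"
    n_boot: int = 200

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.alpha2 < 0 or self.alpha3 < 0:
            raise ValueError("affinity weights must be non-negative")


@dataclass
class AnnotationResult:
    labels: List[str]
    probabilities: np.ndarray  # Nt x K
    class_names: List[str]
    partition: Partition
    escore_report: EScoreReport
    bimodality: BimodalityResult
    cell_ids: List[str] = field(default_factory=list)
    delta_trajectory: List[Optional[float]] = field(default_factory=list)
    training_log: List[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        n = len(self.labels)
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids or [f"cell_{i:05d}" for i in range(n)],
                "predicted_label": self.labels,
                "e_score": self.escore_report.e_score,
                "partition": [
                    "unknown" if i in set(self.partition.unknown_idx.tolist()) else "known"
                    for i in range(n)
                ],
            }
        )
        for k, name in enumerate(self.class_names):
            df[f"p_{name}"] = self.probabilities[:, k]
        return df

    def run_report(self) -> dict:
        return {
            "bimodality": self.bimodality.to_dict(),
            "delta_trajectory": self.delta_trajectory,
            "n_known": int(len(self.partition.known_idx)),
            "n_unknown": int(len(self.partition.unknown_idx)),
            "training_log": self.training_log,
        }


# ---------------------------------------------------------------------------
# banks and neighbors


def _forward_numpy(model: SourceModel, x_input: np.ndarray, batch: int = 512):
    """Batched inference pass: embeddings and the three softmax outputs."""
    zs, ps, p1s, p2s = [], [], [], []
    for start in range(0, x_input.shape[0], batch):
        z = model.embed(x_input[start : start + batch])
        p, p1, p2 = model.net.predict_probs(z)
        zs.append(z)
        ps.append(p)
        p1s.append(p1)
        p2s.append(p2)
    return (np.vstack(zs), np.vstack(ps), np.vstack(p1s), np.vstack(p2s))


def init_banks(model: SourceModel, target: PreprocessedData) -> MemoryBanks:
    """Fill the representation and soft-label banks with one full forward pass."""
    _check_aligned(model, target)
    z, p, p1, p2 = _forward_numpy(model, target.x_input)
    rep = escore_report(p, p1, p2, model.n_classes)
    return MemoryBanks(R=z, S=p, S1=p1, S2=p2, e_scores=rep.e_score)


def _check_aligned(model: SourceModel, target: PreprocessedData):
    if list(target.gene_names) != list(model.gene_names):
        raise ValueError("target genes are not aligned to the model gene list; run align_genes")


def cosine_knn(R: np.ndarray, query_idx, M: int) -> List[np.ndarray]:
    """Indices of the M most cosine-similar bank rows per query (self included).

    Ties break toward the lower index; zero-norm rows get similarity 0.
    """
    R = np.asarray(R, dtype=np.float64)
    nt = R.shape[0]
    if M > nt:
        raise ValueError("M cannot exceed the bank size")
    query_idx = np.asarray(list(query_idx), dtype=int)
    norms = np.linalg.norm(R, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm embeddings; their similarity is 0", stacklevel=2)
    safe = np.where(zero, 1.0, norms)
    Rn = R / safe[:, None]
    sims = Rn[query_idx] @ Rn.T
    sims[:, zero] = 0.0
    sims[zero[query_idx], :] = 0.0
    # self always ranks first (self-similarity is 1, and ties with other
    # cells at similarity 1 must not evict the cell itself)
    sims[np.arange(len(query_idx)), query_idx] = 2.0
    order = np.argsort(-sims, axis=1, kind="stable")  # stable => lowest index wins ties
    return [order[r, :M].copy() for r in range(len(query_idx))]


def split_neighbors(VM: Sequence[np.ndarray]) -> NeighborSets:
    """Partition VM into mutual (V1) and one-way (V2) sets and collect the
    deduplicated neighbors-of-neighbors (V3) outside VM."""
    nt = len(VM)
    vm_sets = [set(v.tolist()) for v in VM]
    V1, V2, V3 = [], [], []
    for i in range(nt):
        v1 = {j for j in vm_sets[i] if i in vm_sets[j]}
        v2 = vm_sets[i] - v1
        v3 = set()
        for j in vm_sets[i]:
            v3 |= vm_sets[j]
        v3 -= vm_sets[i]
        V1.append(np.array(sorted(v1), dtype=int))
        V2.append(np.array(sorted(v2), dtype=int))
        V3.append(np.array(sorted(v3), dtype=int))
    M = len(VM[0]) if nt else 0
    return NeighborSets(
        VM=[np.asarray(v, dtype=int) for v in VM], V1=V1, V2=V2, V3=V3, M=M
    )


def affinity_loss(
    batch_idx,
    p: Tensor,
    nbrs: NeighborSets,
    S: np.ndarray,
    part: Partition,
    alpha2: float = 0.1,
    alpha3: float = 0.1,
) -> Tensor:
    """Multi-order neighborhood affinity loss on the 'known' cells of a batch.

    For each batch cell i in D, the cached soft labels of its neighbors in D
    are aggregated (mutual at weight 1, one-way at alpha2, extensional at
    alpha3) and dotted with the live prediction p_i; the result is averaged
    over ``|D|`` (the global known count) and negated.  Bank rows are
    constants: no gradient flows through S, and cells outside D contribute
    nothing.
    """
    batch_idx = np.asarray(list(batch_idx), dtype=int)
    known = set(part.known_idx.tolist())
    n_known = len(known)
    if n_known == 0:
        warnings.warn("empty 'known' set; affinity loss is 0", stacklevel=2)
        return Tensor(0.0)
    W = np.zeros((len(batch_idx), S.shape[1]))
    for r, i in enumerate(batch_idx):
        if i not in known:
            continue
        for idx_set, w in ((nbrs.V1[i], 1.0), (nbrs.V2[i], alpha2), (nbrs.V3[i], alpha3)):
            keep = [j for j in idx_set if j in known]
            if keep:
                W[r] += w * S[keep].sum(axis=0)
    return -(Tensor(W) * p).sum() * (1.0 / n_known)


# ---------------------------------------------------------------------------
# the adaptation loop


def _recon(model: SourceModel, xb, raw, sfb):
    if model.likelihood == "zinb":
        z, params = model.net.forward(xb, size_factors=sfb)
        return z, zinb_nll(raw, params)
    z, params = model.net.forward(xb)
    return z, bernoulli_nll(raw, params)


def _refresh_rows(model: SourceModel, banks: MemoryBanks, idx: np.ndarray, z: np.ndarray):
    p, p1, p2 = model.net.predict_probs(z)
    banks.R[idx] = z
    banks.S[idx] = p
    banks.S1[idx] = p1
    banks.S2[idx] = p2
    rep = escore_report(p, p1, p2, model.n_classes)
    banks.e_scores[idx] = rep.e_score


def _result_from_banks(
    model: SourceModel,
    banks: MemoryBanks,
    part: Partition,
    bim: BimodalityResult,
    cell_ids,
    delta_traj,
    log,
) -> AnnotationResult:
    rep = escore_report(banks.S, banks.S1, banks.S2, model.n_classes)
    unknown = set(part.unknown_idx.tolist())
    labels = [
        UNKNOWN_LABEL if i in unknown else model.class_names[int(np.argmax(banks.S[i]))]
        for i in range(banks.S.shape[0])
    ]
    return AnnotationResult(
        labels=labels,
        probabilities=banks.S.copy(),
        class_names=list(model.class_names),
        partition=part,
        escore_report=rep,
        bimodality=bim,
        cell_ids=list(cell_ids),
        delta_trajectory=list(delta_traj),
        training_log=list(log),
    )


def _heads_fn(model: SourceModel):
    return lambda z: model.net.predict_probs(z)


def annotate(
    model: SourceModel, target: PreprocessedData, config: Optional[AdaptationConfig] = None
) -> AnnotationResult:
    """Inference-only annotation: no weight updates."""
    config = config or AdaptationConfig()
    banks = init_banks(model, target)
    bim = detect_novelty(banks.e_scores, n_boot=config.n_boot, seed=config.seed)
    delta = None
    if bim.novel_detected:
        delta = mixup_threshold(
            banks.R, _heads_fn(model), n_pairs=config.mixup_pairs, seed=config.seed
        )
    part = partition(banks.e_scores, delta, bim.novel_detected)
    if bim.novel_detected and len(part.unknown_idx) == 0:
        warnings.warn("novelty detected but no cell fell below delta; closed behavior", stacklevel=2)
    return _result_from_banks(
        model, banks, part, bim, target.cell_ids, [delta], []
    )


def adapt(
    model: SourceModel, target: PreprocessedData, config: Optional[AdaptationConfig] = None
) -> AnnotationResult:
    """Fine-tune the encoder on target data under the affinity + count losses.

    Novelty is decided once on the initial E-scores; delta refreshes per
    epoch; banks, per-cell E-scores, and the known/unknown partition refresh
    every mini-batch for the cells of that batch.
    """
    config = config or AdaptationConfig()
    banks = init_banks(model, target)
    bim = detect_novelty(banks.e_scores, n_boot=config.n_boot, seed=config.seed)
    heads = _heads_fn(model)

    params = list(model.net.encoder_params)
    if config.update_decoder:
        params += model.net.decoder_params
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    nt = target.x_input.shape[0]

    delta_traj: List[Optional[float]] = []
    log: List[dict] = []
    delta: Optional[float] = None
    part = partition(banks.e_scores, None, False)

    for epoch in range(config.epochs):
        if bim.novel_detected:
            delta = mixup_threshold(
                banks.R, heads, n_pairs=config.mixup_pairs, seed=config.seed * 1000 + epoch
            )
        delta_traj.append(delta)
        part = partition(banks.e_scores, delta, bim.novel_detected)

        order = rng.permutation(nt)
        ep = dict(recon=0.0, nbh=0.0, n=0)
        for start in range(0, nt, config.batch_size):
            idx = order[start : start + config.batch_size]
            z, recon = _recon(
                model, target.x_input[idx], target.raw_counts[idx], target.size_factors[idx]
            )
            # gradient-free bank refresh for this batch, then partition update
            _refresh_rows(model, banks, idx, z.data.copy())
            part = partition(banks.e_scores, delta, bim.novel_detected)
            vm = cosine_knn(banks.R, range(nt), config.M)
            nbrs = split_neighbors(vm)
            lp, _, _ = model.net.class_logprobs(z)
            p = lp.exp()
            nbh = affinity_loss(idx, p, nbrs, banks.S, part, config.alpha2, config.alpha3)
            loss = recon + nbh
            opt.zero_grad()
            for prm in model.net.classifier_params + model.net.aux_params:
                prm.grad = None
            if not config.update_decoder:
                for prm in model.net.decoder_params:
                    prm.grad = None
            loss.backward()
            opt.step()
            ep["recon"] += float(recon.data) * len(idx)
            ep["nbh"] += float(nbh.data) * len(idx)
            ep["n"] += len(idx)

        # full-bank refresh at epoch end
        z, p, p1, p2 = _forward_numpy(model, target.x_input)
        banks.R, banks.S, banks.S1, banks.S2 = z, p, p1, p2
        banks.e_scores = escore_report(p, p1, p2, model.n_classes).e_score
        part = partition(banks.e_scores, delta, bim.novel_detected)
        log.append(
            {
                "epoch": epoch,
                "recon": ep["recon"] / ep["n"],
                "nbh": ep["nbh"] / ep["n"],
                "delta": delta,
                "n_known": int(len(part.known_idx)),
                "n_unknown": int(len(part.unknown_idx)),
            }
        )

    if bim.novel_detected and len(part.unknown_idx) == 0:
        warnings.warn("novelty detected but no cell fell below delta; closed behavior", stacklevel=2)
    return _result_from_banks(model, banks, part, bim, target.cell_ids, delta_traj, log)
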