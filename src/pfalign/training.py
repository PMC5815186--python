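"""Derivative-free training of the neural scoring function.

The search vector jointly encodes the network parameters and the affine gap
penalties; CMA-ES minimizes ``1 - mean alignment sensitivity`` of the
semi-global aligner over a training set of profile pairs with reference
alignments (one epoch = one CMA-ES generation, evaluated in a batch).
Training starts from parameters pretrained to mimic the Pearson correlation
coefficient on random PSSV pairs, with gap penalties at (-1.5, -0.1), and the
checkpoint maximizing validation sensitivity (earliest epoch on ties) is
selected.

A note on the pretraining target: because the input weight is shared, the
hidden layer sees only the coordinatewise sum of the two PSSVs, and the
correlation coefficient of an independent pair is not a function of that sum
(see docs/methods.md).  Pretraining therefore converges to the best
sum-measurable approximation of the correlation coefficient, not to the
coefficient itself; that approximation is what initializes the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import GapPenalties, semi_global_align
from .cmaes import CmaesConfig, cmaes_ask, cmaes_init, cmaes_tell
from .metrics import alignment_quality
from .profiles import PairwiseAlignment, Profile
from .scoring import NetworkParams, ScoreMatrix, nn_score_matrix, relu
from .synthetic import random_pssv_block


class TrainingError(ValueError):
    pass


Dataset = Sequence[Tuple[Profile, Profile, PairwiseAlignment]]


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop configuration.

    The full-scale profile is hidden_units=144, epochs_max=150,
    validation_start_epoch=50, validation_stride=5, lambda=70, mu=35,
    sigma0=0.032, pretrain_pairs=200_000; desk-scale runs shrink these while
    keeping the same structure.
    """

    hidden_units: int = 144
    epochs_max: int = 150
    validation_start_epoch: int = 50
    validation_stride: int = 5
    cmaes: CmaesConfig = field(default_factory=CmaesConfig)
    init_gap_open: float = -1.5
    init_gap_extend: float = -0.1
    pretrain_pairs: int = 200_000
    pretrain_epochs: int = 80
    pretrain_learning_rate: float = 0.1
    validation_size: Optional[int] = None
    validation_fraction: float = 0.1
    concentration: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise TrainingError("hidden_units must be >= 1")
        if self.validation_start_epoch > self.epochs_max:
            raise TrainingError(
                "validation_start_epoch exceeds epochs_max: no checkpoint "
                "could ever be selected"
            )
        if self.validation_stride < 1:
            raise TrainingError("validation_stride must be >= 1")


# ---------------------------------------------------------------------------
# Search-vector encoding
# ---------------------------------------------------------------------------

def search_dimension(H: int) -> int:
    """20*H (W1) + H (b1) + H (w2) + 1 (b2) + 2 (gap penalties)."""
    return 20 * H + 2 * H + 3


def encode_params(params: NetworkParams, gaps: GapPenalties) -> np.ndarray:
    """Flatten (W1 column-major, b1, w2, b2, open, extend) into one vector."""
    return np.concatenate(
        [
            params.W1.ravel(order="F"),
            params.b1,
            params.w2,
            [params.b2, gaps.open, gaps.extend],
        ]
    )


def decode_params(
    v: np.ndarray, H: int, clamp_gaps: bool = False
) -> Tuple[NetworkParams, GapPenalties]:
    """Inverse of :func:`encode_params`.

    With ``clamp_gaps`` the decoded penalties are projected into the valid
    region (extend <= 0, open <= extend) so an unconstrained search vector
    always yields usable penalties.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (search_dimension(H),):
        raise TrainingError(
            f"search vector length {v.shape} does not match H={H} "
            f"(expected {search_dimension(H)})"
        )
    W1 = v[: 20 * H].reshape((20, H), order="F")
    b1 = v[20 * H : 21 * H]
    w2 = v[21 * H : 22 * H]
    b2 = float(v[22 * H])
    go, ge = float(v[22 * H + 1]), float(v[22 * H + 2])
    if clamp_gaps:
        ge = min(ge, 0.0)
        go = min(go, ge)
    params = NetworkParams(W1=W1, b1=b1, w2=w2, b2=b2)
    return params, GapPenalties(open=go, extend=ge)


# ---------------------------------------------------------------------------
# Cost and evaluation
# ---------------------------------------------------------------------------

def _mean_sensitivity(
    params: NetworkParams, gaps: GapPenalties, dataset: Dataset
) -> float:
    sens = []
    for a, b, ref in dataset:
        try:
            S = nn_score_matrix(params, a, b)
            result = semi_global_align(S, gaps)
        except Exception as exc:
            raise TrainingError(f"pair ({a.id}, {b.id}): {exc}") from exc
        q = alignment_quality(result.alignment, ref)
        if q.sensitivity is not None:
            sens.append(q.sensitivity)
    if not sens:
        raise TrainingError("no pair with a defined sensitivity")
    return float(np.mean(sens))


def batch_cost(v: np.ndarray, dataset: Dataset, H: int) -> float:
    """1 - mean alignment sensitivity of the decoded scorer over the dataset."""
    if not len(dataset):
        raise TrainingError("empty dataset")
    params, gaps = decode_params(v, H, clamp_gaps=True)
    return 1.0 - _mean_sensitivity(params, gaps, dataset)


# ---------------------------------------------------------------------------
# Pretraining: mimic the correlation coefficient
# ---------------------------------------------------------------------------

def _cc_targets(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    return (ac * bc).sum(axis=1) / np.sqrt(
        (ac * ac).sum(axis=1) * (bc * bc).sum(axis=1)
    )


@dataclass(frozen=True)
class PretrainResult:
    params: NetworkParams
    holdout_rmse: float
    train_rmse: float


def pretrain_mimic_cc(
    H: int,
    n_pairs: int,
    seed: int,
    epochs: int = 80,
    learning_rate: float = 0.1,
    batch_size: int = 128,
    concentration: float = 0.3,
    holdout_pairs: int = 2000,
) -> PretrainResult:
    """Fit the shared-weight network to correlation-coefficient targets.

    Mini-batch gradient descent on squared error over random Dirichlet PSSV
    pairs.  Weight sharing is respected throughout, so the fitted function
    depends on the pair only through the coordinatewise sum; the reported
    held-out RMSE measures how closely that sum-measurable projection of the
    correlation coefficient is attained.
    """
    if n_pairs < 1:
        raise TrainingError(f"n_pairs must be >= 1, got {n_pairs}")
    rng = np.random.default_rng(seed)
    a = random_pssv_block(rng, concentration, n_pairs)
    b = random_pssv_block(rng, concentration, n_pairs)
    y = _cc_targets(a, b)
    s = a + b  # all a shared-weight network can see

    W1 = rng.standard_normal((20, H)) * np.sqrt(2.0 / 20)
    b1 = np.zeros(H)
    w2 = rng.standard_normal(H) * np.sqrt(1.0 / H)
    b2 = 0.0

    n = n_pairs
    for epoch in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            sb, yb = s[idx], y[idx]
            m = len(idx)
            u = sb @ W1 + b1
            h = relu(u)
            pred = h @ w2 + b2
            err = pred - yb
            loss_grad = 2.0 * err / m
            gw2 = h.T @ loss_grad
            gb2 = loss_grad.sum()
            gh = np.outer(loss_grad, w2) * (u > 0)
            gW1 = sb.T @ gh
            gb1 = gh.sum(axis=0)
            W1 -= learning_rate * gW1
            b1 -= learning_rate * gb1
            w2 -= learning_rate * gw2
            b2 -= learning_rate * gb2
        probe = relu(s[:256] @ W1 + b1) @ w2 + b2
        probe_loss = float(np.mean(np.square(np.clip(probe - y[:256], -1e150, 1e150))))
        if not (
            np.isfinite(W1).all()
            and np.isfinite(b1).all()
            and np.isfinite(w2).all()
            and np.isfinite(b2)
            and np.isfinite(probe_loss)
            and probe_loss < 1e6
        ):
            raise TrainingError(
                f"pretraining diverged at epoch {epoch}; try a smaller "
                f"learning rate than {learning_rate}"
            )

    params = NetworkParams(W1=W1, b1=b1, w2=w2, b2=b2)
    train_pred = relu(s @ W1 + b1) @ w2 + b2
    train_rmse = float(np.sqrt(np.mean((train_pred - y) ** 2)))
    ha = random_pssv_block(rng, concentration, holdout_pairs)
    hb = random_pssv_block(rng, concentration, holdout_pairs)
    hy = _cc_targets(ha, hb)
    hp = relu((ha + hb) @ W1 + b1) @ w2 + b2
    holdout_rmse = float(np.sqrt(np.mean((hp - hy) ** 2)))
    return PretrainResult(params=params, holdout_rmse=holdout_rmse, train_rmse=train_rmse)


# ---------------------------------------------------------------------------
# The training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Checkpoint:
    epoch: int
    params: NetworkParams
    gaps: GapPenalties
    train_cost: float
    validation_sensitivity: float


@dataclass(frozen=True)
class TrainResult:
    selected: Checkpoint
    checkpoints: Tuple[Checkpoint, ...]
    epoch_log: pd.DataFrame  # epoch, train_cost, sigma, validation_sensitivity
    init_validation_sensitivity: float
    init_train_sensitivity: float
    pretrain_holdout_rmse: float


def select_checkpoint(checkpoints: Sequence[Checkpoint]) -> Checkpoint:
    """Argmax of validation sensitivity; earliest epoch wins ties."""
    if not checkpoints:
        raise TrainingError("no checkpoints recorded")
    best = checkpoints[0]
    for cp in checkpoints[1:]:
        if cp.validation_sensitivity > best.validation_sensitivity:
            best = cp
    return best


def split_dataset(
    dataset: Dataset, config: TrainConfig
) -> Tuple[List, List]:
    """Seeded shuffle into training and validation subsets."""
    n = len(dataset)
    n_val = (
        config.validation_size
        if config.validation_size is not None
        else max(1, int(round(n * config.validation_fraction)))
    )
    if not (0 < n_val < n):
        raise TrainingError(
            f"validation size {n_val} leaves no training data (n={n})"
        )
    order = np.random.default_rng(config.seed).permutation(n)
    val = [dataset[k] for k in order[:n_val]]
    train = [dataset[k] for k in order[n_val:]]
    return train, val


def train(dataset: Dataset, config: TrainConfig) -> TrainResult:
    """CMA-ES training with validation checkpointing.

    One epoch is one CMA-ES generation: lambda batch-cost evaluations on the
    training split.  From ``validation_start_epoch`` on, every
    ``validation_stride`` epochs the generation-best candidate is scored on
    the validation split and recorded as a Checkpoint.
    """
    train_set, val_set = split_dataset(dataset, config)
    H = config.hidden_units

    pre = pretrain_mimic_cc(
        H,
        config.pretrain_pairs,
        seed=config.seed,
        epochs=config.pretrain_epochs,
        learning_rate=config.pretrain_learning_rate,
        concentration=config.concentration,
    )
    gaps0 = GapPenalties(open=config.init_gap_open, extend=config.init_gap_extend)
    x0 = encode_params(pre.params, gaps0)
    init_val = _mean_sensitivity(pre.params, gaps0, val_set)
    init_train = _mean_sensitivity(pre.params, gaps0, train_set)

    cma_cfg = replace(config.cmaes, seed=config.seed, max_generations=config.epochs_max)
    state = cmaes_init(x0, cma_cfg)

    checkpoints: List[Checkpoint] = []
    log_rows = []
    for epoch in range(1, config.epochs_max + 1):
        candidates = cmaes_ask(state)
        costs = [batch_cost(c, train_set, H) for c in candidates]
        cmaes_tell(state, candidates, costs)
        gen_best_idx = int(np.argmin(costs))
        gen_best_cost = costs[gen_best_idx]
        val_sens = None
        due = (
            epoch >= config.validation_start_epoch
            and (epoch - config.validation_start_epoch) % config.validation_stride == 0
        )
        if due:
            params, gaps = decode_params(
                candidates[gen_best_idx], H, clamp_gaps=True
            )
            val_sens = _mean_sensitivity(params, gaps, val_set)
            checkpoints.append(
                Checkpoint(
                    epoch=epoch,
                    params=params,
                    gaps=gaps,
                    train_cost=gen_best_cost,
                    validation_sensitivity=val_sens,
                )
            )
        log_rows.append(
            {
                "epoch": epoch,
                "train_cost": gen_best_cost,
                "sigma": state.sigma,
                "validation_sensitivity": val_sens,
            }
        )

    selected = select_checkpoint(checkpoints)
    return TrainResult(
        selected=selected,
        checkpoints=tuple(checkpoints),
        epoch_log=pd.DataFrame(log_rows),
        init_validation_sensitivity=init_val,
        init_train_sensitivity=init_train,
        pretrain_holdout_rmse=pre.holdout_rmse,
    )


# ---------------------------------------------------------------------------
# Gap-penalty grid search for fixed scorers
# ---------------------------------------------------------------------------

def grid_search_gaps(
    score_matrix_fn: Callable[[Profile, Profile], ScoreMatrix],
    dataset: Dataset,
    open_range: Tuple[float, float] = (-2.0, -0.6),
    extend_range: Tuple[float, float] = (-0.4, -0.1),
    step: float = 0.1,
) -> Tuple[float, float, pd.DataFrame]:
    """Exhaustive grid over gap-penalty combinations.

    Evaluates mean sensitivity (and precision) of the fixed scorer on every
    (open, extend) combination; returns the sensitivity-maximizing pair (first
    in ascending scan order on ties) and the full table.
    """
    if step <= 0:
        raise TrainingError("step must be > 0")
    lo_o, hi_o = open_range
    lo_e, hi_e = extend_range
    if lo_o > hi_o or lo_e > hi_e:
        raise TrainingError("invalid range")
    n_open = int(round((hi_o - lo_o) / step)) + 1
    n_ext = int(round((hi_e - lo_e) / step)) + 1
    opens = [round(lo_o + k * step, 10) for k in range(n_open)]
    extends = [round(lo_e + k * step, 10) for k in range(n_ext)]

    matrices = [score_matrix_fn(a, b) for a, b, _ in dataset]
    refs = [ref for _, _, ref in dataset]

    rows = []
    best = (None, None, -np.inf)
    for go in opens:
        for ge in extends:
            if go > ge:
                continue  # outside the valid affine region
            gaps = GapPenalties(open=go, extend=ge)
            sens, prec = [], []
            for S, ref in zip(matrices, refs):
                q = alignment_quality(semi_global_align(S, gaps).alignment, ref)
                if q.sensitivity is not None:
                    sens.append(q.sensitivity)
                if q.precision is not None:
                    prec.append(q.precision)
            mean_sens = float(np.mean(sens))
            mean_prec = float(np.mean(prec)) if prec else float("nan")
            rows.append(
                {
                    "open": go,
                    "extend": ge,
                    "sensitivity": mean_sens,
                    "precision": mean_prec,
                }
            )
            if mean_sens > best[2]:
                best = (go, ge, mean_sens)
    table = pd.DataFrame(rows)
    return best[0], best[1], table
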