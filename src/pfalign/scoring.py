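"""Site-to-site similarity scoring functions for profile alignment.

The centerpiece is a single-hidden-layer neural scoring function over a pair
of PSSVs,

    y = w2 . relu(x_a W1 + x_b W1 + b1) + b2,

with the input weight matrix shared between the two arguments so that the
score is symmetric by construction.  Classical baselines (cosine similarity,
Pearson correlation, BLOSUM62/MIQS sequence scoring) and interpretation
diagnostics (connection-weight importance, six-decimal score-overlap counts)
live alongside it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .profiles import RESIDUE_ORDER, Profile
from .synthetic import random_pssv_block


class ScoringError(ValueError):
    """Degenerate input to a scoring function."""


@dataclass(frozen=True)
class NetworkParams:
    """Learned scoring-function parameters.

    W1 is the 20 x H input weight matrix applied to *both* PSSVs (shared
    weight), b1 the hidden bias, w2 the hidden-to-output weights, b2 the
    output bias.
    """

    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float

    def __post_init__(self):
        W1 = np.asarray(self.W1, dtype=float)
        b1 = np.asarray(self.b1, dtype=float)
        w2 = np.asarray(self.w2, dtype=float)
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "w2", w2)
        object.__setattr__(self, "b2", float(self.b2))
        H = W1.shape[1] if W1.ndim == 2 else -1
        if W1.ndim != 2 or W1.shape[0] != 20 or H < 1:
            raise ScoringError(f"W1 must be 20 x H with H >= 1, got {W1.shape}")
        if b1.shape != (H,) or w2.shape != (H,):
            raise ScoringError("b1/w2 dimensions do not match hidden width")
        for arr in (W1, b1, w2):
            if not np.isfinite(arr).all():
                raise ScoringError("non-finite network parameter")
        if not np.isfinite(self.b2):
            raise ScoringError("non-finite network parameter")

    @property
    def hidden_units(self) -> int:
        return self.W1.shape[1]

    def save(self, path) -> None:
        """Serialize as a versioned JSON key-value file with explicit dims."""
        payload = {
            "format": "pfalign-network-params",
            "version": 1,
            "input_units": 20,
            "hidden_units": self.hidden_units,
            "residue_order": RESIDUE_ORDER,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "NetworkParams":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "pfalign-network-params":
            raise ScoringError(f"{path}: not a pfalign network-params file")
        return cls(
            W1=np.array(payload["W1"]),
            b1=np.array(payload["b1"]),
            w2=np.array(payload["w2"]),
            b2=payload["b2"],
        )


@dataclass(frozen=True)
class ScoreMatrix:
    """L_A x L_B site-similarity matrix plus the name of its scorer."""

    values: np.ndarray
    scorer_name: str

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.size == 0:
            raise ScoringError(f"score matrix must be 2-D non-empty, got {values.shape}")
        if not np.isfinite(values).all():
            raise ScoringError("non-finite score matrix entry")


def relu(u: np.ndarray) -> np.ndarray:
    """Elementwise max(0, u)."""
    return np.maximum(0.0, u)


def cosine_score(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ScoringError("zero-norm PSSV in cosine_score")
    return float(a @ b / (na * nb))


def correlation_score(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    va, vb = ac @ ac, bc @ bc
    # numerically constant vectors (rounding leaves ~1e-34 residuals)
    if va <= 1e-20 or vb <= 1e-20:
        raise ScoringError("zero-variance PSSV in correlation_score")
    return float(ac @ bc / np.sqrt(va * vb))


def nn_score(params: NetworkParams, a: np.ndarray, b: np.ndarray) -> float:
    """Neural similarity score of one PSSV pair (symmetric by weight sharing)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (20,) or b.shape != (20,):
        raise ScoringError(f"PSSVs must be 20-vectors, got {a.shape}, {b.shape}")
    hidden = relu(a @ params.W1 + b @ params.W1 + params.b1)
    return float(params.w2 @ hidden + params.b2)


def nn_score_matrix(
    params: NetworkParams, A: Profile, B: Profile, chunk: int = 128
) -> ScoreMatrix:
    """All-against-all neural scores as batched matrix products.

    Equals the per-pair loop up to floating-point associativity (<= 1e-9).
    """
    pa = A.vectors @ params.W1  # L_A x H
    pb = B.vectors @ params.W1  # L_B x H
    out = np.empty((len(A), len(B)))
    for s in range(0, len(A), chunk):
        block = relu(pa[s : s + chunk, None, :] + pb[None, :, :] + params.b1)
        out[s : s + chunk] = block @ params.w2 + params.b2
    return ScoreMatrix(values=out, scorer_name="nn")


def cosine_score_matrix(A: Profile, B: Profile) -> ScoreMatrix:
    na = np.linalg.norm(A.vectors, axis=1)
    nb = np.linalg.norm(B.vectors, axis=1)
    if (na == 0).any() or (nb == 0).any():
        raise ScoringError("zero-norm PSSV row")
    values = (A.vectors / na[:, None]) @ (B.vectors / nb[:, None]).T
    return ScoreMatrix(values=values, scorer_name="cosine")


def correlation_score_matrix(A: Profile, B: Profile) -> ScoreMatrix:
    ca = A.vectors - A.vectors.mean(axis=1, keepdims=True)
    cb = B.vectors - B.vectors.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ca, axis=1)
    nb = np.linalg.norm(cb, axis=1)
    if (na <= 1e-10).any() or (nb <= 1e-10).any():
        raise ScoringError("zero-variance PSSV row")
    values = (ca / na[:, None]) @ (cb / nb[:, None]).T
    return ScoreMatrix(values=values, scorer_name="cc")


# ---------------------------------------------------------------------------
# Substitution-matrix sequence scoring
# ---------------------------------------------------------------------------

MIQS_SYNTHETIC_SHA256 = None  # set lazily; frozen by the test suite


def _load_blosum62():
    return substitution_matrices.load("BLOSUM62")


def _load_miqs_synthetic() -> Tuple[dict, str]:
    """Load the bundled synthetic MIQS stand-in.

    The genuine MIQS matrix file is not redistributable here; the bundled
    table is a synthetic stand-in (mean of BLOSUM45 and BLOSUM62, one
    decimal) with the same remote-homolog orientation, and is labeled as
    such in its filename.
    """
    text = (
        resources.files("pfalign").joinpath("data/miqs_synthetic.tsv").read_text()
    )
    digest = hashlib.sha256(text.encode()).hexdigest()
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    residues = lines[0].split("\t")[1:]
    table = {}
    for line in lines[1:]:
        fields = line.split("\t")
        r = fields[0]
        for c, v in zip(residues, fields[1:]):
            table[(r, c)] = float(v)
    return table, digest


def _matrix_lookup(name: str):
    name = name.upper()
    if name == "BLOSUM62":
        m = _load_blosum62()
        alphabet = set(m.alphabet)

        def look(x, y):
            if x not in alphabet:
                x = "X"
            if y not in alphabet:
                y = "X"
            return float(m[x, y])

        return look
    if name == "MIQS":
        table, _ = _load_miqs_synthetic()
        residues = {r for r, _ in table}
        fallback = min(table.values())

        def look(x, y):
            if x not in residues or y not in residues:
                if "X" in residues:
                    x = x if x in residues else "X"
                    y = y if y in residues else "X"
                else:
                    return fallback
            return table[(x, y)]

        return look
    raise ScoringError(f"unknown substitution matrix {name!r}")


def substitution_score_matrix(matrix_name: str, A: Profile, B: Profile) -> ScoreMatrix:
    """Sequence-level scores: entry (i, j) = matrix[A.sequence[i], B.sequence[j]]."""
    look = _matrix_lookup(matrix_name)
    values = np.array(
        [[look(x, y) for y in B.sequence] for x in A.sequence], dtype=float
    )
    return ScoreMatrix(values=values, scorer_name=matrix_name.lower())


# ---------------------------------------------------------------------------
# Interpretation diagnostics
# ---------------------------------------------------------------------------

def connection_weight_importance(
    params: NetworkParams,
) -> Tuple[np.ndarray, np.ndarray]:
    """Connection-weight importance of the 20 input attributes.

    The raw connection weight of attribute i is c_i = sum_j W1[i, j] * w2[j];
    returned as (|c|, sign(c)) so positive- and negative-signed attributes can
    be distinguished.
    """
    c = params.W1 @ params.w2
    return np.abs(c), np.sign(c)


def score_overlap_count(
    scorer: Callable[[np.ndarray, np.ndarray], np.ndarray],
    n: int,
    seed: int,
    concentration: float = 0.3,
) -> int:
    """Count six-decimal score collisions over n random PSSV pairs.

    `scorer` maps two (n, 20) blocks to n scores (use :func:`batch_scorer` to
    lift a scalar function).  Returns n minus the number of distinct values
    after round-half-to-even at 6 decimal places.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    a = random_pssv_block(rng, concentration, n)
    b = random_pssv_block(rng, concentration, n)
    scores = np.asarray(scorer(a, b), dtype=float)
    if scores.shape != (n,):
        raise ScoringError(f"scorer returned shape {scores.shape}, expected ({n},)")
    rounded = np.round(scores, 6)
    return int(n - np.unique(rounded).size)


def batch_scorer(fn, *args) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Lift a scalar pair scorer to blocks, reporting the pair index on error."""

    def run(a_block, b_block):
        out = np.empty(len(a_block))
        for k, (a, b) in enumerate(zip(a_block, b_block)):
            try:
                out[k] = fn(*args, a, b) if args else fn(a, b)
            except ScoringError as exc:
                raise ScoringError(f"pair {k}: {exc}") from exc
        return out

    return run


def nn_batch_scorer(params: NetworkParams):
    """Vectorized block scorer for the neural function."""

    def run(a_block, b_block):
        hidden = relu(a_block @ params.W1 + b_block @ params.W1 + params.b1)
        return hidden @ params.w2 + params.b2

    return run


def cc_batch_scorer():
    def run(a_block, b_block):
        ac = a_block - a_block.mean(axis=1, keepdims=True)
        bc = b_block - b_block.mean(axis=1, keepdims=True)
        va = (ac * ac).sum(axis=1)
        vb = (bc * bc).sum(axis=1)
        if (va <= 1e-20).any() or (vb <= 1e-20).any():
            bad = int(np.argmax((va <= 1e-20) | (vb <= 1e-20)))
            raise ScoringError(f"pair {bad}: zero-variance PSSV")
        return (ac * bc).sum(axis=1) / np.sqrt(va * vb)

    return run
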