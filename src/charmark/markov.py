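"""Per-transcript Markov transition models and stationary-vector features.

Each transcript is modeled on its own (no pooling across transcripts) as a
first- or second-order Markov chain over the 27-symbol alphabet. Transition
probabilities use Laplace smoothing,

    P_ij = (n_ij + alpha) / sum_u (n_iu + alpha),

with alpha = 0.01 by default: large enough to remove zero-probability
transitions (guaranteeing a unique positive stationary vector by
Perron-Frobenius), small enough to preserve the sparsity of natural-language
character statistics. The stationary distribution pi solving pi P = pi,
sum(pi) = 1 is the per-transcript feature vector: the long-run occupancy of
each character state.

For order 2 the states are character bigrams (27^2 = 729 states); smoothing
is applied over the 27 emitted symbols per bigram row, and the stationary
vector lives on the 729 bigram states via the induced chain in which state
(c1, c2) moves to (c2, c3) with probability P[(c1, c2), c3].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .alphabet import ALPHABET, Alphabet
from .preprocess import CharSequence

logger = logging.getLogger(__name__)

#: Main-analysis smoothing constant.
DEFAULT_ALPHA = 0.01
#: Sensitivity-sweep grid for the smoothing constant.
ALPHA_GRID = (0.001, 0.005, 0.01, 0.05, 0.1)

_STATIONARY_RTOL = 1e-8
_POWER_TOL = 1e-12
_POWER_MAX_ITER = 10_000


class MarkovError(ValueError):
    """Raised for invalid transition-model inputs (too-short sequences,
    unnormalizable rows, non-convergent stationary solves)."""


@dataclass
class TransitionModel:
    """Smoothed transition model for a single transcript.

    ``counts`` is k_states x 27 (k_states = 27 for order 1, 729 for order
    2); ``P`` is the row-stochastic Laplace-smoothed matrix of the same
    shape.
    """

    order: int
    counts: np.ndarray
    alpha: float
    P: np.ndarray
    transcript_id: str = ""
    alphabet: Alphabet = field(default=ALPHABET, repr=False)

    @property
    def k_states(self) -> int:
        return self.counts.shape[0]

    def state_names(self) -> list[str]:
        syms = self.alphabet.display_names()
        if self.order == 1:
            return list(syms)
        return [f"{a}|{b}" for a in syms for b in syms]


@dataclass
class SteadyState:
    """Stationary probability vector of a transition model."""

    pi: np.ndarray
    transcript_id: str = ""


@dataclass
class FeatureMatrix:
    """One stationary vector per transcript, with carried metadata."""

    values: np.ndarray
    row_ids: list[str]
    row_groups: list[str]
    row_participants: list[str]
    col_names: list[str]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def group_mask(self, label: str) -> np.ndarray:
        return np.asarray([g == label for g in self.row_groups])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.col_names)
        df.insert(0, "group", self.row_groups)
        df.insert(0, "participant_id", self.row_participants)
        df.insert(0, "transcript_id", self.row_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, dtype={"transcript_id": str, "participant_id": str})
        meta = ["transcript_id", "participant_id", "group"]
        cols = [c for c in df.columns if c not in meta]
        return cls(
            values=df[cols].to_numpy(dtype=float),
            row_ids=df["transcript_id"].tolist(),
            row_groups=df["group"].tolist(),
            row_participants=df["participant_id"].tolist(),
            col_names=cols,
        )


def count_transitions(
    seq: CharSequence, order: int = 1, alphabet: Alphabet | None = None
) -> np.ndarray:
    """Count observed transitions in a sequence.

    For order 1 the result is k x k with entry (i, j) the number of adjacent
    pairs (i, j). For order 2 the row index is the bigram state
    27*c1 + c2 and the column the emitted third symbol. The total count is
    len(seq) - order.
    """
    if order not in (1, 2):
        raise MarkovError(f"order must be 1 or 2, got {order}")
    alphabet = alphabet or seq.alphabet
    k = alphabet.size
    idx = seq.indices
    if idx.size < order + 1:
        raise MarkovError(
            f"transcript {seq.transcript_id!r}: length {idx.size} < "
            f"order + 1 = {order + 1}"
        )
    if order == 1:
        states = idx[:-1]
    else:
        states = k * idx[:-2] + idx[1:-1]
    emits = idx[order:]
    counts = np.zeros((k**order, k), dtype=np.int64)
    np.add.at(counts, (states, emits), 1)
    return counts


def smooth(counts: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Laplace-smooth a count matrix into a row-stochastic matrix.

    P_ij = (n_ij + alpha) / sum_u (n_iu + alpha). With alpha = 0 rows with no
    observations cannot be normalized and raise :class:`MarkovError`.
    """
    counts = np.asarray(counts, dtype=float)
    if alpha < 0:
        raise MarkovError(f"alpha must be nonnegative, got {alpha}")
    if np.any(counts < 0):
        raise MarkovError("negative transition counts")
    row_sums = counts.sum(axis=1, keepdims=True) + alpha * counts.shape[1]
    if alpha == 0 and np.any(row_sums == 0):
        raise MarkovError("alpha=0 with an all-zero count row is unnormalizable")
    return (counts + alpha) / row_sums


def _lift_second_order(P: np.ndarray, k: int) -> np.ndarray:
    """Build the 729x729 bigram-to-bigram chain from a 729x27 emission matrix.

    State (c1, c2) transitions to (c2, c3) with probability P[(c1, c2), c3];
    all other transitions are structurally impossible.
    """
    lifted = np.zeros((k * k, k * k))
    rows = np.arange(k * k)
    c2 = rows % k
    for c3 in range(k):
        lifted[rows, c2 * k + c3] = P[rows, c3]
    return lifted


def _power_iteration(T: np.ndarray) -> np.ndarray:
    pi = np.full(T.shape[0], 1.0 / T.shape[0])
    for _ in range(_POWER_MAX_ITER):
        nxt = pi @ T
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - pi)) < _POWER_TOL:
            return nxt
        pi = nxt
    residual = float(np.max(np.abs(pi @ T - pi)))
    raise MarkovError(
        f"stationary power iteration did not converge; residual {residual:.3e}"
        " — for alpha=0 chains, use alpha > 0 to guarantee irreducibility"
    )


def steady_state(model: TransitionModel) -> SteadyState:
    """Solve pi P = pi, sum(pi) = 1 for the stationary distribution.

    Order 1 uses a dense left-eigendecomposition, taking the eigenvector
    whose eigenvalue is nearest 1, clipping numerically negative entries at
    zero and renormalizing; power iteration is the fallback. Order 2 uses
    power iteration on the lifted bigram chain (the 729x729 matrix is sparse
    in structure and the chain is irreducible whenever alpha > 0).
    """
    k = model.alphabet.size
    T = model.P if model.order == 1 else _lift_second_order(model.P, k)
    pi: np.ndarray | None = None
    if model.order == 1:
        eigvals, eigvecs = scipy.linalg.eig(T.T)
        i = int(np.argmin(np.abs(eigvals - 1.0)))
        if abs(eigvals[i] - 1.0) < 1e-6:
            cand = np.real(eigvecs[:, i])
            cand = np.clip(cand, 0, None) if cand.sum() >= 0 else np.clip(-cand, 0, None)
            if cand.sum() > 0:
                pi = cand / cand.sum()
    if pi is None or np.max(np.abs(pi @ T - pi)) > _STATIONARY_RTOL:
        pi = _power_iteration(T)
    residual = float(np.max(np.abs(pi @ T - pi)))
    if residual > _STATIONARY_RTOL:
        raise MarkovError(
            f"stationary residual {residual:.3e} exceeds {_STATIONARY_RTOL:.0e}"
        )
    return SteadyState(pi=pi, transcript_id=model.transcript_id)


def fit_model(
    seq: CharSequence, alpha: float = DEFAULT_ALPHA, order: int = 1
) -> TransitionModel:
    """Count transitions and smooth them into a TransitionModel."""
    counts = count_transitions(seq, order)
    return TransitionModel(
        order=order,
        counts=counts,
        alpha=alpha,
        P=smooth(counts, alpha),
        transcript_id=seq.transcript_id,
        alphabet=seq.alphabet,
    )


def transcript_features(
    seq: CharSequence, alpha: float = DEFAULT_ALPHA, order: int = 1
) -> SteadyState:
    """Stationary feature vector for one transcript: count -> smooth -> solve."""
    return steady_state(fit_model(seq, alpha, order))


def build_feature_matrix(
    corpus: list[CharSequence], alpha: float = DEFAULT_ALPHA, order: int = 1
) -> FeatureMatrix:
    """Stack per-transcript stationary vectors into a features-by-transcript
    matrix (n x 27 for order 1), carrying ids, participants, and group labels.

    Transcripts too short to fit (length < order + 1) are excluded with a
    logged warning; an all-failed corpus is a hard error.
    """
    if not corpus:
        raise MarkovError("empty corpus")
    rows, ids, groups, participants = [], [], [], []
    for seq in corpus:
        try:
            ss = transcript_features(seq, alpha, order)
        except MarkovError as exc:
            logger.warning("excluding transcript: %s", exc)
            continue
        rows.append(ss.pi)
        ids.append(seq.transcript_id)
        groups.append(seq.group_label)
        participants.append(seq.participant_id)
    if not rows:
        raise MarkovError("no transcript admitted a transition model")
    alphabet = corpus[0].alphabet
    syms = alphabet.display_names()
    col_names = (
        list(syms) if order == 1 else [f"{a}|{b}" for a in syms for b in syms]
    )
    return FeatureMatrix(
        values=np.vstack(rows),
        row_ids=ids,
        row_groups=groups,
        row_participants=participants,
        col_names=col_names,
    )


def second_order_state_count(k: int = 27) -> int:
    """Number of states in the bigram-state chain: k^2."""
    return k * k


def second_order_free_parameters(k: int = 27) -> int:
    """Free transition parameters of the bigram-state chain: k^2 rows of
    k emission probabilities with one sum-to-one constraint each,
    k^2 * (k - 1)."""
    return k * k * (k - 1)
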