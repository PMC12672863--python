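"""Synthetic transcript corpora from group-specific character chains.

The study corpus this pipeline targets is access-gated, so every stage is
exercised on generated data instead. Two groups of character sequences are
drawn from group-specific Markov chains over the 27-symbol alphabet whose
base transition structure is estimated from a bundled English prose sample —
synthetic text therefore has realistic English character statistics (letter
frequencies, word-length scale) even though it is not coherent language.

The case group's chains can differ from control in three separately tunable
ways, emulating the signatures reported for dementia speech:

* ``space_shift`` — additive tilt on every row's transition probability into
  the space symbol (elevated word-boundary/pause rate);
* ``self_loop_boost`` — multiplicative inflation of diagonal transitions
  (repetitive, locally concentrated production);
* ``letter_shift`` — within-row transfer of mass between two letter columns,
  a transition-level effect that leaves each row's space probability
  untouched (for ablation studies with matched space usage).

With all three at zero the two groups share one generator: an exchangeable
null. Per-participant heterogeneity comes from Dirichlet resampling of the
chain rows, creating the participant-level grouping structure that the
cross-validation module must respect. Everything is reproducible from the
spec's seed.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import ALPHABET, Alphabet
from .markov import count_transitions, smooth, steady_state, TransitionModel
from .preprocess import CharSequence, encode, normalize_text

_MIN_PROB = 1e-12


class SynthError(ValueError):
    pass


def base_chain_from_text(
    text: str | None = None, alpha: float = 0.05, alphabet: Alphabet = ALPHABET
) -> np.ndarray:
    """Estimate a strictly positive 27x27 base chain from English prose.

    Defaults to the bundled prose sample. The smoothing constant here only
    shapes the generator (it must make the chain strictly positive); it is
    unrelated to the analysis-side smoothing.
    """
    if text is None:
        text = (
            resources.files("charmark.data")
            .joinpath("english_sample.txt")
            .read_text(encoding="utf-8")
        )
    seq = encode(normalize_text(text), alphabet, transcript_id="base-chain")
    return smooth(count_transitions(seq, 1, alphabet), alpha)


@dataclass
class GeneratorSpec:
    """Parameters of a two-group synthetic corpus.

    Defaults emulate the printed composition of the study corpus: 168 case
    participants contributing 310 transcripts and 98 control participants
    contributing 242, with transcript lengths uniform on [300, 1500]
    characters (picture-description scale). Group effects default to zero
    (the exchangeable null); analyses switch on the effect they probe.
    """

    base_chain: np.ndarray | None = None
    space_shift: float = 0.0
    self_loop_boost: float = 0.0
    letter_shift: float = 0.0
    letter_source: str = "t"
    letter_target: str = "z"
    within_group_noise: float | None = 500.0
    case_noise: float | None = None  # falls back to within_group_noise
    transcript_length: tuple[int, int] = (300, 1500)
    n_participants: dict = field(
        default_factory=lambda: {"case": 168, "control": 98}
    )
    n_transcripts: dict | None = field(
        default_factory=lambda: {"case": 310, "control": 242}
    )
    seed: int = 0
    alphabet: Alphabet = field(default=ALPHABET, repr=False)

    def __post_init__(self) -> None:
        if self.base_chain is None:
            self.base_chain = base_chain_from_text(alphabet=self.alphabet)
        self.base_chain = np.asarray(self.base_chain, dtype=float)
        k = self.alphabet.size
        if self.base_chain.shape != (k, k):
            raise SynthError(f"base_chain must be {k}x{k}")
        if np.any(self.base_chain <= 0):
            raise SynthError("base_chain must be strictly positive")
        if not np.allclose(self.base_chain.sum(axis=1), 1.0, atol=1e-9):
            raise SynthError("base_chain rows must sum to 1")
        for g in ("case", "control"):
            if self.n_participants.get(g, 0) <= 0:
                raise SynthError(f"n_participants[{g!r}] must be positive")

    def echo(self) -> dict:
        """JSON-serializable record of the spec (base chain omitted)."""
        d = asdict(self)
        d.pop("base_chain")
        d.pop("alphabet")
        return d


def _renormalize(chain: np.ndarray) -> np.ndarray:
    chain = np.clip(chain, _MIN_PROB, None)
    return chain / chain.sum(axis=1, keepdims=True)


def make_group_chain(
    spec: GeneratorSpec, group: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw one participant's chain: base + Dirichlet row noise, then the
    case-group tilts (space shift, self-loop boost, letter shift)."""
    if group not in ("case", "control"):
        raise SynthError(f"unknown group {group!r}")
    chain = spec.base_chain.copy()
    conc = (
        spec.case_noise
        if group == "case" and spec.case_noise is not None
        else spec.within_group_noise
    )
    if conc is not None:
        chain = np.vstack(
            [rng.dirichlet(conc * row) for row in chain]
        )
        chain = _renormalize(chain)
    if group == "case":
        sp = spec.alphabet.space_index
        if spec.space_shift:
            old = chain[:, sp]
            new = old + spec.space_shift
            if np.any(new >= 1):
                raise SynthError(
                    "space_shift pushes a row's space probability to >= 1"
                )
            scale = (1 - new) / (1 - old)
            chain *= scale[:, None]
            chain[:, sp] = new
        if spec.self_loop_boost:
            di = np.arange(chain.shape[0])
            chain[di, di] *= 1 + spec.self_loop_boost
            chain = _renormalize(chain)
        if spec.letter_shift:
            src = spec.alphabet.index_of[spec.letter_source]
            dst = spec.alphabet.index_of[spec.letter_target]
            moved = spec.letter_shift * chain[:, src]
            chain[:, src] -= moved
            chain[:, dst] += moved
        chain = _renormalize(chain)
    return chain


def sample_transcript(
    chain: np.ndarray,
    length: int,
    seed,
    *,
    transcript_id: str = "",
    participant_id: str = "",
    group_label: str = "unknown",
    alphabet: Alphabet = ALPHABET,
) -> CharSequence:
    """Sample a character sequence of (at most) ``length`` symbols.

    The initial symbol is drawn from the chain's stationary distribution;
    subsequent symbols follow the transition rows. The raw sample is then
    post-processed to satisfy the transcript invariants — space runs are
    collapsed and boundary spaces trimmed — so the returned sequence can be
    slightly shorter than requested.
    """
    chain = np.asarray(chain, dtype=float)
    if length < 2:
        raise SynthError("length must be >= 2")
    if not np.allclose(chain.sum(axis=1), 1.0, atol=1e-9):
        raise SynthError("chain rows must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = steady_state(
        TransitionModel(order=1, counts=np.zeros_like(chain), alpha=0.0,
                        P=chain, alphabet=alphabet)
    ).pi
    cum = np.cumsum(chain, axis=1)
    cum[:, -1] = 1.0
    cum_rows = [row.tolist() for row in cum]
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    state = int(np.searchsorted(np.cumsum(pi), u[0]))
    state = min(state, chain.shape[0] - 1)
    out[0] = state
    for t in range(1, length):
        state = bisect_right(cum_rows[state], u[t])
        out[t] = state
    # enforce transcript invariants: no space runs, no boundary spaces
    sp = alphabet.space_index
    keep = np.ones(length, dtype=bool)
    keep[1:] = ~((out[1:] == sp) & (out[:-1] == sp))
    out = out[keep]
    start, end = 0, out.size
    while start < end and out[start] == sp:
        start += 1
    while end > start and out[end - 1] == sp:
        end -= 1
    return CharSequence(
        indices=out[start:end],
        transcript_id=transcript_id,
        participant_id=participant_id,
        group_label=group_label,
        alphabet=alphabet,
    )


def _split_counts(total: int, parts: int) -> list[int]:
    """Distribute ``total`` transcripts over ``parts`` participants as evenly
    as possible (first ``total % parts`` participants get one extra)."""
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def generate_corpus(
    spec: GeneratorSpec,
) -> tuple[list[CharSequence], pd.DataFrame]:
    """Generate the full labeled, participant-attributed corpus.

    Returns the encoded sequences plus a manifest frame with the same schema
    as a real-data manifest (path, label, participant_id; path filled on
    dump). Fully deterministic given the spec, including its seed.
    """
    root_ss = np.random.SeedSequence(spec.seed)
    group_ss = {g: s for g, s in zip(("control", "case"), root_ss.spawn(2))}
    corpus: list[CharSequence] = []
    rows = []
    for group in ("control", "case"):
        n_part = spec.n_participants[group]
        totals = (
            _split_counts(spec.n_transcripts[group], n_part)
            if spec.n_transcripts
            else [1] * n_part
        )
        if spec.n_transcripts and spec.n_transcripts[group] < n_part:
            raise SynthError(
                f"group {group!r}: fewer transcripts than participants"
            )
        part_seeds = group_ss[group].spawn(n_part)
        for i, (n_tr, ss) in enumerate(zip(totals, part_seeds)):
            rng = np.random.default_rng(ss)
            pid = f"{group}_p{i:03d}"
            chain = make_group_chain(spec, group, rng)
            lo, hi = spec.transcript_length
            for t in range(n_tr):
                length = int(rng.integers(lo, hi + 1))
                tid = f"{pid}_t{t:02d}"
                seq = sample_transcript(
                    chain, length, rng,
                    transcript_id=tid, participant_id=pid, group_label=group,
                    alphabet=spec.alphabet,
                )
                corpus.append(seq)
                rows.append(
                    {"path": f"{tid}.txt", "label": group, "participant_id": pid}
                )
    manifest = pd.DataFrame(rows)
    return corpus, manifest


def dump_corpus(
    corpus: list[CharSequence],
    manifest: pd.DataFrame,
    outdir: str | Path,
    spec: GeneratorSpec | None = None,
) -> Path:
    """Write one .txt file per transcript, the manifest CSV, and (if given)
    a JSON echo of the generator spec. Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for seq in corpus:
        (outdir / f"{seq.transcript_id}.txt").write_text(
            seq.decode(), encoding="utf-8"
        )
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    if spec is not None:
        (outdir / "generator_spec.json").write_text(
            json.dumps(spec.echo(), indent=2), encoding="utf-8"
        )
    return manifest_path
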