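"""Simplified Plan-7 profile hidden Markov models for subfamily scoring.

A profile HMM is built from a subfamily alignment: columns with at most
50% gaps become match states; residues in non-match columns are treated
as insertions and gaps in match columns as deletions.  Match emissions
are count-plus-pseudocount estimates against a pooled background,
insert states emit the background, and transition probabilities are
estimated from the observed match/insert/delete paths with Laplace
smoothing.

Sequences are scored globally (begin-to-end) with the forward
algorithm in log space; scores are reported as log-odds in bits
against a null model that shares the model's transition structure but
emits the background everywhere.  That null makes the score of a
background-emission model exactly zero and cancels length effects, so
the *margin* between two subfamily models carries the classification
signal.  Viterbi scores (best single path, same null) are available
alongside and are never above the forward score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msa import AMINO_ACIDS, GAP, ReferencedMSA, _AA_INDEX

__all__ = ["ProfileHMM", "build_profile_hmm", "score_sequence", "classify_subfamily",
           "SequenceScore", "Classification"]

_LN2 = math.log(2.0)
_NEG_INF = -np.inf

# transition kinds out of each state class, in storage order
_FROM_M = ("mm", "mi", "md")
_FROM_I = ("im", "ii", "id")
_FROM_D = ("dm", "di", "dd")


@dataclass
class ProfileHMM:
    """Match/insert/delete profile HMM with log-space parameters."""

    log_match_emission: np.ndarray  # (L+1, 20); row 0 unused (Begin)
    log_background: np.ndarray  # (20,)
    log_t: dict[str, np.ndarray]  # each (L+1,), index j = source column
    match_columns: np.ndarray  # alignment columns that became match states
    pseudocount: float

    @property
    def length(self) -> int:
        return self.log_match_emission.shape[0] - 1

    @property
    def emission_log_odds_bits(self) -> np.ndarray:
        """Match-state emission log-odds against the background, bits."""
        return (self.log_match_emission[1:] - self.log_background) / _LN2

    def consensus(self) -> str:
        """Highest-emission residue of each match state."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.log_match_emission[1:], axis=1))

    def null_model(self) -> "ProfileHMM":
        """Same transitions, background emissions everywhere."""
        log_e = np.tile(self.log_background, (self.length + 1, 1))
        return ProfileHMM(
            log_match_emission=log_e,
            log_background=self.log_background.copy(),
            log_t={k: v.copy() for k, v in self.log_t.items()},
            match_columns=self.match_columns.copy(),
            pseudocount=self.pseudocount,
        )


def build_profile_hmm(
    msa: ReferencedMSA | list[str],
    pseudocount: float = 1.0,
    max_gap_fraction: float = 0.5,
) -> ProfileHMM:
    """Estimate a profile HMM from a (sub)family alignment.

    Raises a model error if no column passes the match-state gap
    threshold.
    """
    rows = list(msa.rows) if isinstance(msa, ReferencedMSA) else [r.upper() for r in msa]
    if len(rows) < 2:
        raise ValueError("profile HMM needs at least 2 sequences")
    n_cols = len(rows[0])
    if any(len(r) != n_cols for r in rows):
        raise ValueError("alignment rows have unequal lengths")

    gap_frac = np.array(
        [sum(r[c] == GAP for r in rows) / len(rows) for c in range(n_cols)]
    )
    match_cols = np.where(gap_frac <= max_gap_fraction)[0]
    if len(match_cols) == 0:
        raise ValueError("alignment has no match columns (all columns exceed the gap threshold)")
    L = len(match_cols)

    pooled = np.zeros(20)
    for r in rows:
        for a in r:
            i = _AA_INDEX.get(a)
            if i is not None:
                pooled[i] += 1
    if pooled.sum() == 0:
        raise ValueError("alignment contains no standard residues")
    # Laplace-floored background: every residue keeps nonzero probability
    bg = (pooled + 1.0) / (pooled.sum() + 20.0)

    counts = np.zeros((L + 1, 20))
    t_counts = {k: np.ones(L + 1) for k in _FROM_M + _FROM_I + _FROM_D}  # Laplace

    is_match = np.zeros(n_cols, dtype=bool)
    is_match[match_cols] = True
    col_to_state = {c: j + 1 for j, c in enumerate(match_cols)}

    for r in rows:
        prev = ("m", 0)  # Begin behaves as M_0
        for c in range(n_cols):
            a = r[c]
            if is_match[c]:
                j = col_to_state[c]
                if a != GAP:
                    i = _AA_INDEX.get(a)
                    if i is not None:
                        counts[j, i] += 1
                    state = ("m", j)
                else:
                    state = ("d", j)
                t_counts[prev[0] + state[0]][prev[1]] += 1
                prev = state
            elif a != GAP:
                # insertion between match states: emits background, self-loops
                t_counts[prev[0] + "i"][prev[1]] += 1
                prev = ("i", prev[1])
        t_counts[prev[0] + "m"][prev[1]] += 1  # exit to End

    n_eff = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        em = (counts + pseudocount * bg) / (n_eff + pseudocount)
        log_em = np.log(em)
    log_em[0] = np.log(bg)  # Begin row, never used for emission

    log_t: dict[str, np.ndarray] = {}
    for src, kinds in (("m", _FROM_M), ("i", _FROM_I), ("d", _FROM_D)):
        tot = sum(t_counts[k] for k in kinds)
        for k in kinds:
            log_t[k] = np.log(t_counts[k] / tot)
    # delete state does not exist at j=0
    for k in _FROM_D:
        log_t[k][0] = _NEG_INF

    return ProfileHMM(
        log_match_emission=log_em,
        log_background=np.log(bg),
        log_t=log_t,
        match_columns=match_cols,
        pseudocount=pseudocount,
    )


def _dp(hmm: ProfileHMM, seq_idx: np.ndarray, combine) -> float:
    """Global profile-HMM DP; ``combine`` is logsumexp (forward) or max (Viterbi)."""
    L = hmm.length
    n = len(seq_idx)
    t = hmm.log_t
    log_bg = hmm.log_background

    m = np.full((L + 1, n + 1), _NEG_INF)
    ins = np.full((L + 1, n + 1), _NEG_INF)
    d = np.full((L + 1, n + 1), _NEG_INF)
    m[0, 0] = 0.0

    for j in range(0, L + 1):
        for i in range(0, n + 1):
            if j > 0:
                if i > 0:
                    m[j, i] = hmm.log_match_emission[j, seq_idx[i - 1]] + combine(
                        (m[j - 1, i - 1] + t["mm"][j - 1],
                         ins[j - 1, i - 1] + t["im"][j - 1],
                         d[j - 1, i - 1] + t["dm"][j - 1])
                    )
                d[j, i] = combine(
                    (m[j - 1, i] + t["md"][j - 1],
                     ins[j - 1, i] + t["id"][j - 1],
                     d[j - 1, i] + t["dd"][j - 1])
                )
            if i > 0:
                ins[j, i] = log_bg[seq_idx[i - 1]] + combine(
                    (m[j, i - 1] + t["mi"][j],
                     ins[j, i - 1] + t["ii"][j],
                     d[j, i - 1] + t["di"][j])
                )
    return combine((m[L, n] + t["mm"][L], ins[L, n] + t["im"][L], d[L, n] + t["dm"][L]))


def _logsumexp(vals) -> float:
    m = max(vals)
    if m == _NEG_INF:
        return _NEG_INF
    return m + math.log(sum(math.exp(v - m) for v in vals))


@dataclass(frozen=True)
class SequenceScore:
    """Log-odds scores of one sequence against one model, bits."""

    forward_bits: float
    viterbi_bits: float


def score_sequence(hmm: ProfileHMM, seq: str) -> SequenceScore:
    """Score an unaligned sequence against the model (global, log-odds bits)."""
    seq = seq.upper().replace(GAP, "")
    if not seq:
        raise ValueError("cannot score an empty sequence")
    bad = [a for a in seq if a not in _AA_INDEX]
    if bad:
        raise ValueError(f"sequence contains letters outside the amino-acid alphabet: {bad[0]!r}")
    idx = np.array([_AA_INDEX[a] for a in seq])
    log_f = _dp(hmm, idx, _logsumexp)
    log_v = _dp(hmm, idx, max)
    log_null = _dp(hmm.null_model(), idx, _logsumexp)
    return SequenceScore(
        forward_bits=(log_f - log_null) / _LN2,
        viterbi_bits=(log_v - log_null) / _LN2,
    )


@dataclass(frozen=True)
class Classification:
    """Best-scoring subfamily model for a sequence."""

    best: str
    margin_bits: float  # best minus second best
    scores: dict[str, float]
    tie: bool
    low_confidence: bool


def classify_subfamily(
    seq: str,
    models: dict[str, ProfileHMM],
    margin_threshold: float = 2.0,
) -> Classification:
    """Assign a sequence to the best-scoring of several subfamily models.

    The margin is the forward-score gap (bits) to the runner-up; a
    margin below ``margin_threshold`` flags a low-confidence call, and
    an exact tie is reported as such.
    """
    if len(models) < 2:
        raise ValueError("classification needs at least 2 models")
    scores = {name: score_sequence(m, seq).forward_bits for name, m in models.items()}
    ranked = sorted(scores.items(), key=lambda kv: -kv[1])
    margin = ranked[0][1] - ranked[1][1]
    return Classification(
        best=ranked[0][0],
        margin_bits=margin,
        scores=scores,
        tie=margin == 0.0,
        low_confidence=margin < margin_threshold,
    )
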