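"""Sufficient statistics of symbol sequences for order-``n`` chain likelihoods.

The likelihood of a sequence under an order-``n`` chain depends on the data
only through (a) per-word switch and stay counts over the last ``N - n``
symbols and (b) the first ``n`` symbols (the initial word).  Trials pooled
within a subject add their counts and concatenate their initial words: the
count terms multiply as probabilities and the initial-word prefactors
multiply separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    Alphabet,
    DEFAULT_ALPHABET,
    Word,
    _check_order,
    successor_indices,
)


class ShortTrialError(ValueError):
    """A trial is too short to contribute at the requested order."""


@dataclass(frozen=True)
class SymbolSequence:
    """One trial: a string of binary symbols with subject/trial identity."""

    subject_id: str
    trial_id: str
    symbols: str
    alphabet: Alphabet = field(default=DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError(
                f"trial {self.subject_id}/{self.trial_id}: empty sequence"
            )
        # raises on foreign symbols
        self.alphabet.encode(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def encoded(self) -> np.ndarray:
        return self.alphabet.encode(self.symbols)


@dataclass(frozen=True)
class SufficientStats:
    """Per-word switch/stay counts plus the initial word of each trial.

    ``switch[i]`` counts transitions from word ``i`` where the appended
    symbol differed from the word's last symbol, ``stay[i]`` where it
    repeated it.  For order 0 the two length-1 vectors degenerate to the
    total counts of symbol 0 ('L') and symbol 1 ('R') over all symbols,
    with an empty initial word per trial.
    """

    order: int
    switch: np.ndarray
    stay: np.ndarray
    initial_words: tuple[Word, ...]

    def __post_init__(self) -> None:
        _check_order(self.order)
        d = 1 << self.order
        switch = np.asarray(self.switch, dtype=np.int64)
        stay = np.asarray(self.stay, dtype=np.int64)
        if switch.shape != (d,) or stay.shape != (d,):
            raise ValueError(f"count vectors must have length {d}")
        if np.any(switch < 0) or np.any(stay < 0):
            raise ValueError("counts must be nonnegative")
        for w in self.initial_words:
            if len(w) != self.order:
                raise ValueError(
                    f"initial word {w} has wrong length for order {self.order}"
                )
        object.__setattr__(self, "switch", switch)
        object.__setattr__(self, "stay", stay)
        object.__setattr__(self, "initial_words", tuple(self.initial_words))

    @property
    def n_trials(self) -> int:
        return len(self.initial_words)

    @property
    def n_transitions(self) -> int:
        """Total classified steps, sum over trials of ``N_t - order``."""
        return int(self.switch.sum() + self.stay.sum())

    def initial_word_counts(self) -> np.ndarray:
        """How often each word index occurs as a trial's initial word."""
        counts = np.zeros(1 << self.order, dtype=np.int64)
        for w in self.initial_words:
            idx = 0
            for s in w:
                idx = (idx << 1) | s
            counts[idx] += 1
        return counts


def count_transitions(
    sequence: SymbolSequence | str, order: int
) -> SufficientStats:
    """Sufficient statistics of a single trial at the given order.

    A sliding window classifies each of the ``N - order`` steps after the
    initial word by its preceding word and by whether the new symbol
    switches away from that word's last symbol.  Order 0 counts all
    symbols directly (the empty initial word has probability 1, so no
    symbols are set aside for a prefactor).
    """
    if isinstance(sequence, str):
        sequence = SymbolSequence("anon", "t0", sequence)
    _check_order(order)
    x = sequence.encoded()
    n_sym = len(x)
    if order == 0:
        n_r = int(x.sum())
        return SufficientStats(
            0, np.array([n_sym - n_r]), np.array([n_r]), ((),)
        )
    if n_sym < order + 1:
        raise ShortTrialError(
            f"trial {sequence.subject_id}/{sequence.trial_id}: length "
            f"{n_sym} < {order + 1} required at order {order}"
        )
    d = 1 << order
    # word index preceding each appended symbol, built incrementally
    words = np.zeros(n_sym - order, dtype=np.int64)
    for k in range(order):
        words = (words << 1) | x[k : n_sym - order + k]
    appended = x[order:]
    last = x[order - 1 : n_sym - 1]
    switched = appended != last
    switch = np.bincount(words[switched], minlength=d)
    stay = np.bincount(words[~switched], minlength=d)
    return SufficientStats(
        order, switch, stay, (tuple(int(v) for v in x[:order]),)
    )


def pool_stats(stats_list: list[SufficientStats]) -> SufficientStats:
    """Pool trials of one subject: counts add, initial words concatenate."""
    if not stats_list:
        raise ValueError("cannot pool an empty list of statistics")
    order = stats_list[0].order
    for s in stats_list[1:]:
        if s.order != order:
            raise ValueError(
                f"cannot pool statistics of orders {order} and {s.order}"
            )
    switch = np.sum([s.switch for s in stats_list], axis=0)
    stay = np.sum([s.stay for s in stats_list], axis=0)
    initial = tuple(w for s in stats_list for w in s.initial_words)
    return SufficientStats(order, switch, stay, initial)


@dataclass(frozen=True)
class MLETransitionMatrix:
    """Word-space transition matrix at the maximum-likelihood estimates.

    ``eps_hat[i] = c_i / (c_i + cbar_i)`` is NaN for words never observed;
    the corresponding matrix rows carry NaN in their two structural
    nonzero positions rather than an invented value.
    """

    order: int
    eps_hat: np.ndarray
    matrix: np.ndarray
    missing: np.ndarray

    @property
    def has_missing(self) -> bool:
        return bool(self.missing.any())


def mle_transition_matrix(stats: SufficientStats) -> MLETransitionMatrix:
    """Plug-in MLE switch probabilities and the induced transition matrix."""
    if stats.order < 1:
        raise ValueError("MLE transition matrix requires order >= 1")
    total = stats.switch + stats.stay
    missing = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        eps_hat = np.where(missing, np.nan, stats.switch / np.maximum(total, 1))
    d = 1 << stats.order
    stay_to, switch_to = successor_indices(stats.order)
    idx = np.arange(d)
    matrix = np.zeros((d, d))
    matrix[idx, switch_to] = eps_hat
    matrix[idx, stay_to] = 1.0 - eps_hat
    return MLETransitionMatrix(stats.order, eps_hat, matrix, missing)
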