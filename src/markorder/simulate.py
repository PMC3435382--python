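"""Simulation of two-state Markov chains and synthetic subject fixtures.

The simulator mirrors the validation protocol for the order estimator:
random transition matrices with independently Uniform(0,1) switch
probabilities, a long burn-in (default 30,000 iterates) to remove
transients, and sequences of 20-50 symbols matching the length of
microsaccade-direction trials in a 20-second fixation interval.  An
optional exclusion band keeps switch probabilities away from 0.5, where
orders are unidentifiable at these sequence lengths.

Seed discipline: a master seed deterministically derives a child seed per
(order, model, sequence) via ``numpy.random.SeedSequence`` spawn keys, so
any single sequence is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import MarkovModel, _check_order
from .stats import SymbolSequence

DEFAULT_BURN_IN = 30_000
DEFAULT_LENGTH_RANGE = (20, 50)

SeedLike = int | np.random.SeedSequence | np.random.Generator


def _as_rng(seed: SeedLike | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_model(
    order: int, seed: SeedLike | None = None, exclusion_halfwidth: float = 0.0
) -> MarkovModel:
    """Random model with iid Uniform(0,1) switch probabilities.

    With ``exclusion_halfwidth = h > 0``, parameters within ``h`` of 0.5
    are redrawn, producing identifiable benchmark regimes.  Draws are
    also redrawn away from exactly 0 so the chain is never degenerate.
    """
    _check_order(order)
    if exclusion_halfwidth < 0 or exclusion_halfwidth >= 0.5:
        raise ValueError("exclusion_halfwidth must lie in [0, 0.5)")
    rng = _as_rng(seed)
    params = rng.random(1 << order)
    while True:
        bad = (params == 0.0) | (np.abs(params - 0.5) < exclusion_halfwidth)
        if not bad.any():
            break
        params[bad] = rng.random(int(bad.sum()))
    return MarkovModel(order, params)


def simulate_sequence(
    model: MarkovModel,
    length: int,
    burn_in: int = DEFAULT_BURN_IN,
    seed: SeedLike | None = None,
    subject_id: str = "sim",
    trial_id: str = "t000",
) -> SymbolSequence:
    """One realization of the chain after discarding ``burn_in`` iterates.

    For orders >= 1 the initial word is drawn uniformly over words before
    the burn-in (immaterial after 30,000 iterates); each subsequent step
    appends the switching symbol with the current word's switch
    probability.  Order 0 emits iid draws.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    rng = _as_rng(seed)
    n = model.order
    if n == 0:
        p_l = model.params[0]
        symbols = (rng.random(length) >= p_l).astype(np.int64)
        return SymbolSequence(
            subject_id, trial_id, model.alphabet.decode(symbols)
        )
    word = int(rng.integers(1 << n))
    u = rng.random(burn_in + length).tolist()
    eps = model.params.tolist()
    mask = (1 << n) - 1
    out = []
    append = out.append
    for t in range(burn_in):
        last = word & 1
        s = 1 - last if u[t] < eps[word] else last
        word = ((word << 1) & mask) | s
    for t in range(burn_in, burn_in + length):
        last = word & 1
        s = 1 - last if u[t] < eps[word] else last
        word = ((word << 1) & mask) | s
        append(s)
    return SymbolSequence(subject_id, trial_id, model.alphabet.decode(out))


def simulate_batch(
    model: MarkovModel,
    n_chains: int,
    length: int,
    burn_in: int = DEFAULT_BURN_IN,
    seed: SeedLike | None = None,
    initial_words: np.ndarray | None = None,
) -> np.ndarray:
    """Many independent realizations stepped in lockstep (vectorized).

    Returns an ``(n_chains, length)`` 0/1 array.  ``initial_words`` may
    force the pre-burn-in word index per chain (used to verify that the
    burn-in erases the initial condition); by default words are uniform.
    """
    rng = _as_rng(seed)
    n = model.order
    if n == 0:
        return (rng.random((n_chains, length)) >= model.params[0]).astype(
            np.int64
        )
    if initial_words is None:
        word = rng.integers(0, 1 << n, size=n_chains)
    else:
        word = np.asarray(initial_words, dtype=np.int64).copy()
    eps = model.params
    mask = (1 << n) - 1
    out = np.empty((n_chains, length), dtype=np.int64)
    for t in range(burn_in + length):
        u = rng.random(n_chains)
        last = word & 1
        s = np.where(u < eps[word], 1 - last, last)
        word = ((word << 1) & mask) | s
        if t >= burn_in:
            out[:, t - burn_in] = s
    return out


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions for the simulated validation dataset."""

    orders: tuple[int, ...] = (0, 1, 2)
    models_per_order: int = 19
    sequences_per_order: int = 532
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
    burn_in: int = DEFAULT_BURN_IN
    master_seed: int = 0
    exclusion_halfwidth: float = 0.0

    def __post_init__(self) -> None:
        if self.models_per_order < 1 or self.sequences_per_order < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length range")
        for order in self.orders:
            _check_order(order)


@dataclass(frozen=True)
class BenchmarkGroup:
    """Sequences sharing one true model, labeled with the ground truth."""

    order: int
    model: MarkovModel
    sequences: tuple[SymbolSequence, ...]


@dataclass(frozen=True)
class BenchmarkDataset:
    spec: BenchmarkSpec
    groups: tuple[BenchmarkGroup, ...] = field(default_factory=tuple)

    def sequences(self) -> list[SymbolSequence]:
        return [s for g in self.groups for s in g.sequences]


def _allocate(total: int, bins: int) -> list[int]:
    base = total // bins
    counts = [base] * bins
    counts[-1] += total - base * bins  # remainder goes to the last model
    return counts


def generate_benchmark(spec: BenchmarkSpec) -> BenchmarkDataset:
    """Labeled validation dataset, fully reproducible from the master seed."""
    groups = []
    for order in spec.orders:
        counts = _allocate(spec.sequences_per_order, spec.models_per_order)
        for m, n_seq in enumerate(counts):
            model_seed = np.random.SeedSequence(
                spec.master_seed, spawn_key=(order, m)
            )
            model = random_model(order, model_seed, spec.exclusion_halfwidth)
            subject = f"order{order}_model{m:02d}"
            seqs = []
            for k in range(n_seq):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        spec.master_seed, spawn_key=(order, m, k)
                    )
                )
                lo, hi = spec.length_range
                length = int(rng.integers(lo, hi + 1))
                seqs.append(
                    simulate_sequence(
                        model,
                        length,
                        burn_in=spec.burn_in,
                        seed=rng,
                        subject_id=subject,
                        trial_id=f"trial{k:03d}",
                    )
                )
            groups.append(BenchmarkGroup(order, model, tuple(seqs)))
    return BenchmarkDataset(spec, tuple(groups))


def generate_subject_fixture(
    order: int,
    params,
    n_trials: int = 30,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    seed: SeedLike | None = None,
    subject_id: str = "subject",
    burn_in: int = DEFAULT_BURN_IN,
) -> list[SymbolSequence]:
    """Per-subject trial fixture emulating the shape of fixation data:
    ~30 trials of 20-50 direction symbols from a single chain."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    model = MarkovModel(order, np.asarray(params, dtype=float))
    base = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length range")
    trials = []
    for k in range(n_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence(base.entropy, spawn_key=base.spawn_key + (k,))
        )
        length = int(rng.integers(lo, hi + 1))
        trials.append(
            simulate_sequence(
                model,
                length,
                burn_in=burn_in,
                seed=rng,
                subject_id=subject_id,
                trial_id=f"trial{k:03d}",
            )
        )
    return trials
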