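"""Order selection via deciban Bayes factors and a parsimony rule.

Every candidate order ``k >= 1`` is compared against the order-0 null by
``DB_k = 10 * log10(E_k / E_0)`` decibans, interpreted on the Jeffreys
scale.  Because the models are nested, data truly of order ``k`` also puts
evidence against the null at higher orders; the parsimony (Occam's razor)
rule therefore selects the *lowest* order whose evidence is within a
configurable margin of the best one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evidence import EvidenceResult, IntegrationSettings, integrated_log_evidence
from .stats import (
    ShortTrialError,
    SufficientStats,
    SymbolSequence,
    count_transitions,
    mle_transition_matrix,
    pool_stats,
)

logger = logging.getLogger(__name__)

_DB_PER_NAT = 10.0 / float(np.log(10.0))

#: Jeffreys deciban band upper edges and labels; values at or below the
#: first edge support the null hypothesis.
DEFAULT_JEFFREYS_BOUNDARIES = (0.0, 5.0, 10.0, 15.0, 20.0)
JEFFREYS_LABELS = (
    "supports null",
    "weak",
    "substantial",
    "strong",
    "very strong",
    "decisive",
)

#: Default parsimony margin: one Jeffreys interpretation band.
DEFAULT_PARSIMONY_MARGIN = 5.0


def bayes_factor_deciban(
    log_evidence_alt: float, log_evidence_null: float
) -> float:
    """Deciban Bayes factor, ``10 * log10`` of the evidence ratio."""
    if not (np.isfinite(log_evidence_alt) and np.isfinite(log_evidence_null)):
        raise ValueError(
            f"non-finite log evidence: alt={log_evidence_alt}, "
            f"null={log_evidence_null}"
        )
    return _DB_PER_NAT * (log_evidence_alt - log_evidence_null)


def jeffreys_category(
    db: float, boundaries: tuple[float, ...] = DEFAULT_JEFFREYS_BOUNDARIES
) -> str:
    """Jeffreys-scale label for a deciban value.

    Band edges are configurable but must be strictly increasing and match
    one fewer than the number of labels (weak through decisive above the
    null-support edge).
    """
    if not np.isfinite(db):
        raise ValueError(f"non-finite deciban value {db}")
    if len(boundaries) != len(JEFFREYS_LABELS) - 1 or any(
        b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])
    ):
        raise ValueError("boundaries must be strictly increasing, length 5")
    for edge, label in zip(boundaries, JEFFREYS_LABELS):
        if db <= edge:
            return label
    return JEFFREYS_LABELS[-1]


def select_parsimonious(
    decibans: dict[int, float], margin: float = DEFAULT_PARSIMONY_MARGIN
) -> int:
    """Smallest order whose deciban value is within ``margin`` of the best.

    ``decibans`` maps candidate orders to their deciban evidence against
    the null (the null itself enters as ``DB_0 = 0``).  With ``margin=0``
    this reduces to an argmax with lowest-order tie-breaking; with every
    ``DB_k <= 0`` it returns the null.
    """
    if not decibans:
        raise ValueError("no candidate orders")
    if margin < 0:
        raise ValueError("parsimony margin must be nonnegative")
    db_max = max(decibans.values())
    return min(k for k, v in decibans.items() if v >= db_max - margin - 1e-12)


def default_settings(
    max_order: int, seed: int = 0, prefactor_mode: str = "stationary"
) -> dict[int, IntegrationSettings]:
    """Per-order integration defaults.

    Orders 0-1 use the 100-point midpoint grid; order 2 (4 dimensions)
    uses a 30-point grid (8.1e5 stationary solves, seconds when batched);
    order 3 (8 dimensions) uses seeded Monte Carlo with 1e5 samples, since
    even a 10-point grid would be at the node budget.
    """
    per_dim = {0: 100, 1: 100, 2: 30}
    settings: dict[int, IntegrationSettings] = {}
    for order in range(max_order + 1):
        if order <= 2:
            settings[order] = IntegrationSettings(
                method="grid",
                grid_points_per_dim=per_dim[order],
                prefactor_mode=prefactor_mode,
                seed=seed,
            )
        else:
            settings[order] = IntegrationSettings(
                method="monte_carlo",
                mc_samples=100_000,
                prefactor_mode=prefactor_mode,
                seed=seed + order,
            )
    return settings


@dataclass(frozen=True)
class OrderEstimate:
    """Result of comparing all candidate orders on one subject's trials."""

    subject_id: str
    evidences: dict[int, EvidenceResult]
    decibans: dict[int, float]
    categories: dict[int, str]
    selected_order: int
    parsimony_margin: float
    warnings: tuple[str, ...] = field(default_factory=tuple)
    settings: dict[int, IntegrationSettings] = field(default_factory=dict)
    mle_order1: dict | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "evidences": {k: v.to_dict() for k, v in self.evidences.items()},
            "decibans": dict(self.decibans),
            "categories": dict(self.categories),
            "selected_order": self.selected_order,
            "parsimony_margin": self.parsimony_margin,
            "warnings": list(self.warnings),
            "settings": {
                k: {
                    "method": s.method,
                    "grid_points_per_dim": s.grid_points_per_dim,
                    "mc_samples": s.mc_samples,
                    "seed": s.seed,
                    "prefactor_mode": s.prefactor_mode,
                }
                for k, s in self.settings.items()
            },
            "mle_transition_order1": self.mle_order1,
        }


def _pool_for_order(
    sequences: list[SymbolSequence],
    order: int,
    short_trial_policy: str,
    warnings: list[str],
) -> SufficientStats:
    usable, dropped = [], []
    for seq in sequences:
        if order >= 1 and len(seq) < order + 1:
            dropped.append(seq)
        else:
            usable.append(seq)
    if dropped:
        names = ", ".join(f"{s.subject_id}/{s.trial_id}" for s in dropped)
        if short_trial_policy == "error":
            raise ShortTrialError(
                f"trials too short for order {order}: {names} "
                "(pass short_trial_policy='drop' to skip them)"
            )
        msg = f"order {order}: dropped short trials {names}"
        warnings.append(msg)
        logger.warning(msg)
    if not usable:
        raise ValueError(f"no trial is long enough for order {order}")
    return pool_stats([count_transitions(s, order) for s in usable])


def estimate_order(
    sequences: list[SymbolSequence],
    max_order: int = 3,
    settings: dict[int, IntegrationSettings] | IntegrationSettings | None = None,
    parsimony_margin: float = DEFAULT_PARSIMONY_MARGIN,
    prefactor_mode: str = "stationary",
    seed: int = 0,
    short_trial_policy: str = "error",
    jeffreys_boundaries: tuple[float, ...] = DEFAULT_JEFFREYS_BOUNDARIES,
) -> OrderEstimate:
    """Estimate the Markov order of one subject's pooled trials.

    Pools sufficient statistics per candidate order 0..``max_order``,
    computes each order's evidence, converts to decibans against the
    order-0 null (``DB_0 = 0`` by definition), and selects the smallest
    order whose deciban value lies within ``parsimony_margin`` of the
    maximum.  With all ``DB_k <= 0`` this reduces to the null.

    A warning is attached when a Monte Carlo evidence sits close enough to
    the selection threshold that a 3-standard-error shift could flip its
    inclusion in the candidate set.
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    if not 0 <= max_order:
        raise ValueError("max_order must be nonnegative")
    if parsimony_margin < 0:
        raise ValueError("parsimony margin must be nonnegative")
    subject = sequences[0].subject_id

    resolved = default_settings(max_order, seed=seed, prefactor_mode=prefactor_mode)
    if isinstance(settings, IntegrationSettings):
        resolved = {k: settings for k in resolved}
    elif settings:
        resolved.update(settings)

    warn_list: list[str] = []
    evidences: dict[int, EvidenceResult] = {}
    for order in range(max_order + 1):
        stats = _pool_for_order(sequences, order, short_trial_policy, warn_list)
        evidences[order] = integrated_log_evidence(stats, order, resolved[order])
        logger.info(
            "subject %s order %d: log evidence %.4f (%s)",
            subject,
            order,
            evidences[order].log_evidence,
            evidences[order].method,
        )

    log_e0 = evidences[0].log_evidence
    db = {0: 0.0}
    for order in range(1, max_order + 1):
        db[order] = bayes_factor_deciban(evidences[order].log_evidence, log_e0)
    categories = {
        k: jeffreys_category(v, jeffreys_boundaries) for k, v in db.items() if k > 0
    }

    db_max = max(db.values())
    threshold = db_max - parsimony_margin
    selected = select_parsimonious(db, parsimony_margin)

    for order, result in evidences.items():
        if result.mc_standard_error is None:
            continue
        db_se = _DB_PER_NAT * result.mc_standard_error
        if abs(db[order] - threshold) <= 3 * db_se:
            warn_list.append(
                f"order {order}: deciban value {db[order]:.2f} is within 3 "
                f"Monte Carlo standard errors ({3 * db_se:.2f} dB) of the "
                f"selection threshold {threshold:.2f}"
            )

    mle_order1 = None
    if max_order >= 1:
        stats1 = _pool_for_order(sequences, 1, "drop", [])
        mle = mle_transition_matrix(stats1)
        mle_order1 = {
            "eps_hat": [None if np.isnan(e) else float(e) for e in mle.eps_hat],
            "matrix": [
                [None if np.isnan(v) else float(v) for v in row]
                for row in mle.matrix
            ],
        }

    return OrderEstimate(
        subject_id=subject,
        evidences=evidences,
        decibans=db,
        categories=categories,
        selected_order=selected,
        parsimony_margin=parsimony_margin,
        warnings=tuple(warn_list),
        settings=resolved,
        mle_order1=mle_order1,
    )
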