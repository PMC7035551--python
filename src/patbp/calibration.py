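"""Advanced point-to-point-pairing (PTP) calibration.

Plain PTP calibration solves a BP-PAT model exactly from as many cuff-BP /
mean-PAT pairs as the model has unknowns.  Because a single cuff reading is
noisy, the advanced variant averages over repeated exact solutions: each
calibration *round* collects four pairs of (cuff BP, 30-s mean PAT); every
subset of the round of the model's required size is solved exactly (C(4,1),
C(4,2) or C(4,3) subsets for 1-, 2- and 3-point models), and the resulting
parameter sets are averaged arithmetically over all successful subsets of
all rounds (four rounds by default, about eight minutes of cuff use).
Subsets that are degenerate or have no real solution are skipped with a
recorded reason.  The averaged parameters are then frozen for the whole
monitoring session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import models as bpm
from .models import (
    BaselineState,
    ModelDomainError,
    ModelParams,
    calibrate_from_points,
    required_calibration_points,
)
from .signals import PATWindow
from .synth import CuffReading

__all__ = [
    "CalibPair",
    "CalibrationPlan",
    "CalibrationAudit",
    "CalibrationFailureError",
    "pair_cuff_with_pat",
    "advanced_ptp_calibrate",
]

logger = logging.getLogger(__name__)

DEFAULT_ROUNDS = 4
PAIRS_PER_ROUND = 4


@dataclass(frozen=True)
class CalibPair:
    """One cuff reading paired with the co-temporal 30-s mean PAT."""

    pat_bar: float  # s
    sbp_cuf: float  # mmHg
    dbp_cuf: float  # mmHg
    t_start: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.pat_bar <= 0:
            raise ValueError("pat_bar must be positive")
        if self.sbp_cuf <= self.dbp_cuf:
            raise ValueError("sbp_cuf must exceed dbp_cuf")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pat_bar, self.sbp_cuf, self.dbp_cuf)


@dataclass(frozen=True)
class CalibrationPlan:
    """Rounds of calibration pairs for one subject and model."""

    rounds: tuple[tuple[CalibPair, ...], ...]
    model: str
    gamma: float = bpm.DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.model not in bpm.MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}")
        if not self.rounds:
            raise ValueError("plan needs at least one round")
        rounds = tuple(tuple(sorted(r, key=lambda p: p.t_start)) for r in self.rounds)
        object.__setattr__(self, "rounds", rounds)

    @classmethod
    def from_pairs(cls, pairs: list[CalibPair], model: str,
                   gamma: float = bpm.DEFAULT_GAMMA,
                   pairs_per_round: int = PAIRS_PER_ROUND) -> "CalibrationPlan":
        """Chunk a time-ordered pair list into consecutive rounds."""
        if len(pairs) % pairs_per_round:
            raise ValueError(
                f"{len(pairs)} pairs do not divide into rounds of {pairs_per_round}")
        rounds = tuple(tuple(pairs[i:i + pairs_per_round])
                       for i in range(0, len(pairs), pairs_per_round))
        return cls(rounds=rounds, model=model, gamma=gamma)


@dataclass
class CalibrationAudit:
    """Per-subset bookkeeping from one advanced-PTP run."""

    n_subsets: int = 0
    n_success: int = 0
    skips: list[str] = field(default_factory=list)
    subset_params: list[ModelParams] = field(default_factory=list)


class CalibrationFailureError(RuntimeError):
    """No calibration subset succeeded."""


def pair_cuff_with_pat(cuff: list[CuffReading], windows: list[PATWindow],
                       max_offset: float = 5.0) -> tuple[list[CalibPair], int]:
    """Pair each cuff reading with the most-overlapping PAT window.

    Pairing is one-to-one and greedy in time order; a pairing is accepted
    only when the window start lies within ``max_offset`` seconds of the
    cuff start.  Returns the pairs plus the count of cuff readings that
    could not be paired.
    """
    pairs: list[CalibPair] = []
    unpaired = 0
    used: set[int] = set()
    for reading in cuff:
        if reading.sbp_cuf <= reading.dbp_cuf:
            # inverted reading (device error larger than the pulse
            # pressure): physically invalid, dropped and counted
            unpaired += 1
            continue
        best, best_overlap = None, 0.0
        for j, w in enumerate(windows):
            if j in used:
                continue
            overlap = min(reading.t_end, w.t_end) - max(reading.t_start, w.t_start)
            if overlap > best_overlap:
                best, best_overlap = j, overlap
        if best is None or abs(windows[best].t_start - reading.t_start) > max_offset:
            unpaired += 1
            continue
        used.add(best)
        pairs.append(CalibPair(pat_bar=windows[best].pat_bar,
                               sbp_cuf=reading.sbp_cuf, dbp_cuf=reading.dbp_cuf,
                               t_start=reading.t_start))
    if unpaired:
        logger.info("%d cuff readings left unpaired", unpaired)
    return pairs, unpaired


def _average_params(model: str, gamma: float,
                    param_sets: list[ModelParams]) -> ModelParams:
    if model in ("MK-BH", "dMK-BH"):
        sbp0 = float(np.mean([p.baseline.sbp0 for p in param_sets]))
        dbp0 = float(np.mean([p.baseline.dbp0 for p in param_sets]))
        pat0 = float(np.mean([p.baseline.pat0 for p in param_sets]))
        # PP0 / MBP0 are recomputed from the averaged anchors so the
        # baseline identities still hold after averaging
        return ModelParams(model, baseline=BaselineState(
            sbp0=sbp0, dbp0=dbp0, pat0=pat0, gamma=gamma))
    sbp = tuple(np.mean([p.sbp_coeffs for p in param_sets], axis=0))
    dbp = tuple(np.mean([p.dbp_coeffs for p in param_sets], axis=0))
    return ModelParams(model, tuple(map(float, sbp)), tuple(map(float, dbp)))


def advanced_ptp_calibrate(plan: CalibrationPlan) -> tuple[ModelParams, CalibrationAudit]:
    """Average exact PTP solutions over all subsets of all rounds.

    For each round, every subset of size ``required_calibration_points``
    is solved with :func:`patbp.models.calibrate_from_points`; degenerate
    and no-real-solution subsets are skipped (reasons recorded in the
    audit).  All scalar parameters are averaged arithmetically across the
    successful subsets of every round.

    Raises
    ------
    CalibrationFailureError
        When no subset of any round succeeds; the message lists the
        per-subset reasons.
    """
    k = required_calibration_points(plan.model)
    audit = CalibrationAudit()
    successes: list[ModelParams] = []
    for r_idx, rnd in enumerate(plan.rounds):
        if len(rnd) < k:
            raise ValueError(f"round {r_idx} has {len(rnd)} pairs, needs >= {k}")
        for subset in combinations(rnd, k):
            audit.n_subsets += 1
            try:
                params = calibrate_from_points(
                    plan.model, [p.as_tuple() for p in subset], gamma=plan.gamma)
            except ModelDomainError as exc:
                audit.skips.append(f"round {r_idx}: {exc}")
                logger.debug("skipping subset in round %d: %s", r_idx, exc)
                continue
            successes.append(params)
            audit.subset_params.append(params)
    audit.n_success = len(successes)
    if not successes:
        raise CalibrationFailureError(
            "no calibration subset succeeded: " + "; ".join(audit.skips))
    return _average_params(plan.model, plan.gamma, successes), audit
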