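"""Blood-pressure / pulse-arrival-time models and their exact calibration.

Five models relating a beat's pulse arrival time (PAT, seconds) to systolic
and diastolic blood pressure (mmHg) are implemented:

===========  =========================================================  ======
identifier   SBP channel                                                points
===========  =========================================================  ======
``MK-EE``    ``a1*ln(PAT) + b1``                                        2
``L-MK``     ``a2 + b2*PAT``                                            2
``MK-BH``    ``SBP0 - (2/(gamma*PAT0))*(PAT - PAT0)``                   1
``dMK-BH``   ``DBP + PP0*(PAT0/PAT)**2`` (DBP from MBP0 and gamma)      1
``M-M``      ``a3 + sqrt(b3 + c3/PAT**2)``                              3
===========  =========================================================  ======

The DBP channel of MK-EE / L-MK / M-M uses an independent coefficient set of
the same functional form.  MK-BH derives DBP from its own SBP estimate as
``SBP - PP0*(PAT0/PAT)**2``; dMK-BH evaluates DBP first as
``MBP0 + (2/gamma)*ln(PAT0/PAT) - (PP0/3)*(PAT0/PAT)**2`` and adds the pulse
pressure term back for SBP.  The first four are vascular-elasticity (VE)
models built on the Moens-Korteweg equation; M-M is an elastic-tube (ET)
model.  ``gamma`` is a vascular-state constant (mmHg^-1), 0.031 for healthy
young adults.

"Point-to-point pairing" calibration solves each model's parameters exactly
from as many (PAT, cuff-BP) pairs as the model has unknowns per channel:
1 for MK-BH/dMK-BH, 2 for MK-EE/L-MK, 3 for M-M.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "MODEL_IDS",
    "VE_MODELS",
    "ET_MODELS",
    "BaselineState",
    "ModelParams",
    "BPEstimate",
    "ModelDomainError",
    "DegenerateCalibrationError",
    "NoRealSolutionError",
    "required_calibration_points",
    "estimate_bp",
    "calibrate_from_points",
]

logger = logging.getLogger(__name__)

#: Closed set of model identifiers.
MODEL_IDS = ("MK-EE", "L-MK", "MK-BH", "dMK-BH", "M-M")
VE_MODELS = ("MK-EE", "L-MK", "MK-BH", "dMK-BH")
ET_MODELS = ("M-M",)

#: Default vascular-state parameter for healthy young adults (mmHg^-1).
DEFAULT_GAMMA = 0.031

_CALIB_POINTS = {"MK-EE": 2, "L-MK": 2, "MK-BH": 1, "dMK-BH": 1, "M-M": 3}


class ModelDomainError(ValueError):
    """A model was evaluated or calibrated outside its mathematical domain."""


class DegenerateCalibrationError(ModelDomainError):
    """Calibration points are degenerate (duplicate PATs, singular system)."""


class NoRealSolutionError(ModelDomainError):
    """The M-M radicand is negative: no real-valued solution exists."""


def _check_model(model: str) -> str:
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model id {model!r}; expected one of {MODEL_IDS}")
    return model


def required_calibration_points(model: str) -> int:
    """Number of (PAT, cuff-BP) pairs that determine the model exactly.

    MK-BH and dMK-BH need a single pair (it becomes the baseline state),
    the two-coefficient MK-EE and L-MK need two, and the three-coefficient
    M-M needs three.
    """
    return _CALIB_POINTS[_check_model(model)]


@dataclass(frozen=True)
class BaselineState:
    """Calibration anchor for the MK-BH and dMK-BH models.

    ``pp0`` and ``mbp0`` are derived quantities: pulse pressure
    ``SBP0 - DBP0`` and mean pressure ``SBP0/3 + 2*DBP0/3``.
    """

    sbp0: float
    dbp0: float
    pat0: float
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if not (self.sbp0 > self.dbp0 > 0):
            raise ValueError(f"need SBP0 > DBP0 > 0, got {self.sbp0}/{self.dbp0}")
        if self.pat0 <= 0:
            raise ValueError(f"PAT0 must be positive, got {self.pat0}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    @property
    def pp0(self) -> float:
        return self.sbp0 - self.dbp0

    @property
    def mbp0(self) -> float:
        return self.sbp0 / 3.0 + 2.0 * self.dbp0 / 3.0


@dataclass(frozen=True)
class ModelParams:
    """Fully-specified parameters of one BP-PAT model.

    ``sbp_coeffs`` / ``dbp_coeffs`` hold the per-channel coefficient tuples
    for MK-EE, L-MK ((a, b)) and M-M ((a, b, c)); MK-BH and dMK-BH carry a
    :class:`BaselineState` instead.
    """

    model: str
    sbp_coeffs: tuple[float, ...] | None = None
    dbp_coeffs: tuple[float, ...] | None = None
    baseline: BaselineState | None = None

    def __post_init__(self) -> None:
        _check_model(self.model)
        if self.model in ("MK-BH", "dMK-BH"):
            if self.baseline is None:
                raise ValueError(f"{self.model} requires a baseline state")
        else:
            n = 3 if self.model == "M-M" else 2
            for name, coeffs in (("sbp_coeffs", self.sbp_coeffs),
                                 ("dbp_coeffs", self.dbp_coeffs)):
                if coeffs is None or len(coeffs) != n:
                    raise ValueError(
                        f"{self.model} requires {n} coefficients in {name}")

    def to_json(self) -> str:
        d: dict = {"model": self.model}
        if self.baseline is not None:
            d["baseline"] = asdict(self.baseline)
        if self.sbp_coeffs is not None:
            d["sbp_coeffs"] = list(self.sbp_coeffs)
        if self.dbp_coeffs is not None:
            d["dbp_coeffs"] = list(self.dbp_coeffs)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        d = json.loads(text)
        baseline = BaselineState(**d["baseline"]) if "baseline" in d else None
        return cls(
            model=d["model"],
            sbp_coeffs=tuple(d["sbp_coeffs"]) if "sbp_coeffs" in d else None,
            dbp_coeffs=tuple(d["dbp_coeffs"]) if "dbp_coeffs" in d else None,
            baseline=baseline,
        )


@dataclass(frozen=True)
class BPEstimate:
    """One model-estimated (SBP, DBP) pair in mmHg."""

    sbp_est: float
    dbp_est: float


def _estimate_channel(model: str, coeffs: tuple[float, ...], pat: np.ndarray) -> np.ndarray:
    if model == "MK-EE":
        a, b = coeffs
        return a * np.log(pat) + b
    if model == "L-MK":
        a, b = coeffs
        return a + b * pat
    if model == "M-M":
        return _mm_forward(coeffs, pat)
    raise AssertionError(model)


def _mm_forward(coeffs: tuple[float, float, float], pat: np.ndarray) -> np.ndarray:
    # BP = a + sqrt(b + c/PAT^2); the radicand may go negative for some
    # PAT, in which case there is no real solution.
    a, b, c = coeffs
    radicand = b + c / pat**2
    if np.any(radicand < 0):
        raise NoRealSolutionError(
            f"M-M radicand negative (min {np.min(radicand):.4g}): no real solution")
    return a + np.sqrt(radicand)


def estimate_bp(params: ModelParams, pat: float | Sequence[float]) -> BPEstimate:
    """Evaluate a calibrated model at one or more PAT values.

    Parameters
    ----------
    params
        Complete model parameters.
    pat
        PAT in seconds, scalar or array; must be positive.

    Returns
    -------
    BPEstimate with scalar or array-valued channels (mmHg).

    Raises
    ------
    NoRealSolutionError
        If the M-M radicand is negative at any requested PAT.
    ModelDomainError
        If any output is non-finite.
    """
    pat_arr = np.asarray(pat, dtype=float)
    scalar = pat_arr.ndim == 0
    pat_arr = np.atleast_1d(pat_arr)
    if np.any(pat_arr <= 0):
        raise ValueError("PAT must be positive")

    m = params.model
    if m in ("MK-BH", "dMK-BH"):
        b = params.baseline
        ratio2 = (b.pat0 / pat_arr) ** 2
        if m == "MK-BH":
            sbp = b.sbp0 - (2.0 / (b.gamma * b.pat0)) * (pat_arr - b.pat0)
            dbp = sbp - b.pp0 * ratio2
        else:
            # algebraically identical to MBP0 + (2/g)ln(PAT0/PAT) - (PP0/3)r^2
            # and its SBP counterpart, but rearranged so both channels hit
            # the anchor (SBP0, DBP0) exactly at PAT = PAT0
            logr = np.log(b.pat0 / pat_arr)
            dbp = b.dbp0 + (2.0 / b.gamma) * logr + (b.pp0 / 3.0) * (1.0 - ratio2)
            sbp = b.sbp0 + (2.0 / b.gamma) * logr + (2.0 * b.pp0 / 3.0) * (ratio2 - 1.0)
    else:
        sbp = _estimate_channel(m, params.sbp_coeffs, pat_arr)
        dbp = _estimate_channel(m, params.dbp_coeffs, pat_arr)

    if not (np.all(np.isfinite(sbp)) and np.all(np.isfinite(dbp))):
        raise ModelDomainError(f"{m} produced non-finite blood pressure")
    if np.any(sbp <= dbp):
        # Physiologically impossible outputs are allowed in parts of the
        # models' domains but are worth surfacing.
        logger.warning("%s produced SBP <= DBP at %d of %d PAT values",
                       m, int(np.sum(sbp <= dbp)), sbp.size)
    if scalar:
        return BPEstimate(float(sbp[0]), float(dbp[0]))
    return BPEstimate(sbp, dbp)


# ---------------------------------------------------------------------------
# calibration (exact, point-to-point)

#: PATs closer than this relative spacing are degenerate for calibration
#: (rounding noise, not information).
_DUP_RTOL = 1e-9


def _check_distinct(pats: np.ndarray) -> None:
    scale = float(np.max(np.abs(pats)))
    p = np.sort(pats)
    if np.any(np.diff(p) <= _DUP_RTOL * scale):
        raise DegenerateCalibrationError("duplicate PAT values")


def _calibrate_loglinear(pats: np.ndarray, bps: np.ndarray) -> tuple[float, float]:
    _check_distinct(pats)
    l1, l2 = np.log(pats)
    a = (bps[0] - bps[1]) / (l1 - l2)
    return float(a), float(bps[0] - a * l1)


def _calibrate_linear(pats: np.ndarray, bps: np.ndarray) -> tuple[float, float]:
    _check_distinct(pats)
    b = (bps[0] - bps[1]) / (pats[0] - pats[1])
    return float(bps[0] - b * pats[0]), float(b)


def _calibrate_mm(pats: np.ndarray, bps: np.ndarray) -> tuple[float, float, float]:
    # (BP_i - a)^2 = b + c*u_i with u_i = 1/PAT_i^2.  Pairwise subtraction
    # eliminates b and leaves a 2x2 linear system in (a, c):
    #   2*(BP_i - BP_j)*a + (u_i - u_j)*c = BP_i^2 - BP_j^2
    _check_distinct(pats)
    u = 1.0 / pats**2
    A = np.array([[2.0 * (bps[0] - bps[1]), u[0] - u[1]],
                  [2.0 * (bps[1] - bps[2]), u[1] - u[2]]])
    rhs = np.array([bps[0]**2 - bps[1]**2, bps[1]**2 - bps[2]**2])
    if abs(np.linalg.det(A)) < 1e-12 * max(1.0, float(np.abs(A).max())**2):
        raise DegenerateCalibrationError("singular M-M calibration system")
    a, c = np.linalg.solve(A, rhs)
    b = (bps[0] - a) ** 2 - c * u[0]
    for bp_i, u_i in zip(bps, u):
        if b + c * u_i < 0:
            raise NoRealSolutionError(
                "M-M radicand negative at a calibration point: no real solution")
        if bp_i - a < 0:
            # The squared system admits the spurious branch BP = a - sqrt(.);
            # those parameters cannot reproduce the calibration points.
            raise NoRealSolutionError(
                "M-M calibration landed on the negative root branch")
    return float(a), float(b), float(c)


def calibrate_from_points(
    model: str,
    pairs: Sequence[tuple[float, float, float]],
    gamma: float = DEFAULT_GAMMA,
) -> ModelParams:
    """Solve a model's parameters exactly from minimal calibration pairs.

    Parameters
    ----------
    model
        Model identifier.
    pairs
        ``required_calibration_points(model)`` tuples
        ``(pat_bar, sbp_cuf, dbp_cuf)`` — a windowed mean PAT (s) with the
        cuff systolic/diastolic reading (mmHg) taken over the same window.
    gamma
        Vascular-state constant (mmHg^-1), used by MK-BH and dMK-BH only.

    The returned parameters reproduce every calibration pair exactly
    (to floating-point round-off) when re-evaluated with
    :func:`estimate_bp`.

    Raises
    ------
    DegenerateCalibrationError
        Duplicate PAT values (zero denominators / singular system).
    NoRealSolutionError
        M-M system has no real-valued solution at the given points.
    """
    _check_model(model)
    k = required_calibration_points(model)
    if len(pairs) != k:
        raise ValueError(f"{model} needs exactly {k} calibration pairs, got {len(pairs)}")
    arr = np.asarray(pairs, dtype=float)
    pats, sbps, dbps = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(pats <= 0):
        raise ValueError("calibration PATs must be positive")

    if model in ("MK-BH", "dMK-BH"):
        return ModelParams(
            model=model,
            baseline=BaselineState(sbp0=float(sbps[0]), dbp0=float(dbps[0]),
                                   pat0=float(pats[0]), gamma=gamma),
        )
    if model == "MK-EE":
        return ModelParams(model, _calibrate_loglinear(pats, sbps),
                           _calibrate_loglinear(pats, dbps))
    if model == "L-MK":
        return ModelParams(model, _calibrate_linear(pats, sbps),
                           _calibrate_linear(pats, dbps))
    return ModelParams(model, _calibrate_mm(pats, sbps), _calibrate_mm(pats, dbps))
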