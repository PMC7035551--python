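"""Model/Results front end for PAT-based BP estimation.

:class:`PATBPModel` is constructed from calibration data (cuff BP paired
with 30-s mean PAT), ``fit()`` runs the advanced point-to-point-pairing
calibration, and the returned :class:`PATBPResults` carries the frozen
parameters, the per-subset calibration audit, prediction and evaluation
methods, and a text ``summary()``.

Example
-------
>>> import pandas as pd
>>> from patbp import PATBPModel
>>> df = pd.DataFrame({"pat_bar": [0.250, 0.245, 0.252, 0.248],
...                    "sbp_cuf": [121.0, 123.5, 120.2, 122.1],
...                    "dbp_cuf": [79.0, 80.5, 78.6, 79.9]})
>>> res = PATBPModel.from_dataframe(df, model="dMK-BH").fit()
>>> bp = res.predict([0.24, 0.23])
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibPair,
    CalibrationAudit,
    CalibrationPlan,
    advanced_ptp_calibrate,
)
from .evaluation import PairedSeries, aami_verdict, error_summary, pearson_correlation
from .models import (
    DEFAULT_GAMMA,
    MODEL_IDS,
    ModelParams,
    estimate_bp,
    required_calibration_points,
)

__all__ = ["PATBPModel", "PATBPResults"]


class PATBPModel:
    """A BP-PAT estimation model awaiting calibration.

    Parameters
    ----------
    pairs
        Calibration data: ``CalibPair`` objects or ``(pat_bar, sbp, dbp)``
        tuples, time-ordered.  The number of pairs must divide into rounds
        of ``pairs_per_round``.
    model
        One of ``MK-EE``, ``L-MK``, ``MK-BH``, ``dMK-BH``, ``M-M``.
    gamma
        Vascular-state constant (mmHg^-1) for MK-BH / dMK-BH.
    """

    def __init__(self, pairs: Sequence, model: str = "dMK-BH",
                 gamma: float = DEFAULT_GAMMA, pairs_per_round: int = 4):
        if model not in MODEL_IDS:
            raise ValueError(f"unknown model {model!r}; choose from {MODEL_IDS}")
        self.pairs = [p if isinstance(p, CalibPair) else CalibPair(*p)
                      for p in pairs]
        self.model = model
        self.gamma = gamma
        self.pairs_per_round = pairs_per_round

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "dMK-BH",
                       gamma: float = DEFAULT_GAMMA, pairs_per_round: int | None = None,
                       pat_col: str = "pat_bar", sbp_col: str = "sbp_cuf",
                       dbp_col: str = "dbp_cuf") -> "PATBPModel":
        """Build the model from a calibration table.

        When ``pairs_per_round`` is omitted every row forms one round of
        its own... unless the row count is divisible by 4, in which case
        the conventional 4-pair rounds are used.
        """
        if pairs_per_round is None:
            pairs_per_round = 4 if len(df) % 4 == 0 else 1
        pairs = [CalibPair(pat_bar=float(r[pat_col]), sbp_cuf=float(r[sbp_col]),
                           dbp_cuf=float(r[dbp_col]),
                           t_start=float(r.get("t_start", i)))
                 for i, (_, r) in enumerate(df.iterrows())]
        return cls(pairs, model=model, gamma=gamma, pairs_per_round=pairs_per_round)

    def fit(self) -> "PATBPResults":
        """Run advanced PTP calibration and freeze the parameters."""
        plan = CalibrationPlan.from_pairs(self.pairs, self.model, gamma=self.gamma,
                                          pairs_per_round=self.pairs_per_round)
        params, audit = advanced_ptp_calibrate(plan)
        return PATBPResults(self, params, audit)


class PATBPResults:
    """Frozen calibration result with prediction and evaluation methods."""

    def __init__(self, model: PATBPModel, params: ModelParams,
                 audit: CalibrationAudit):
        self.model = model
        self.params = params
        self.audit = audit

    def predict(self, pat: float | Sequence[float]) -> pd.DataFrame:
        """Estimated SBP/DBP (mmHg) at the given PAT values (s)."""
        est = estimate_bp(self.params, np.atleast_1d(np.asarray(pat, float)))
        return pd.DataFrame({"sbp_est": np.atleast_1d(est.sbp_est),
                             "dbp_est": np.atleast_1d(est.dbp_est)})

    def evaluate(self, pat: Sequence[float], sbp_cuf: Sequence[float],
                 dbp_cuf: Sequence[float]) -> pd.DataFrame:
        """Error summary of the fitted model against reference cuff readings."""
        pred = self.predict(pat)
        rows = []
        for channel, est, cuf in (("SBP", pred["sbp_est"], sbp_cuf),
                                  ("DBP", pred["dbp_est"], dbp_cuf)):
            paired = PairedSeries(np.asarray(est, float), np.asarray(cuf, float))
            s = error_summary(paired)
            v = aami_verdict(s)
            r = (pearson_correlation(paired)
                 if paired.n >= 3 and np.ptp(paired.bp_est) > 0
                 and np.ptp(paired.bp_cuf) > 0 else np.nan)
            rows.append({"channel": channel, "n": s.n, "me": s.me, "sd": s.sd,
                         "mad": s.mad, "sse": s.sse, "sigma": s.sigma,
                         "cv": np.nan if s.cv is None else s.cv, "rmse": s.rmse,
                         "r": r, "aami_pass": v.passed})
        return pd.DataFrame(rows).set_index("channel")

    def _param_rows(self) -> list[tuple[str, float]]:
        p = self.params
        if p.baseline is not None:
            b = p.baseline
            return [("SBP0 (mmHg)", b.sbp0), ("DBP0 (mmHg)", b.dbp0),
                    ("PAT0 (s)", b.pat0), ("PP0 (mmHg)", b.pp0),
                    ("MBP0 (mmHg)", b.mbp0), ("gamma (mmHg^-1)", b.gamma)]
        names = "abc"
        rows = [(f"{names[i]} (SBP)", v) for i, v in enumerate(p.sbp_coeffs)]
        rows += [(f"{names[i]}' (DBP)", v) for i, v in enumerate(p.dbp_coeffs)]
        return rows

    def summary(self) -> str:
        """Human-readable calibration summary."""
        lines = [
            "Advanced PTP calibration results",
            "=" * 44,
            f"{'Model:':<28}{self.params.model}",
            f"{'Calibration pairs:':<28}{len(self.model.pairs)}",
            f"{'Rounds:':<28}{len(self.model.pairs) // self.model.pairs_per_round}",
            f"{'Points per exact solution:':<28}"
            f"{required_calibration_points(self.params.model)}",
            f"{'Subsets solved:':<28}{self.audit.n_success}/{self.audit.n_subsets}",
            "-" * 44,
        ]
        for name, value in self._param_rows():
            lines.append(f"{name:<28}{value:>16.6g}")
        if self.audit.skips:
            lines.append("-" * 44)
            lines.append(f"Skipped subsets: {len(self.audit.skips)}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<PATBPResults model={self.params.model} "
                f"subsets={self.audit.n_success}/{self.audit.n_subsets}>")
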