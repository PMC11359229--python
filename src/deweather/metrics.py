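"""Model-evaluation statistics for paired observed/predicted series.

The headline metric is Willmott's index of agreement (IOA),

    d = 1 - sum((P_i - O_i)^2) / sum((|P_i - Obar| + |O_i - Obar|)^2),

which is 1 for perfect prediction and 0 for a predictor constant at the
observed mean — unlike R², it penalises bias and anti-correlation.  The
supporting suite is MBE, MAE, RMSE and their observed-mean-normalised
counterparts NMBE, NMAE (= NME) and NRMSE, reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["MetricReport", "index_of_agreement", "error_metrics", "pearson_r2"]


@dataclass(frozen=True)
class MetricReport:
    """Evaluation statistics over n paired complete observations.

    Absolute errors are in the units of the series (µg/m³ for NO2);
    normalised errors are percentages of the observed mean.
    """

    n: int
    ioa: float
    mbe: float
    nmbe: float
    mae: float
    nmae: float
    rmse: float
    nrmse: float
    r2: float

    @property
    def nme(self) -> float:
        """Alias: normalised mean error equals NMAE under equal-n sums."""
        return self.nmae

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n, "ioa": self.ioa, "mbe": self.mbe, "nmbe": self.nmbe,
            "mae": self.mae, "nmae": self.nmae, "rmse": self.rmse,
            "nrmse": self.nrmse, "r2": self.r2,
        }


def _paired(obs, pred, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape:
        raise ValidationError(f"obs and pred lengths differ: {o.shape} vs {p.shape}")
    keep = ~(np.isnan(o) | np.isnan(p))
    o, p = o[keep], p[keep]
    if o.size < min_n:
        raise ValidationError(f"need at least {min_n} paired complete values, got {o.size}")
    return o, p


def index_of_agreement(obs, pred) -> float:
    """Willmott's index of agreement d (quadratic form); d <= 1."""
    o, p = _paired(obs, pred)
    obar = o.mean()
    num = np.sum((p - o) ** 2)
    if np.all(o == obar):  # constant observations: d degenerates
        if num == 0.0:
            return 1.0  # matched exactly
        raise ValidationError("index of agreement undefined: observations are constant")
    den = np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2)
    return float(1.0 - num / den)


def pearson_r2(x, y) -> float:
    """Squared Pearson product-moment correlation."""
    a, b = _paired(x, y, min_n=3)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValidationError("pearson_r2 undefined: a series has zero variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def error_metrics(obs, pred) -> MetricReport:
    """Full metric suite; normalised metrics are percent of the observed mean."""
    o, p = _paired(obs, pred)
    obar = o.mean()
    if obar == 0.0:
        raise ValidationError("normalised metrics undefined: observed mean is zero")
    err = p - o
    mbe = float(err.mean())
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    if o.size >= 3 and np.std(o) > 0.0 and np.std(p) > 0.0:
        r2 = pearson_r2(o, p)
    else:
        r2 = float("nan")
    ioa = index_of_agreement(o, p) if np.std(o) > 0.0 or mae == 0.0 else float("nan")
    return MetricReport(
        n=int(o.size),
        ioa=ioa,
        mbe=mbe,
        nmbe=100.0 * mbe / obar,
        mae=mae,
        nmae=100.0 * mae / obar,
        rmse=rmse,
        nrmse=100.0 * rmse / obar,
        r2=r2,
    )
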