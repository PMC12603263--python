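"""Dose-response models of contamination index versus spiked cell count.

Two empirical descriptors are fitted: an ordinary least-squares line
CI = m * count + c, and a power law CI = a * count ** b obtained by least
squares on the log-log scale.  On an unsaturated workflow the index rises
linearly with cell count; dynamic-range-compressing (bead) workflows bend
the curve concave — a power law with exponent b < 1 — reflecting saturation
at high contamination.

Model comparison is performed on the raw CI scale over the shared
positive-count points (log-log and raw R^2 are not comparable), with a
small-sample-corrected AIC as tie-break; both models carry the same
parameter count, so in practice the lower raw residual sum of squares wins.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import stats

__all__ = ["DoseResponseFit", "fit_linear", "fit_power_law", "compare_models"]


@dataclasses.dataclass
class DoseResponseFit:
    model: str                      # "linear" or "power"
    params: dict[str, float]        # {m, c} or {a, b}
    r2: float                       # on the model's fitting scale
    n_points: int
    pearson_r: float | None = None  # raw-scale Pearson r (linear fit)
    degenerate: bool = False        # zero total variance convention r2 = 0
    n_dropped: int = 0              # nonpositive pairs removed (power fit)

    def predict(self, counts) -> np.ndarray:
        x = np.asarray(counts, dtype=float)
        if self.model == "linear":
            return self.params["m"] * x + self.params["c"]
        return self.params["a"] * np.power(x, self.params["b"])


def _finite_pairs(counts, cis):
    x = np.asarray(counts, dtype=float)
    y = np.asarray(cis, dtype=float)
    if x.shape != y.shape:
        raise ValueError("counts and cis must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def fit_linear(counts, cis) -> DoseResponseFit:
    """OLS line CI = m * count + c with raw-scale R^2 and Pearson r."""
    x, y = _finite_pairs(counts, cis)
    if x.size < 3:
        raise ValueError("fit_linear needs at least 3 finite pairs")
    if np.ptp(x) == 0:
        raise ValueError("fit_linear needs variation in cell counts")
    if np.ptp(y) == 0:
        # constant response: slope 0, total variance 0 -> r2 = 0 by convention
        return DoseResponseFit(
            "linear", {"m": 0.0, "c": float(y[0])}, r2=0.0,
            n_points=int(x.size), pearson_r=0.0, degenerate=True,
        )
    res = stats.linregress(x, y)
    return DoseResponseFit(
        "linear",
        {"m": float(res.slope), "c": float(res.intercept)},
        r2=float(res.rvalue**2),
        n_points=int(x.size),
        pearson_r=float(res.rvalue),
    )


def fit_power_law(counts, cis) -> DoseResponseFit:
    """Power law CI = a * count**b via least squares on log10-log10.

    Pairs with nonpositive count or CI are dropped (and counted); R^2 is
    reported on the log-log fitting scale.
    """
    x, y = _finite_pairs(counts, cis)
    positive = (x > 0) & (y > 0)
    n_dropped = int(x.size - positive.sum())
    x, y = x[positive], y[positive]
    if x.size < 3:
        raise ValueError("fit_power_law needs at least 3 positive pairs")
    if np.ptp(x) == 0:
        raise ValueError("fit_power_law needs variation in cell counts")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(ly) == 0:
        return DoseResponseFit(
            "power", {"a": float(10.0 ** ly[0]), "b": 0.0}, r2=0.0,
            n_points=int(x.size), degenerate=True, n_dropped=n_dropped,
        )
    res = stats.linregress(lx, ly)
    return DoseResponseFit(
        "power",
        {"a": float(10.0**res.intercept), "b": float(res.slope)},
        r2=float(res.rvalue**2),
        n_points=int(x.size),
        n_dropped=n_dropped,
    )


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def compare_models(counts, cis) -> dict:
    """Fit both models and pick the better raw-scale description.

    Each model is fitted on its natural domain (linear: all finite pairs,
    zero counts included; power: positive pairs only), then both are
    evaluated on the shared positive-pair subset on the raw CI scale so
    residuals are comparable.  Preference goes to the lower raw-scale
    residual sum of squares, reported together with the AICc margin.  If one
    fit fails, the comparison degrades to the surviving model with a
    warning.
    """
    x, y = _finite_pairs(counts, cis)
    positive = (x > 0) & (y > 0)
    xs, ys = x[positive], y[positive]
    linear = power = None
    try:
        linear = fit_linear(x, y)
    except ValueError as err:
        warnings.warn(f"linear fit failed: {err}")
    try:
        power = fit_power_law(xs, ys)
    except ValueError as err:
        warnings.warn(f"power-law fit failed: {err}")
    if linear is None and power is None:
        raise ValueError("both model fits failed")
    out = {"linear": linear, "power": power, "n_shared": int(xs.size)}
    if linear is None or power is None:
        surviving = "linear" if linear is not None else "power"
        out.update(preferred=surviving, note="comparison degraded: one fit failed",
                   delta_aicc=np.nan)
        return out
    k = 3  # slope/exponent + intercept/prefactor + residual variance
    rss_lin = float(np.sum((ys - linear.predict(xs)) ** 2))
    rss_pow = float(np.sum((ys - power.predict(xs)) ** 2))
    aicc_lin = _aicc(rss_lin, xs.size, k)
    aicc_pow = _aicc(rss_pow, xs.size, k)
    if rss_lin == rss_pow:
        preferred = "linear" if aicc_lin <= aicc_pow else "power"
    else:
        preferred = "linear" if rss_lin < rss_pow else "power"
    out.update(
        preferred=preferred,
        rss_linear=rss_lin,
        rss_power=rss_pow,
        aicc_linear=aicc_lin,
        aicc_power=aicc_pow,
        delta_aicc=aicc_lin - aicc_pow,
        note="",
    )
    return out
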