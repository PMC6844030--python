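"""Global contamination estimation from HAMA allele frequencies.

At a catalog site, the expected allele frequency scales linearly with the
global contamination fraction alpha:

    H_f = alpha * H_c                (per-site prediction)
    alpha = H_f / H_c                (per-site inversion)

Aggregated over the common catalog, the median H_f of one sample is itself
linear in alpha with a dataset-level coefficient (the average H_c of the
catalog under the sample's coverage profile), so a single sample's
contamination can be estimated as

    alpha_hat = median(H_f) / coefficient

The default coefficient is 0.7519, the value derived from whole-exome
human/mouse mixtures; ``calibrate`` re-derives it for any other data by an
origin-constrained least-squares fit of median H_f against known alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_COEFFICIENT = 0.7519
MIN_STABLE_SITES = 100


@dataclass(frozen=True)
class CalibrationModel:
    """Linear (through-origin) map from contamination level to median H_f."""

    coefficient: float = DEFAULT_COEFFICIENT
    fit_points: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    ci95: tuple[float, float] | None = None

    def __post_init__(self):
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")


def predict_hf(alpha: float, h_c: float) -> float:
    """Expected site allele frequency at contamination ``alpha``."""
    return alpha * h_c


def estimate_alpha_at_site(h_f: float, h_c: float) -> float:
    """Invert the per-site relation; undefined when H_c is zero."""
    if h_c <= 0:
        raise ValueError("H_c must be positive to invert H_f = alpha * H_c")
    return h_f / h_c


def estimate_alpha(
    hf_values: Sequence[float],
    model: CalibrationModel | None = None,
    min_sites: int = MIN_STABLE_SITES,
) -> float:
    """Single-sample contamination estimate: median(H_f) / coefficient.

    The result is clamped to [0, 1] (with a warning if the raw ratio fell
    outside). Fewer than ``min_sites`` values triggers an instability
    warning; an empty input is an error.
    """
    hf = np.asarray(hf_values, dtype=float)
    if hf.size == 0:
        raise ValueError("hf_values must be non-empty")
    if hf.size < min_sites:
        logger.warning("only %d H_f values; estimate may be unstable", hf.size)
    model = model or CalibrationModel()
    alpha_hat = float(np.median(hf)) / model.coefficient
    if alpha_hat > 1.0 or alpha_hat < 0.0:
        logger.warning("alpha estimate %.4f outside [0, 1]; clamped", alpha_hat)
    return float(np.clip(alpha_hat, 0.0, 1.0))


def calibrate(fit_points: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Fit the median-H_f coefficient on (alpha_true, median_hf) points.

    Least squares through the origin: coefficient = sum(a*m) / sum(a^2).
    The 95% interval of estimation error is taken from leave-one-out
    residuals of the implied alpha estimates.
    """
    pts = [(float(a), float(m)) for a, m in fit_points]
    alphas = np.array([a for a, _ in pts])
    medians = np.array([m for _, m in pts])
    if len(set(alphas.tolist())) < 2:
        raise ValueError("calibration needs at least two distinct alpha levels")
    if np.any(alphas <= 0):
        raise ValueError("alpha_true values must be positive")
    coefficient = float(np.dot(alphas, medians) / np.dot(alphas, alphas))

    residuals = []
    for i in range(len(pts)):
        mask = np.arange(len(pts)) != i
        a, m = alphas[mask], medians[mask]
        if len(set(a.tolist())) < 2:
            continue
        coef_i = float(np.dot(a, m) / np.dot(a, a))
        residuals.append(medians[i] / coef_i - alphas[i])
    ci95 = None
    if residuals:
        ci95 = (float(np.percentile(residuals, 2.5)), float(np.percentile(residuals, 97.5)))
    return CalibrationModel(coefficient=coefficient, fit_points=tuple(pts), ci95=ci95)
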