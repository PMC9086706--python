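"""Log-normal laws fitted to median [IQR] summaries.

Cohort tables report right-skewed quantities as median [Q1-Q3].  A
log-normal law is identified exactly by those three numbers: on the log
scale the quartiles are symmetric around the median, so

    mu    = ln(median)
    sigma = ln(Q3/Q1) / (2 * z_0.75)

with z_0.75 = Phi^-1(0.75) ~= 0.67449.  The fitted law reproduces the
input median exactly and the quartile ratio Q3/Q1 exactly; when the
printed quartiles are not exactly log-symmetric around the median the
ratio (spread), not the individual quartiles, is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

# Phi^-1(0.75)
Z75 = 0.6744897501960817


@dataclass(frozen=True)
class DistributionSpec:
    """A log-normal law on the positive reals, parameterised on the log scale."""

    mu: float
    sigma: float
    family: str = "log-normal"

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    @property
    def quartiles(self) -> tuple[float, float, float]:
        half = Z75 * self.sigma
        return (
            math.exp(self.mu - half),
            math.exp(self.mu),
            math.exp(self.mu + half),
        )

    @property
    def mean(self) -> float:
        return math.exp(self.mu + 0.5 * self.sigma**2)

    @property
    def sd(self) -> float:
        return self.mean * math.sqrt(math.expm1(self.sigma**2))

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return np.exp(self.mu + self.sigma * rng.standard_normal(size))

    def from_latent(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal latent draws through the law (copula use)."""
        return np.exp(self.mu + self.sigma * np.asarray(z))


def fit_lognormal_from_median_iqr(median: float, q1: float, q3: float) -> DistributionSpec:
    """Fit a log-normal law to a median [Q1-Q3] summary.

    Parameters
    ----------
    median, q1, q3
        Positive reals with q1 < median < q3.

    Returns
    -------
    DistributionSpec
        Law with exp(mu) == median and sigma == ln(q3/q1)/(2 z_0.75).
    """
    vals = {"q1": q1, "median": median, "q3": q3}
    for name, v in vals.items():
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name}={v!r} must be a positive finite number")
    if not (q1 < median < q3):
        raise ValueError(
            f"quartile ordering violated: need q1 < median < q3, got "
            f"q1={q1} median={median} q3={q3}"
        )
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2.0 * Z75)
    return DistributionSpec(mu=mu, sigma=sigma)


def truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size=None
) -> np.ndarray:
    """Draw from Normal(mean, sd) truncated to [low, high] by rejection."""
    out = rng.normal(mean, sd, size=size)
    arr = np.atleast_1d(np.asarray(out, dtype=float))
    bad = (arr < low) | (arr > high)
    # rejection loop; acceptance probability is ~1 for the BSA default
    while bad.any():
        arr[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (arr < low) | (arr > high)
    return float(arr[0]) if np.isscalar(out) or out is None or np.ndim(out) == 0 else arr.reshape(np.shape(out))
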