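"""Comparing validity correlations.

Two situations arise when benchmarking a text-based score against a rating
scale:

* two *dependent overlapping* correlations — two prediction vectors (e.g.
  all-questions features vs the best single question) correlated with the
  same observed score, compared with Steiger's (1980) modified Fisher-z
  statistic, which corrects for the correlation between the two predictors;
* two *independent* correlations — e.g. the model's validity r against the
  scale's test-retest reliability estimated on a different sample, compared
  with the classic Fisher-z two-sample statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationComparison",
    "fisher_transform",
    "compare_independent",
    "compare_dependent_overlapping",
]


@dataclass(frozen=True)
class CorrelationComparison:
    method: str
    z: float
    p_one_sided: float
    p_two_sided: float
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "z": self.z,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "inputs": self.inputs,
        }


def fisher_transform(r: float) -> float:
    """Fisher's variance-stabilizing z-transform, atanh(r)."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def compare_independent(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Fisher z-test for correlations from two independent samples.

    z = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3) + 1/(n2−3)).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples must have n > 3")
    z = (fisher_transform(r1) - fisher_transform(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return CorrelationComparison(
        method="independent",
        z=float(z),
        p_one_sided=float(stats.norm.sf(abs(z))),
        p_two_sided=float(2 * stats.norm.sf(abs(z))),
        inputs={"r1": r1, "n1": n1, "r2": r2, "n2": n2},
    )


def _check_psd(r1y: float, r2y: float, r12: float) -> None:
    m = np.array([[1.0, r12, r1y], [r12, 1.0, r2y], [r1y, r2y, 1.0]])
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")


def compare_dependent_overlapping(
    r1y: float, r2y: float, r12: float, n: int
) -> CorrelationComparison:
    """Steiger's (1980) Z for two correlations sharing the variable y.

    Both correlations with y are Fisher-transformed; their difference is
    scaled by a covariance term that grows with the inter-predictor
    correlation r12, evaluated at the mean of r1y and r2y:

        Z = (z1 − z2) · sqrt((n − 3) / (2 (1 − s̄)))

    where s̄ = ψ̄ / (1 − r̄²)² with r̄ = (r1y + r2y)/2 and

        ψ̄ = r12 (1 − 2 r̄²) − r̄² (1 − 2 r̄² − r12²) / 2.

    Sign convention: Z has the sign of r1y − r2y.
    """
    if n <= 3:
        raise ValueError("n must be > 3")
    for name, r in (("r1y", r1y), ("r2y", r2y), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"|{name}| must be < 1")
    _check_psd(r1y, r2y, r12)
    z1, z2 = fisher_transform(r1y), fisher_transform(r2y)
    rbar = (r1y + r2y) / 2.0
    cov = (r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)) / (
        (1 - rbar**2) ** 2
    )
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    return CorrelationComparison(
        method="dependent_overlapping",
        z=float(z),
        p_one_sided=float(stats.norm.sf(abs(z))),
        p_two_sided=float(2 * stats.norm.sf(abs(z))),
        inputs={"r1y": r1y, "r2y": r2y, "r12": r12, "n": n},
    )
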