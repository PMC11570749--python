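"""Degree distributions for LT/Raptor-style fountain codes.

A degree distribution is a probability vector over packet degrees 1..40.
To be usable for encoding it must satisfy four constraints: every entry
in [0, 1); entries sum to 1; degree 1 has positive mass (decodability);
and at least two degrees are active.  ``enforce_constraints`` projects an
arbitrary real vector onto this set; the standard Raptor table and the
robust soliton family are provided as baselines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MAX_DEGREE",
    "DegreeDistribution",
    "enforce_constraints",
    "raptor_rfc5053",
    "robust_soliton",
    "builtin_distributions",
]

MAX_DEGREE = 40
_EPS = 1e-6  # minimal mass forced onto degree 1 before normalization

# Standard Raptor degree table: cumulative thresholds out of 2^20 at the
# degrees 1, 2, 3, 4, 10, 11, 40 (all other degrees carry zero mass).
_RAPTOR_CDF = {
    1: 10241,
    2: 491582,
    3: 712794,
    4: 831695,
    10: 948446,
    11: 1032189,
    40: 1048576,
}


@dataclass(frozen=True)
class DegreeDistribution:
    """Probability vector over degrees 1..40 (index 0 holds degree 1)."""

    probs: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (MAX_DEGREE,):
            raise ValueError(f"need exactly {MAX_DEGREE} entries, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite probability")
        if np.any(p < 0) or np.any(p >= 1):
            raise ValueError("entries must lie in [0, 1)")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        if p[0] <= 0:
            raise ValueError("degree 1 must have positive probability")
        if np.count_nonzero(p) < 2:
            raise ValueError("need at least 2 active degrees")
        object.__setattr__(self, "probs", tuple(float(x) for x in p))
        object.__setattr__(self, "_array", p.copy())
        object.__setattr__(self, "_cdf", np.cumsum(p))

    @property
    def array(self) -> np.ndarray:
        return self._array.copy()

    @property
    def cdf(self) -> np.ndarray:
        return self._cdf

    def prob(self, degree: int) -> float:
        return self.probs[degree - 1]

    def sample_degree(self, u: float) -> int:
        """Inverse-CDF lookup: uniform u in [0,1) -> degree 1..40."""
        return int(np.searchsorted(self.cdf, u, side="right")) + 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"degrees": list(self.probs)}))

    @classmethod
    def from_json(cls, path: str | Path) -> "DegreeDistribution":
        data = json.loads(Path(path).read_text())
        return cls(tuple(data["degrees"]))


def enforce_constraints(raw, rng: np.random.RandomState) -> DegreeDistribution:
    """Project an arbitrary length-40 real vector onto the valid set.

    Min-max clipping to [0, 1), a forced floor on degree 1, activation of
    a random extra degree when fewer than two are active, then
    normalization.  Idempotent on already-valid distributions up to
    normalization tolerance.
    """
    p = np.asarray(raw, dtype=float).copy()
    if p.shape != (MAX_DEGREE,):
        raise ValueError(f"need exactly {MAX_DEGREE} entries")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite input")
    np.clip(p, 0.0, 1.0 - _EPS, out=p)
    if p[0] < _EPS:
        p[0] = _EPS
    if np.count_nonzero(p) < 2:
        idx = int(rng.randint(1, MAX_DEGREE))
        p[idx] = max(p[idx], rng.uniform(0.01, 0.1))
    p /= p.sum()
    # renormalization can only shrink entries below 1 since >= 2 are active
    return DegreeDistribution(tuple(p))


def raptor_rfc5053() -> DegreeDistribution:
    """The standard Raptor degree distribution (mass at 1,2,3,4,10,11,40)."""
    p = np.zeros(MAX_DEGREE)
    prev = 0
    for deg, cum in sorted(_RAPTOR_CDF.items()):
        p[deg - 1] = (cum - prev) / 1048576
        prev = cum
    return DegreeDistribution(tuple(p))


def robust_soliton(n: int, c: float = 0.025, delta: float = 0.001) -> DegreeDistribution:
    """Robust soliton distribution over n symbols, folded to degrees <= 40.

    Closed form: ideal soliton rho plus the spike term tau with
    R = c * ln(n/delta) * sqrt(n); mass at degrees above 40 is truncated
    and the vector renormalized, since packets here carry at most 40
    chunks.
    """
    if n < 2 or c <= 0 or not (0 < delta < 1):
        raise ValueError("need n >= 2, c > 0, 0 < delta < 1")
    rho = np.zeros(n + 1)
    rho[1] = 1.0 / n
    for d in range(2, n + 1):
        rho[d] = 1.0 / (d * (d - 1))
    R = c * math.log(n / delta) * math.sqrt(n)
    tau = np.zeros(n + 1)
    spike = max(int(round(n / R)), 1) if R > 0 else n
    spike = min(spike, n)
    for d in range(1, spike):
        tau[d] = R / (d * n)
    tau[spike] = R * math.log(R / delta) / n if R > delta else 0.0
    mu = rho + tau
    mu /= mu.sum()
    p = np.zeros(MAX_DEGREE)
    upper = min(n, MAX_DEGREE)
    p[:upper] = mu[1 : upper + 1]
    p /= p.sum()
    return DegreeDistribution(tuple(p))


def builtin_distributions(n: int = 100, c: float = 0.025, delta: float = 0.001):
    """Named baseline distributions."""
    return {
        "raptor_rfc5053": raptor_rfc5053(),
        "robust_soliton": robust_soliton(n, c, delta),
    }
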