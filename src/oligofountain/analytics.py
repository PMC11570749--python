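"""Closed-form and dynamic-programming analyses of the packet space.

Exact counting of homopolymer-containing seed images, coupon-collector
duplicate arithmetic for per-degree packet uniqueness, binomial ceilings
on unique payloads, seed-space capacity estimates, and quaternary Shannon
entropy.  All combinatorial counts use arbitrary-precision integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .distributions import MAX_DEGREE, DegreeDistribution
from .rules import bytes_to_dna, dna_codes

__all__ = [
    "SeedSpaceReport",
    "count_runs_at_least",
    "count_run_free",
    "seed_space_report",
    "coupon_expected_draws",
    "expected_unique",
    "degree_ceilings",
    "capacity_estimate",
    "quaternary_entropy",
]

EULER_GAMMA = 0.57721


@dataclass(frozen=True)
class SeedSpaceReport:
    """How much of a seed space is lost to homopolymer runs alone."""

    seed_len_nt: int
    run_threshold: int
    violating_count: int

    @property
    def total(self) -> int:
        return 4**self.seed_len_nt

    @property
    def violating_fraction(self) -> float:
        return self.violating_count / self.total


def count_run_free(length_nt: int, run: int) -> int:
    """Quaternary strings of given length with every run shorter than ``run``.

    Linear recurrence f(m) = 3 * sum_{j=1..run-1} f(m-j): a run-free
    string ends in a maximal run of some length j < run preceded by a
    different base (factor 3); short strings are unconstrained (4^m).
    Integer-exact.
    """
    if length_nt < 1 or run < 2:
        raise ValueError("need length_nt >= 1 and run >= 2")
    f = [0] * (length_nt + 1)
    f[0] = 1
    for m in range(1, length_nt + 1):
        if m < run:
            f[m] = 4**m
        else:
            f[m] = 3 * sum(f[m - j] for j in range(1, run))
    return f[length_nt]


def count_runs_at_least(length_nt: int, run: int) -> int:
    """Quaternary strings containing >= one homopolymer run of length >= run."""
    return 4**length_nt - count_run_free(length_nt, run)


def seed_space_report(seed_len_nt: int, run_threshold: int) -> SeedSpaceReport:
    return SeedSpaceReport(
        seed_len_nt=seed_len_nt,
        run_threshold=run_threshold,
        violating_count=count_runs_at_least(seed_len_nt, run_threshold),
    )


def coupon_expected_draws(n_unique: int, exact: bool = True) -> float:
    """Expected draws (with replacement) to collect all ``n_unique`` coupons.

    Exact: n * H_n (harmonic sum).  Approximate: n * (ln n + gamma) with
    Euler's constant gamma = 0.57721.
    """
    if n_unique < 1:
        raise ValueError("n_unique must be >= 1")
    if exact:
        return n_unique * float(sum(Fraction(1, k) for k in range(1, n_unique + 1)))
    return n_unique * (math.log(n_unique) + EULER_GAMMA)


def expected_unique(n_unique: int, draws: int) -> float:
    """Expected distinct coupons after ``draws`` uniform draws:
    n * (1 - (1 - 1/n)^N)."""
    if n_unique < 1 or draws < 0:
        raise ValueError("need n_unique >= 1 and draws >= 0")
    return n_unique * (1.0 - (1.0 - 1.0 / n_unique) ** draws)


def degree_ceilings(
    n: int, dist: DegreeDistribution, seed_space: int
) -> dict[int, dict[str, float]]:
    """Per-degree uniqueness ceilings C(n, d) vs. expected generation.

    ``expected_generated = seed_space * probs[d]``; a degree is flagged
    as duplicate-forcing when expectation exceeds the ceiling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    table: dict[int, dict[str, float]] = {}
    for d in range(1, MAX_DEGREE + 1):
        ceiling = math.comb(n, d) if d <= n else 0
        expected = seed_space * dist.prob(d)
        table[d] = {
            "ceiling": ceiling,
            "expected_generated": expected,
            "duplicate_forcing": expected > ceiling,
        }
    return table


def capacity_estimate(seed_bits: int, chunk_bytes: int, valid_fraction: float) -> int:
    """Maximum storable bytes: floor(2^seed_bits * chunk_bytes * fraction).

    The fraction is snapped to its shortest decimal rational so that
    printed fractions like 0.468 floor exactly (binary floats round a
    hair below and would lose the last byte).
    """
    if seed_bits < 1 or chunk_bytes < 1 or not 0 <= valid_fraction <= 1:
        raise ValueError("invalid capacity parameters")
    frac = Fraction(valid_fraction).limit_denominator(10**9)
    return int((1 << seed_bits) * chunk_bytes * frac)


def quaternary_entropy(data: bytes | str) -> float:
    """Shannon entropy (log base 2) over empirical base frequencies.

    Byte input is translated to DNA first; maximum is 2 bits/base for a
    uniform base composition.  0*log(0) := 0.
    """
    if not data:
        raise ValueError("entropy of empty input is undefined")
    seq = bytes_to_dna(data) if isinstance(data, (bytes, bytearray)) else data
    counts = np.bincount(dna_codes(seq), minlength=4)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())
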