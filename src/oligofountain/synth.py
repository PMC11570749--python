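"""Synthetic input files with controlled quaternary entropy.

Real DNA-storage evaluations span inputs from near-constant bitmaps
(entropy ~0.5 bits/base) through natural-language text (~1.9) to
compressed/encrypted archives (~2.0).  This module emulates that ladder
without external downloads: bases are drawn from a one-spike symbol
family (a, (1-a)/3, (1-a)/3, (1-a)/3) whose entropy sweeps [0, 2]
monotonically in the spike weight, solved by bisection, then packed two
bits per base into bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rules import RuleSet, dna_to_bytes, BASES

__all__ = ["generate_file", "entropy_ladder", "fixture_suite", "Scenario"]

# Entropy levels emulating the black-and-white / grayscale bitmaps, raw
# text, JPEG, and ZIP inputs of typical evaluations.
ENTROPY_LADDER = (0.52611, 1.45598, 1.77103, 1.91665, 1.96631, 1.99996)


def _spike_entropy(a: float) -> float:
    if a >= 1.0:
        return 0.0
    rest = (1.0 - a) / 3.0
    h = 0.0
    for p in (a, rest, rest, rest):
        if p > 0:
            h -= p * np.log2(p)
    return h


def _solve_spike(target: float) -> float:
    """Spike weight a in [0.25, 1] with entropy(a) = target (bisection)."""
    if not 0.0 <= target <= 2.0:
        raise ValueError("quaternary entropy target must lie in [0, 2]")
    lo, hi = 0.25, 1.0  # entropy 2.0 at lo, 0.0 at hi; monotone decreasing
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _spike_entropy(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_file(size: int, target_entropy_q: float, rng_seed: int = 0) -> bytes:
    """Random bytes whose quaternary entropy matches the target.

    ``size`` is in bytes (4 bases each); deterministic per ``rng_seed``.
    A target of 0 yields constant bytes, 2.0 uniform bytes.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    a = _solve_spike(target_entropy_q)
    rest = (1.0 - a) / 3.0
    rng = np.random.RandomState(rng_seed)
    codes = rng.choice(4, size=size * 4, p=[a, rest, rest, rest])
    seq = "".join(BASES[c] for c in codes)
    return dna_to_bytes(seq)


def entropy_ladder(size: int = 4096, rng_seed: int = 0) -> dict[float, bytes]:
    """The six-step entropy ladder as named synthetic files."""
    return {
        h: generate_file(size, h, rng_seed=rng_seed + i)
        for i, h in enumerate(ENTROPY_LADDER)
    }


@dataclass(frozen=True)
class Scenario:
    name: str
    data: bytes
    chunk_size: int
    rules: RuleSet


def fixture_suite(rng_seed: int = 7) -> list[Scenario]:
    """Small deterministic encode/decode scenarios used across the tests.

    Includes a 6,641-byte medium-entropy text stand-in (entropy ~1.94
    bits/base, the regime of natural-language prose), a low-entropy
    bitmap stand-in, and a high-entropy archive stand-in.
    """
    default = RuleSet(h_max=3, gc_min=0.4, gc_max=0.6)
    relaxed = RuleSet(h_max=4, gc_min=0.3, gc_max=0.7)
    return [
        Scenario("text_medium_entropy",
                 generate_file(6641, 1.94101, rng_seed=rng_seed), 40, default),
        Scenario("bitmap_low_entropy",
                 generate_file(2048, 0.52611, rng_seed=rng_seed + 1), 40, relaxed),
        Scenario("archive_high_entropy",
                 generate_file(4096, 1.99996, rng_seed=rng_seed + 2), 60, default),
    ]
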