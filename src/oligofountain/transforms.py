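"""Packet-level transforms that decouple seed and content from rule violations.

Three invertible operations:

* **seed masking** — XOR the iteration counter with a static mask so that
  sequentially generated packets do not all start with the homopolymer-prone
  leading zeros of small seeds;
* **seed spacing** — interleave the seed bases among the payload bases so a
  rule-violating seed alone cannot doom a packet;
* **payload masking** — XOR the payload with a seed-keyed Bernoulli(1/2)
  bit stream, raising the entropy of low-entropy content.

All three compose and invert exactly; the decoder re-applies the inverses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransformConfig",
    "SpacingError",
    "apply_seed_mask",
    "interleave_seed",
    "deinterleave_seed",
    "mask_payload",
    "default_seed_mask",
]

# Default mask for 2-byte seeds; repeats/truncates for other lengths.
DEFAULT_MASK_PATTERN = bytes([0xAC, 0x34])

# Domain-separation constant so the payload-mask PRNG stream can never
# coincide with the recipe stream keyed by the bare seed.
DEFAULT_MASK_SALT = 0x0F0F_5EED


# shared MT19937 for the mask stream; re-seeded per call
_MASK_RS = np.random.RandomState(0)


class SpacingError(ValueError):
    """Seed spacing too large for the payload length."""


def default_seed_mask(seed_len: int) -> bytes:
    """The static 0xAC34 pattern repeated/truncated to ``seed_len`` bytes."""
    reps = -(-seed_len // len(DEFAULT_MASK_PATTERN))
    return (DEFAULT_MASK_PATTERN * reps)[:seed_len]


@dataclass(frozen=True)
class TransformConfig:
    """Which transforms are active and with what parameters.

    ``seed_mask`` of ``None`` disables masking; ``spacing`` is the number
    of payload bases emitted after each seed base (0 = plain prefix);
    ``mask_stream_salt`` separates the payload-mask PRNG domain from the
    recipe PRNG domain.
    """

    seed_mask: bytes | None = None
    spacing: int = 0
    payload_mask_enabled: bool = False
    mask_stream_salt: int = DEFAULT_MASK_SALT

    def __post_init__(self):
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")

    @classmethod
    def all_on(cls, seed_len: int = 2, spacing: int = 4) -> "TransformConfig":
        return cls(
            seed_mask=default_seed_mask(seed_len),
            spacing=spacing,
            payload_mask_enabled=True,
        )


def apply_seed_mask(seed: int, mask: bytes) -> int:
    """XOR an integer seed with a byte mask of the seed's width (involution)."""
    width = len(mask)
    if seed < 0 or seed >= 1 << (8 * width):
        raise ValueError(f"seed {seed} does not fit in {width} bytes")
    return seed ^ int.from_bytes(mask, "big")


def interleave_seed(seed_nt: str, payload_nt: str, spacing: int) -> str:
    """Merge seed bases into the payload with ``spacing`` payload bases
    after each seed base; spacing 0 is plain concatenation.

    Order within seed and within payload is preserved, so the merge is
    exactly invertible given the seed length and spacing.
    """
    if spacing == 0:
        return seed_nt + payload_nt
    _check_spacing(len(seed_nt), len(payload_nt), spacing)
    out: list[str] = []
    pos = 0
    for base in seed_nt:
        out.append(base)
        out.append(payload_nt[pos : pos + spacing])
        pos += spacing
    out.append(payload_nt[pos:])
    return "".join(out)


def deinterleave_seed(seq: str, seed_len_nt: int, spacing: int) -> tuple[str, str]:
    """Exact inverse of :func:`interleave_seed`."""
    if spacing == 0:
        return seq[:seed_len_nt], seq[seed_len_nt:]
    payload_len = len(seq) - seed_len_nt
    _check_spacing(seed_len_nt, payload_len, spacing)
    seed_chars: list[str] = []
    payload_chars: list[str] = []
    pos = 0
    for _ in range(seed_len_nt):
        seed_chars.append(seq[pos])
        payload_chars.append(seq[pos + 1 : pos + 1 + spacing])
        pos += 1 + spacing
    payload_chars.append(seq[pos:])
    return "".join(seed_chars), "".join(payload_chars)


def _check_spacing(seed_len_nt: int, payload_len_nt: int, spacing: int) -> None:
    # beyond this bound the tail of the seed would sit unspaced at the end
    if seed_len_nt and spacing * seed_len_nt > payload_len_nt:
        raise SpacingError(
            f"spacing {spacing} exceeds payload capacity "
            f"({payload_len_nt} nt payload for {seed_len_nt} nt seed)"
        )


def mask_payload(payload: bytes, seed: int, salt: int = DEFAULT_MASK_SALT) -> bytes:
    """XOR the payload with a deterministic MT19937 byte stream keyed by
    (seed, salt).  Involution; uniform Bernoulli(1/2) per bit."""
    if not payload:
        return b""
    _MASK_RS.seed(np.array([seed & 0xFFFFFFFF, salt & 0xFFFFFFFF], dtype=np.uint32))
    stream = _MASK_RS.randint(0, 256, size=len(payload), dtype=np.uint8)
    data = np.frombuffer(bytes(payload), dtype=np.uint8)
    return (data ^ stream).tobytes()
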