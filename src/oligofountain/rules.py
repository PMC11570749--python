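"""DNA channel constraints and binary/quaternary translation.

The DNA storage channel rejects sequences with long homopolymer runs,
unbalanced GC content (globally and per sliding window), and occurrences
of forbidden motifs (primers, Lox sites, adapters and their reverse
complements).  This module houses the rule set, a floating-point error
score whose threshold 1.0 marks a hard violation, and the fixed 2-bit
byte <-> nucleotide mapping used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "RuleSet",
    "ErrorScore",
    "AlphabetError",
    "bytes_to_dna",
    "dna_to_bytes",
    "reverse_complement",
    "max_homopolymer",
    "gc_stats",
    "find_forbidden",
    "error_score",
    "load_rules",
    "load_motifs_fasta",
]

# Fixed, documented bijection: each byte maps MSB-first, 2 bits per base.
# 00 -> A, 01 -> C, 10 -> G, 11 -> T
BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

# byte value -> 4-char DNA string, and uint8 lookup table byte -> 4 base codes
_BYTE_TO_DNA = [
    "".join(BASES[(v >> s) & 0b11] for s in (6, 4, 2, 0)) for v in range(256)
]
_BYTE_TO_CODES = np.array(
    [[(v >> s) & 0b11 for s in (6, 4, 2, 0)] for v in range(256)], dtype=np.uint8
)
# ASCII byte of base char -> 0..3 code (255 = invalid)
_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ASCII_TO_CODE[ord(_b)] = _c

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Sequence contains a symbol outside {A, C, G, T}."""


def bytes_to_dna(data: bytes) -> str:
    """Translate a byte string to DNA, 4 bases per byte, MSB first."""
    if not data:
        return ""
    arr = np.frombuffer(bytes(data), dtype=np.uint8)
    return "".join([_BYTE_TO_DNA[v] for v in arr])


def dna_codes(seq: str) -> np.ndarray:
    """Internal: sequence as uint8 codes 0..3; raises AlphabetError."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ASCII_TO_CODE[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise AlphabetError(f"non-ACGT symbol {bad!r} in sequence")
    return codes


def dna_to_bytes(seq: str) -> bytes:
    """Inverse of :func:`bytes_to_dna`; length must be a multiple of 4."""
    if len(seq) % 4:
        raise ValueError(f"sequence length {len(seq)} not divisible by 4")
    if not seq:
        return b""
    codes = dna_codes(seq).reshape(-1, 4).astype(np.uint16)
    vals = (codes[:, 0] << 6) | (codes[:, 1] << 4) | (codes[:, 2] << 2) | codes[:, 3]
    return vals.astype(np.uint8).tobytes()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RuleSet:
    """Channel constraints applied to every stored sequence.

    Parameters mirror common in-vitro synthesis limits: homopolymer runs
    of at most ``h_max`` bases, GC fraction within ``[gc_min, gc_max]``
    globally and within ``[gc_window_min, gc_window_max]`` per sliding
    window of ``gc_window`` nt (0 disables windowed checking), and a set
    of ``forbidden`` motifs, closed under reverse complement when
    ``include_revcomp`` is set.
    """

    h_max: int = 3
    gc_min: float = 0.4
    gc_max: float = 0.6
    gc_window: int = 0
    gc_window_min: float = 0.4
    gc_window_max: float = 0.6
    forbidden: frozenset[str] = frozenset()
    include_revcomp: bool = True

    def __post_init__(self):
        if self.h_max < 1:
            raise ValueError("h_max must be >= 1")
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if not (0 <= self.gc_window_min <= self.gc_window_max <= 1):
            raise ValueError("need 0 <= gc_window_min <= gc_window_max <= 1")
        motifs = frozenset(m.upper() for m in self.forbidden)
        for m in motifs:
            if not m or any(c not in _BASE_CODE for c in m):
                raise ValueError(f"forbidden motif {m!r} is not a nonempty ACGT string")
        object.__setattr__(self, "forbidden", motifs)

    @property
    def motif_set(self) -> frozenset[str]:
        """Motifs to screen, including reverse complements if configured."""
        if not self.include_revcomp:
            return self.forbidden
        return self.forbidden | frozenset(reverse_complement(m) for m in self.forbidden)


@dataclass
class ErrorScore:
    """Floating-point rule score; ``total >= 1.0`` is a hard violation."""

    total: float
    per_rule: dict[str, float] = field(default_factory=dict)

    @property
    def violating(self) -> bool:
        return self.total >= 1.0


def _max_run(codes: np.ndarray) -> int:
    if len(codes) == 1:
        return 1
    # positions where the base changes split the sequence into runs
    change = np.flatnonzero(codes[1:] != codes[:-1])
    bounds = np.concatenate(([-1], change, [len(codes) - 1]))
    return int(np.diff(bounds).max())


def max_homopolymer(seq: str) -> int:
    """Longest run of any single base; 0 for the empty sequence."""
    if not seq:
        return 0
    return _max_run(dna_codes(seq))


def _gc_mask(codes: np.ndarray) -> np.ndarray:
    # codes 1 (C) and 2 (G)
    return (codes == 1) | (codes == 2)


def gc_stats(seq: str, rules: RuleSet) -> tuple[float, int]:
    """Global GC fraction and count of out-of-band sliding windows."""
    if not seq:
        raise ValueError("GC content of an empty sequence is undefined")
    codes = dna_codes(seq)
    gc = _gc_mask(codes)
    global_gc = float(gc.mean())
    violations = 0
    w = rules.gc_window
    if w and len(codes) >= w:
        cs = np.concatenate(([0], np.cumsum(gc)))
        win = (cs[w:] - cs[:-w]) / w
        violations = int(
            np.count_nonzero((win < rules.gc_window_min) | (win > rules.gc_window_max))
        )
    return global_gc, violations


def find_forbidden(seq: str, rules: RuleSet) -> list[tuple[str, int]]:
    """All (motif, position) occurrences of forbidden motifs in ``seq``."""
    hits: list[tuple[str, int]] = []
    for motif in sorted(rules.motif_set):
        start = seq.find(motif)
        while start != -1:
            hits.append((motif, start))
            start = seq.find(motif, start + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def _windowed_gc_penalty(codes: np.ndarray, rules: RuleSet) -> float:
    # graded near-miss score: per-window distance outside the band,
    # normalized by band width, capped at 1.0 for the whole rule class
    w = rules.gc_window
    if not w or len(codes) < w:
        return 0.0
    cs = np.concatenate(([0], np.cumsum(_gc_mask(codes))))
    win = (cs[w:] - cs[:-w]) / w
    band = max(rules.gc_window_max - rules.gc_window_min, 1e-9)
    below = np.clip(rules.gc_window_min - win, 0.0, None)
    above = np.clip(win - rules.gc_window_max, 0.0, None)
    return float(min((below + above).sum() / band, 1.0))


def error_score(seq: str, rules: RuleSet) -> ErrorScore:
    """Score a sequence against the rule set.

    Hard rules (homopolymer run > h_max, global GC outside its band, any
    forbidden motif) each contribute exactly 1.0 per rule class; windowed
    GC near-misses contribute a graded amount in [0, 1).  A total >= 1.0
    marks the sequence as unusable for synthesis.
    """
    if not seq:
        raise ValueError("cannot score an empty sequence")
    codes = dna_codes(seq)
    per_rule: dict[str, float] = {}

    run = _max_run(codes)
    per_rule["homopolymer"] = 1.0 if run > rules.h_max else 0.0

    gc = float(_gc_mask(codes).mean())
    per_rule["gc_global"] = 0.0 if rules.gc_min <= gc <= rules.gc_max else 1.0

    per_rule["gc_window"] = _windowed_gc_penalty(codes, rules)

    if rules.motif_set:
        per_rule["forbidden_motif"] = 1.0 if _has_motif(seq, rules) else 0.0
    else:
        per_rule["forbidden_motif"] = 0.0

    return ErrorScore(total=sum(per_rule.values()), per_rule=per_rule)


def _has_motif(seq: str, rules: RuleSet) -> bool:
    return any(m in seq for m in rules.motif_set)


def load_rules(path: str | Path) -> RuleSet:
    """Read a RuleSet from a YAML or JSON config file."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    cfg = dict(cfg or {})
    if "forbidden" in cfg:
        cfg["forbidden"] = frozenset(cfg["forbidden"])
    return RuleSet(**cfg)


def load_motifs_fasta(path: str | Path) -> frozenset[str]:
    """Load a forbidden-motif list from a plain FASTA file."""
    from Bio import SeqIO

    return frozenset(str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta"))
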