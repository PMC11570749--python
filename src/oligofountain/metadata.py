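"""Metadata signalling through codeword presence/absence in the DNA pool.

Small metadata (which degree distribution was used, file tags, ...) is
signalled without dedicated index bytes: each metadata ID maps to a short
DNA codeword; during encoding every codeword except the target's is
added to the forbidden-motif set, and the free bytes of the header chunk
are searched until at least one rule-abiding packet contains the target
codeword.  A decoder recovers the ID by scanning for which single
codeword occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HEADER_FIXED_BYTES, SourceBlock, encode_packet
from .distributions import DegreeDistribution
from .rules import RuleSet, error_score
from .transforms import TransformConfig

__all__ = [
    "CodewordMap",
    "EmbeddingInfeasibleError",
    "embed_codeword",
    "detect_metadata",
    "rules_excluding",
]

DEFAULT_CODEWORD_LEN = 8  # long enough to be rare by chance, short enough to embed


class EmbeddingInfeasibleError(RuntimeError):
    """Search budget exhausted without producing a witness packet."""


@dataclass(frozen=True)
class CodewordMap:
    """Mapping metadata-ID -> DNA codeword.

    Codewords must be pairwise distinct, none a substring of another, and
    each must itself pass the rule set it will be embedded under.
    """

    entries: dict[int, str]

    def __post_init__(self):
        words = {k: v.upper() for k, v in self.entries.items()}
        vals = list(words.values())
        if len(set(vals)) != len(vals):
            raise ValueError("codewords must be pairwise distinct")
        for i, a in enumerate(vals):
            for b in vals[i + 1:]:
                if a in b or b in a:
                    raise ValueError(f"codeword {a!r} is a substring of {b!r}")
        object.__setattr__(self, "entries", words)

    def validate_against(self, rules: RuleSet) -> None:
        for word in self.entries.values():
            if error_score(word, RuleSet(
                h_max=rules.h_max, gc_min=0.0, gc_max=1.0,
                forbidden=rules.forbidden, include_revcomp=rules.include_revcomp,
            )).violating:
                raise ValueError(f"codeword {word!r} violates the rule set")


def rules_excluding(rules: RuleSet, cmap: CodewordMap, target_id: int) -> RuleSet:
    """Rule set with every non-target codeword added to the forbidden set."""
    others = {w for i, w in cmap.entries.items() if i != target_id}
    return RuleSet(
        h_max=rules.h_max, gc_min=rules.gc_min, gc_max=rules.gc_max,
        gc_window=rules.gc_window, gc_window_min=rules.gc_window_min,
        gc_window_max=rules.gc_window_max,
        forbidden=frozenset(rules.forbidden) | others,
        include_revcomp=rules.include_revcomp,
    )


def embed_codeword(
    block: SourceBlock,
    target_id: int,
    cmap: CodewordMap,
    dist: DegreeDistribution,
    rules: RuleSet,
    transforms: TransformConfig | None = None,
    seed_len: int = 2,
    search_budget: int = 4096,
    rng_seed: int = 0,
) -> tuple[SourceBlock, int]:
    """Force a rule-abiding packet containing the target codeword to exist.

    Random assignments of the header chunk's free bytes are tried; for
    each assignment the seed space is scanned until some packet both
    contains the codeword and passes the (codeword-augmented) rules.
    Returns the modified block and the witness packet's seed.  No payload
    byte outside the free header region is ever altered.
    """
    if block.header_chunk is None:
        raise ValueError("codeword embedding requires the header chunk")
    if target_id not in cmap.entries:
        raise KeyError(f"unknown metadata id {target_id}")
    target = cmap.entries[target_id]
    pool_rules = rules_excluding(rules, cmap, target_id)
    transforms = transforms or TransformConfig()
    free_len = block.chunk_size - HEADER_FIXED_BYTES
    rng = np.random.RandomState(rng_seed)

    def witness(candidate: SourceBlock) -> int | None:
        for seed in range(search_budget):
            pkt = encode_packet(
                seed, candidate, dist, transforms, pool_rules, seed_len=seed_len
            )
            if target in pkt.dna and not pkt.score.violating:
                return seed
        return None

    # the original free bytes may already produce a witness
    seed = witness(block)
    if seed is not None:
        return block, seed

    fixed = block.header_chunk[:HEADER_FIXED_BYTES]
    tries = max(search_budget // 64, 8)
    for _ in range(tries):
        free = rng.bytes(free_len) if free_len else b""
        candidate = SourceBlock(
            data=block.data, chunk_size=block.chunk_size, n=block.n,
            pad_len=block.pad_len, header_chunk=fixed + free,
        )
        seed = witness(candidate)
        if seed is not None:
            return candidate, seed
    raise EmbeddingInfeasibleError(
        f"no witness packet for codeword {target!r} within the search budget; "
        "consider a shorter codeword"
    )


def detect_metadata(sequences, cmap: CodewordMap) -> int | None:
    """The unique metadata ID whose codeword occurs in >= 1 sequence while
    no other codeword occurs; ``None`` (undecided) otherwise."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    present = {
        mid for mid, word in cmap.entries.items()
        if any(word in s for s in seqs)
    }
    if len(present) == 1:
        return present.pop()
    return None
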