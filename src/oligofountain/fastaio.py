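"""FASTA interchange and whole-file encode/decode pipelines.

FASTA is the single sequence interchange format: one record per packet,
id ``seed_<decimal>``, with all transform parameters echoed as
``key=value`` tokens in every record description so a decoder can
self-configure.  Packets whose per-packet CRC-32 fails on read are
dropped, simulating an erasure channel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DecodeResult,
    Packet,
    SourceBlock,
    derive_recipe,
    encode_packet,
    ge_decode,
    reassemble,
    split_into_chunks,
)
from .distributions import DegreeDistribution, raptor_rfc5053
from .rules import RuleSet, dna_to_bytes
from .transforms import TransformConfig, apply_seed_mask, deinterleave_seed, mask_payload

__all__ = ["EncodeParams", "encode_file", "write_fasta", "read_fasta", "decode_file"]


@dataclass
class EncodeParams:
    """Everything a decoder needs, echoed into the FASTA descriptions."""

    seed_len: int
    spacing: int
    payload_mask: bool
    salt: int
    chunk_size: int
    n: int
    header: bool
    crc: bool
    file_len: int

    def tokens(self) -> str:
        return (
            f"seed_len={self.seed_len} spacing={self.spacing} "
            f"payload_mask={int(self.payload_mask)} salt={self.salt} "
            f"chunk_size={self.chunk_size} n={self.n} header={int(self.header)} "
            f"crc={int(self.crc)} file_len={self.file_len}"
        )

    @classmethod
    def from_tokens(cls, description: str) -> "EncodeParams":
        kv = dict(tok.split("=", 1) for tok in description.split() if "=" in tok)
        return cls(
            seed_len=int(kv["seed_len"]), spacing=int(kv["spacing"]),
            payload_mask=bool(int(kv["payload_mask"])), salt=int(kv["salt"]),
            chunk_size=int(kv["chunk_size"]), n=int(kv["n"]),
            header=bool(int(kv["header"])), crc=bool(int(kv["crc"])),
            file_len=int(kv["file_len"]),
        )


def encode_file(
    data: bytes,
    chunk_size: int = 40,
    dist: DegreeDistribution | None = None,
    transforms: TransformConfig | None = None,
    rules: RuleSet | None = None,
    seed_len: int = 2,
    count: int | None = None,
    with_header: bool = True,
    with_crc: bool = True,
    max_seeds: int | None = None,
) -> tuple[list[Packet], EncodeParams, SourceBlock]:
    """Encode a file into rule-abiding packets guaranteed to decode.

    Seed counters are scanned in order; packets violating the rules are
    skipped.  Collection stops once at least ``count`` packets (default
    ``n`` + 10% overhead margin) are gathered *and* their recipe matrix
    has full rank ``n``, so the emitted FASTA is always decodable.
    """
    dist = dist or raptor_rfc5053()
    transforms = transforms or TransformConfig()
    block = split_into_chunks(data, chunk_size, with_header=with_header)
    count = count if count is not None else block.n + max(block.n // 10, 2)
    max_seeds = max_seeds if max_seeds is not None else 1 << (8 * seed_len)

    from .core import GESolver

    solver = GESolver(block.n)
    selected: list[Packet] = []
    for counter in range(max_seeds):
        seed = (
            apply_seed_mask(counter, transforms.seed_mask)
            if transforms.seed_mask is not None
            else counter
        )
        pkt = encode_packet(
            seed, block, dist, transforms, rules, seed_len=seed_len, with_crc=with_crc
        )
        if pkt.score is not None and pkt.score.violating:
            continue
        selected.append(pkt)
        solver.insert(pkt.chunk_ids)
        if len(selected) >= count and solver.solved:
            break
    if not solver.solved:
        raise RuntimeError(
            f"seed space exhausted at rank {solver.rank}/{block.n}; "
            "relax rules or enlarge the seed space"
        )
    params = EncodeParams(
        seed_len=seed_len, spacing=transforms.spacing,
        payload_mask=transforms.payload_mask_enabled,
        salt=transforms.mask_stream_salt, chunk_size=chunk_size, n=block.n,
        header=with_header, crc=with_crc, file_len=len(data),
    )
    return selected, params, block


def write_fasta(packets: list[Packet], params: EncodeParams, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(pkt.dna), id=f"seed_{pkt.seed}", description=params.tokens())
        for pkt in packets
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path):
    """Yield (seed, dna) pairs plus the self-configuration parameters."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"no sequences in {path}")
    params = EncodeParams.from_tokens(records[0].description)
    pairs = []
    for rec in records:
        if not rec.id.startswith("seed_"):
            raise ValueError(f"record id {rec.id!r} does not carry a seed")
        pairs.append((int(rec.id[5:]), str(rec.seq).upper()))
    return pairs, params


def decode_file(
    path: str | Path,
    dist: DegreeDistribution | None = None,
    params: EncodeParams | None = None,
) -> tuple[bytes, DecodeResult, int]:
    """Decode a FASTA/FASTQ of packets back to the original bytes.

    Returns (data, decode result, number of packets dropped by the
    per-packet CRC erasure check).  The header CRC-32 is verified before
    the decode is declared successful.
    """
    dist = dist or raptor_rfc5053()
    pairs, file_params = read_fasta(path)
    params = params or file_params
    seed_nt_len = params.seed_len * 4
    rows = []
    dropped = 0
    for seed, dna in pairs:
        seed_nt, tail_nt = deinterleave_seed(dna, seed_nt_len, params.spacing)
        stored_seed = int.from_bytes(dna_to_bytes(seed_nt), "big")
        if stored_seed != seed:
            dropped += 1
            continue
        tail = dna_to_bytes(tail_nt)
        if params.crc:
            payload, crc = tail[:-4], int.from_bytes(tail[-4:], "big")
            if zlib.crc32(seed.to_bytes(params.seed_len, "big") + payload) != crc:
                dropped += 1
                continue
        else:
            payload = tail
        if params.payload_mask:
            payload = mask_payload(payload, seed, params.salt)
        _, ids = derive_recipe(seed, params.n, dist)
        rows.append((ids, payload))
    result = ge_decode(rows, params.n)
    if not result.success:
        return b"", result, dropped
    data = reassemble(
        result, params.header, params.chunk_size,
        file_len=None if params.header else params.file_len,
    )
    return data, result, dropped
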