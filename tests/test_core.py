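"""Chunking, recipes, packet encoding, GF(2) decoding, sampling metrics."""

import numpy as np
import pytest
from scipy import stats

from oligofountain.core import (
    GESolver,
    IntegrityError,
    derive_recipe,
    encode_packet,
    estimate_metrics_sampling,
    ge_decode,
    generate_pool,
    reassemble,
    split_into_chunks,
)
from oligofountain.distributions import DegreeDistribution, raptor_rfc5053
from oligofountain.transforms import TransformConfig


def _degree_forced(degree: int) -> DegreeDistribution:
    p = np.zeros(40)
    p[degree - 1] = 1 - 1e-9
    other = 1 if degree != 2 else 2
    p[0] = max(p[0], 1e-9)
    p[other] += 1 - p.sum()  # sliver of mass elsewhere keeps entries < 1
    return DegreeDistribution(tuple(p))


class TestChunking:
    def test_counts_and_padding(self):
        b = split_into_chunks(bytes(6641), 40, with_header=False)
        assert b.n == 167 and b.pad_len == (-6641) % 40
        b = split_into_chunks(bytes(40), 40, with_header=False)
        assert b.n == 1 and b.pad_len == 0
        b = split_into_chunks(bytes(41), 40, with_header=False)
        assert b.n == 2 and b.pad_len == 39

    def test_header_chunk_layout(self):
        data = bytes(range(100))
        b = split_into_chunks(data, 40, with_header=True)
        assert b.n == 1 + 3
        assert int.from_bytes(b.header_chunk[:8], "big") == 100
        import zlib

        assert int.from_bytes(b.header_chunk[8:12], "big") == zlib.crc32(data)
        assert len(b.header_chunk) == 40

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_into_chunks(b"", 40)


class TestRecipe:
    def test_deterministic(self, raptor):
        assert derive_recipe(1234, 100, raptor) == derive_recipe(1234, 100, raptor)

    def test_single_chunk_degenerate(self, raptor):
        for seed in range(50):
            assert derive_recipe(seed, 1, raptor) == (1, (0,))

    def test_degree_matches_cardinality(self, raptor):
        for seed in range(200):
            degree, ids = derive_recipe(seed, 57, raptor)
            assert degree == len(ids) == len(set(ids))
            assert all(0 <= i < 57 for i in ids)
            assert list(ids) == sorted(ids)

    def test_degree_histogram_matches_distribution(self, raptor):
        """Chi-square over 2^14 seeds against the Raptor table."""
        n_seeds = 1 << 14
        counts = np.zeros(40)
        for seed in range(n_seeds):
            d, _ = derive_recipe(seed, 200, raptor)
            counts[d - 1] += 1
        expected = raptor.array * n_seeds
        active = expected > 0
        _, p = stats.chisquare(counts[active], expected[active])
        assert p > 1e-4


class TestEncode:
    def test_degree_one_packet_is_the_chunk(self, raptor):
        block = split_into_chunks(bytes(range(200)), 20, with_header=False)
        dist = _degree_forced(1)
        pkt = encode_packet(3, block, dist, seed_len=2, with_crc=False)
        assert pkt.degree == 1
        assert pkt.payload == bytes(block.chunks[pkt.chunk_ids[0]])

    def test_payload_is_xor_of_chunks(self, raptor):
        block = split_into_chunks(bytes(range(200)), 20, with_header=False)
        for seed in range(30):
            pkt = encode_packet(seed, block, raptor, with_crc=False)
            expect = np.bitwise_xor.reduce(block.chunks[list(pkt.chunk_ids)], axis=0)
            assert pkt.payload == expect.tobytes()

    def test_transform_inversion_recovers_payload(self, raptor):
        from oligofountain.rules import dna_to_bytes
        from oligofountain.transforms import deinterleave_seed, mask_payload

        block = split_into_chunks(bytes(range(180)), 20, with_header=False)
        tf = TransformConfig(spacing=3, payload_mask_enabled=True)
        for seed in (0, 77, 901):
            pkt = encode_packet(seed, block, raptor, tf, with_crc=False)
            seed_nt, tail_nt = deinterleave_seed(pkt.dna, 8, 3)
            assert int.from_bytes(dna_to_bytes(seed_nt), "big") == seed
            recovered = mask_payload(dna_to_bytes(tail_nt), seed)
            plain = encode_packet(seed, block, raptor, with_crc=False)
            assert recovered == plain.payload


class TestGEDecode:
    def test_degree_one_cover_decodes_with_zero_overhead(self):
        block = split_into_chunks(bytes(range(60)), 12, with_header=False)
        rows = [((i,), bytes(block.chunks[i])) for i in range(block.n)]
        res = ge_decode(rows, block.n)
        assert res.success and res.solved_chunks == block.n and res.overhead == 0
        assert reassemble(res, False, 12, file_len=60) == bytes(range(60))

    def test_partial_solve_hand_reduced(self):
        # rows {0} and {0,1} over n=3: chunks 0 and 1 solvable, 2 is not
        rows = [((0,), b"\x05"), ((0, 1), b"\x0c")]
        res = ge_decode(rows, 3)
        assert not res.success
        assert res.solved_chunks == 2
        assert res.chunks == {0: b"\x05", 1: b"\x09"}

    def test_superset_of_successful_set_still_succeeds(self, raptor):
        block = split_into_chunks(bytes(range(60)), 12, with_header=False)
        rows = [((i,), bytes(block.chunks[i])) for i in range(block.n)]
        extra = [((0, 4), None), ((1, 2, 3), None)]
        res = ge_decode([(ids, None) for ids, _ in rows] + extra, block.n)
        assert res.success

    def test_order_independence(self, raptor):
        block = split_into_chunks(bytes(range(100)), 10, with_header=False)
        pool = generate_pool(block, raptor, seed_range=(0, 25), with_crc=False)
        rng = np.random.RandomState(5)
        base = ge_decode(pool.packets, block.n)
        for _ in range(5):
            perm = [pool.packets[i] for i in rng.permutation(len(pool.packets))]
            res = ge_decode(perm, block.n)
            assert (res.success, res.solved_chunks) == (base.success, base.solved_chunks)
            assert res.chunks == base.chunks

    def test_solved_monotone_in_packet_set(self, raptor):
        block = split_into_chunks(bytes(range(100)), 10, with_header=False)
        pool = generate_pool(block, raptor, seed_range=(0, 40), with_crc=False)
        prev = 0
        for k in range(1, len(pool.packets) + 1):
            res = ge_decode(pool.packets[:k], block.n)
            assert res.solved_chunks >= prev
            prev = res.solved_chunks

    def test_inconsistent_system_raises(self):
        with pytest.raises(IntegrityError):
            ge_decode([((0,), b"\x01"), ((0,), b"\x02")], 2)

    def test_out_of_range_chunk_rejected(self):
        solver = GESolver(4)
        with pytest.raises(ValueError):
            solver.insert((4,))


class TestPool:
    def test_pool_size_one(self, raptor):
        block = split_into_chunks(bytes(range(50)), 10, with_header=False)
        pool = generate_pool(block, raptor, seed_range=(5, 6))
        assert len(pool.packets) == 1 and pool.packets[0].seed == 5

    def test_unique_payload_ceiling_degree_two(self):
        block = split_into_chunks(bytes(1000), 20, with_header=False)
        assert block.n == 50
        pool = generate_pool(block, _degree_forced(2), seed_range=(0, 5000))
        assert pool.unique_payload_count <= 1225  # C(50, 2)

    def test_unique_count_vs_pairwise_oracle(self, raptor):
        block = split_into_chunks(bytes(range(100)), 10, with_header=False)
        pool = generate_pool(block, raptor, seed_range=(0, 300), with_crc=False)
        keys = [p.canonical_key for p in pool.packets]
        distinct = sum(
            all(keys[i] != keys[j] for j in range(i)) for i in range(len(keys))
        )
        assert pool.unique_payload_count == distinct


class TestSamplingMetrics:
    def test_trivial_pool_exact_cover(self):
        block = split_into_chunks(bytes(range(60)), 12, with_header=False)
        pool = [
            encode_packet(s, block, _degree_forced(1), with_crc=False)
            for s in range(2000)
        ]
        # keep exactly one degree-1 packet per chunk
        seen, keep = set(), []
        for p in pool:
            if p.chunk_ids not in seen:
                seen.add(p.chunk_ids)
                keep.append(p)
        keep = keep[: block.n]
        assert len(keep) == block.n
        triple = estimate_metrics_sampling(keep, block.n, reps=5, rng_seed=1)
        assert triple == (float(block.n), 1.0, float(block.n))

    def test_deterministic_and_bounded(self, raptor):
        block = split_into_chunks(bytes(range(100)), 10, with_header=False)
        pool = generate_pool(block, raptor, seed_range=(0, 60), with_crc=False)
        a = estimate_metrics_sampling(pool, block.n, reps=8, rng_seed=3)
        b = estimate_metrics_sampling(pool, block.n, reps=8, rng_seed=3)
        assert a == b
        assert a[0] >= block.n and 0 <= a[1] <= 1 and a[2] <= block.n
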