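import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alnzip import codec
from alnzip.arborescence import minimum_spanning_arborescence
from alnzip.codec import (
    DeltaRecord,
    ReferenceRecord,
    apply_runs,
    backend_compress,
    backend_decompress,
    compress,
    decompress,
    deserialize_archive,
    encode_archive,
    serialize_archive,
)
from alnzip.errors import (
    CorruptArchiveError,
    UnrecognizedArchiveError,
    UnsupportedBackendError,
)
from alnzip.graph import CostModel, MismatchRun, build_encodability_graph, mismatch_runs
from alnzip.likelihood import WindowConfig
from alnzip.msa_io import msa_from_rows, write_fasta_msa
from alnzip.synthetic import EvolutionParams, generate_msa

from conftest import random_msa


def pipeline_archive(msa, cfg=None):
    cfg = cfg or WindowConfig()
    from alnzip.likelihood import rank_by_likelihood, sliding_windows

    wins = sliding_windows(rank_by_likelihood(msa), cfg)
    eg = build_encodability_graph(msa, wins)
    ma = minimum_spanning_arborescence(eg)
    return eg, ma, encode_archive(msa, ma)


class TestApplyRuns:
    def test_empty_runs_identity(self):
        assert apply_runs("acgt", []) == "acgt"

    def test_worked_example_direction(self, pair_two_runs):
        s1, s2 = pair_two_runs
        runs = [MismatchRun(2, "aa"), MismatchRun(10, "cc")]
        assert apply_runs(s2, runs) == s1

    def test_out_of_bounds_rejected(self):
        with pytest.raises(CorruptArchiveError, match="corrupt delta"):
            apply_runs("acgt", [MismatchRun(3, "gg")])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 80))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_inverse_of_mismatch_runs(self, seed, l):
        rng = np.random.default_rng(seed)
        chars = np.array(list("acgt-"))
        a = "".join(chars[rng.integers(0, 5, l)])
        b = "".join(chars[rng.integers(0, 5, l)])
        assert apply_runs(a, mismatch_runs(a, b)) == b


class TestArchiveStructure:
    def test_identical_rows_single_reference(self):
        m = msa_from_rows(["acgtacgt"] * 6)
        _, ma, archive = pipeline_archive(m, WindowConfig(6, 0))
        refs = [r for r in archive.records if isinstance(r, ReferenceRecord)]
        deltas = [r for r in archive.records if isinstance(r, DeltaRecord)]
        assert len(refs) == 1
        assert len(deltas) == 5
        assert all(len(d.runs) == 0 for d in deltas)

    def test_single_row_archive(self):
        m = msa_from_rows(["acgt"])
        _, _, archive = pipeline_archive(m)
        assert len(archive.records) == 1
        assert isinstance(archive.records[0], ReferenceRecord)

    def test_reference_count_equals_root_children(self, clustered_msa):
        _, ma, archive = pipeline_archive(clustered_msa)
        refs = [r for r in archive.records if isinstance(r, ReferenceRecord)]
        assert sorted(r.original_index for r in refs) == ma.references

    def test_parents_precede_children(self, clustered_msa):
        _, _, archive = pipeline_archive(clustered_msa)
        seen = set()
        for rec in archive.records:
            if isinstance(rec, DeltaRecord):
                assert rec.parent_original_index in seen
            seen.add(rec.original_index)

    def test_delta_chains_terminate_at_reference(self, clustered_msa):
        _, ma, archive = pipeline_archive(clustered_msa)
        kind = {
            r.original_index: isinstance(r, ReferenceRecord) for r in archive.records
        }
        for i in range(clustered_msa.n):
            hops = 0
            j = i
            from alnzip.graph import ROOT

            while ma.parent[j] != ROOT:
                j = ma.parent[j]
                hops += 1
                assert hops <= clustered_msa.n
            assert kind[j]


class TestSerialization:
    def test_round_trip_identity(self, clustered_msa):
        _, _, archive = pipeline_archive(clustered_msa)
        back = deserialize_archive(serialize_archive(archive))
        assert back.n == archive.n and back.l == archive.l
        assert back.headers == archive.headers
        assert back.records == archive.records
        assert back.alphabet == archive.alphabet

    def test_serialization_deterministic(self, clustered_msa):
        _, _, archive = pipeline_archive(clustered_msa)
        assert serialize_archive(archive) == serialize_archive(archive)

    def test_cost_fidelity_sum_equals_arborescence_weight(self, clustered_msa):
        from alnzip.codec import _record_bits
        from alnzip.graph import ROOT

        eg, ma, archive = pipeline_archive(clustered_msa)
        total = 0
        for rec in archive.records:
            bits = _record_bits(rec, archive.cost_model, archive.l)
            if isinstance(rec, ReferenceRecord):
                assert bits == eg.weight(ROOT, rec.original_index)
            else:
                assert bits == eg.weight(rec.parent_original_index, rec.original_index)
            total += bits
        assert total == ma.total_weight

    def test_bad_magic_distinguished_from_truncation(self):
        m = msa_from_rows(["acgt", "acct"])
        blob = compress(m)
        with pytest.raises(UnrecognizedArchiveError):
            decompress(b"XXXX" + blob[4:])
        with pytest.raises(CorruptArchiveError):
            decompress(blob[:-3])

    def test_checksum_detects_corruption(self):
        m = msa_from_rows(["acgt", "acct"])
        blob = bytearray(compress(m, backend="none"))
        blob[-2] ^= 0xFF
        with pytest.raises(CorruptArchiveError):
            decompress(bytes(blob))


class TestBackends:
    @pytest.mark.parametrize("backend", ["none", "bzip2", "gzip", "lzma"])
    def test_backend_round_trip(self, backend):
        data = b"some archive payload" * 50
        assert backend_decompress(backend_compress(data, backend), backend) == data

    def test_unknown_backend_rejected(self):
        with pytest.raises(UnsupportedBackendError):
            backend_compress(b"x", "zstd")
        with pytest.raises(UnsupportedBackendError):
            compress(msa_from_rows(["aa"]), backend="zstd")

    def test_redundant_archive_shrinks_under_bzip2(self):
        m = generate_msa(EvolutionParams(n=60, l=800, substitution_prob=0.001, seed=2))
        _, _, archive = pipeline_archive(m)
        inner = serialize_archive(archive)
        assert len(backend_compress(inner, "bzip2")) < len(inner)


class TestFullPipeline:
    @pytest.mark.parametrize("backend", ["none", "bzip2", "gzip", "lzma"])
    def test_round_trip_all_backends(self, small_msa, backend):
        assert decompress(compress(small_msa, backend=backend)) == small_msa

    def test_round_trip_pathological_inputs(self):
        cases = [
            msa_from_rows(["a"]),
            msa_from_rows(["-" * 30] * 4),  # all-gap alignment
            msa_from_rows(["AcGt" * 5, "aCgT" * 5]),  # case-mixed
            msa_from_rows(["acgt", "ac-t"], headers=["", " spaced  header "]),
        ]
        for m in cases:
            assert decompress(compress(m)) == m

    def test_compress_deterministic(self, clustered_msa):
        assert compress(clustered_msa) == compress(clustered_msa)

    def test_low_divergence_beats_raw_and_backend_alone(self):
        import bz2

        m = generate_msa(
            EvolutionParams(n=100, l=1000, substitution_prob=0.01, seed=7)
        )
        blob = compress(m)
        buf = io.StringIO()
        write_fasta_msa(m, buf)
        raw = buf.getvalue().encode()
        assert len(blob) < len(raw)
        assert len(blob) < len(bz2.compress(raw, 9))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 25))
        l = int(rng.integers(1, 60))
        m = random_msa(rng, n, l, alphabet="acgtACGTN-")
        assert decompress(compress(m)) == m
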