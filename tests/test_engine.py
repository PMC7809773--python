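"""Incremental linkage workflow: PID assignment, persistence, candidate
retrieval and the equivalence of the vectorized matcher with the scalar
similarity operations."""

import numpy as np
import pytest

from pprlink.blocking import BlockingConfig, retrieve_candidates
from pprlink.encoding import ConfigError, EncodingConfig, encode_record
from pprlink.engine import LinkageEngine, generate_pid
from pprlink.matching import (
    MatchingConfig,
    aggregate_similarity,
    compound_similarity,
    default_bloom_fields,
    default_plain_fields,
    dice_bits,
    dice_string,
    numeric_equality,
)
from pprlink.preprocessing import RawRecord, normalize_record

import random


def _raw(first, last, d, m, y, rid=None):
    return RawRecord(first, last, d, m, y, record_id=rid)


class TestInsertWorkflow:
    def test_empty_store_yields_new(self):
        eng = LinkageEngine(mode="plain")
        res = eng.insert_record(_raw("ANNA", "KLEIN", 1, 2, 1990, "r1"))
        assert res.status == "new" and res.pid
        assert res.candidate_count == 0

    def test_exact_duplicate_reuses_pid(self):
        eng = LinkageEngine(mode="plain")
        first = eng.insert_record(_raw("ANNA", "KLEIN", 1, 2, 1990, "r1"))
        dup = eng.insert_record(_raw("Anna", "Klein", "1", "2", "1990", "r2"))
        assert dup.status == "matched"
        assert dup.pid == first.pid
        assert dup.similarity == pytest.approx(1.0)

    def test_typo_duplicate_matches(self):
        eng = LinkageEngine(
            mode="plain",
            matching=MatchingConfig(tuple(default_plain_fields()), t1=0.8, t2=0.8),
        )
        first = eng.insert_record(_raw("STEFANIE", "SCHUMACHER", 3, 7, 1975, "r1"))
        dup = eng.insert_record(_raw("STEFANIE", "SCHUMACHR", 3, 7, 1975, "r2"))
        assert dup.status == "matched" and dup.pid == first.pid

    def test_invalid_record_not_persisted(self):
        eng = LinkageEngine(mode="plain")
        res = eng.insert_record(_raw("ANNA", "KLEIN", 31, 4, 1990, "bad"))
        assert res.status == "invalid" and res.pid is None
        assert eng.size() == 0

    def test_mode_mismatch_raises(self):
        enc = encode_record(
            normalize_record(_raw("ANNA", "KLEIN", 1, 2, 1990)), EncodingConfig()
        )
        eng = LinkageEngine(mode="plain")
        with pytest.raises(ConfigError):
            eng.insert_record(enc)

    def test_bloom_mode_accepts_encoded_and_raw(self):
        cfg = EncodingConfig()
        eng = LinkageEngine(mode="bloom", encoding=cfg)
        r1 = eng.insert_record(_raw("ANNA", "KLEIN", 1, 2, 1990, "r1"))
        enc = encode_record(normalize_record(_raw("ANNA", "KLEIN", 1, 2, 1990, "r2")), cfg)
        r2 = eng.insert_record(enc)
        assert r2.status == "matched" and r2.pid == r1.pid

    def test_possible_match_band(self):
        eng = LinkageEngine(
            mode="plain",
            matching=MatchingConfig(tuple(default_plain_fields()), t1=0.95, t2=0.60),
        )
        eng.insert_record(_raw("STEFANIE", "SCHUMACHER", 3, 7, 1975, "r1"))
        res = eng.insert_record(_raw("STEFANIE", "SCHUMACHER", 3, 7, 1999, "r2"))
        assert res.status == "possible"
        assert res.pid is not None  # persisted as a new patient, flagged


class TestPidGeneration:
    def test_unique_pids(self):
        rng, issued = random.Random(5), set()
        pids = {generate_pid(rng, issued) for _ in range(10_000)}
        assert len(pids) == 10_000

    def test_no_collision_after_reopen(self, tmp_path):
        path = str(tmp_path / "store.db")
        eng = LinkageEngine(mode="plain", store_path=path, seed=1)
        pid1 = eng.insert_record(_raw("ANNA", "KLEIN", 1, 2, 1990, "r1")).pid
        eng.close()
        eng2 = LinkageEngine(mode="plain", store_path=path, seed=1)
        pid2 = eng2.insert_record(_raw("OTTO", "WOLF", 9, 9, 1955, "r2")).pid
        assert pid1 != pid2
        eng2.close()


class TestPersistence:
    def test_reopen_preserves_matching(self, tmp_path):
        path = str(tmp_path / "store.db")
        eng = LinkageEngine(mode="plain", store_path=path)
        first = eng.insert_record(_raw("ANNA", "PINKETT SMITH", 1, 2, 1990, "r1"))
        eng.close()
        eng2 = LinkageEngine(mode="plain", store_path=path)
        assert eng2.size() == 1
        dup = eng2.insert_record(_raw("ANNA", "PINKETT", 1, 2, 1990, "r2"))
        assert dup.status == "matched" and dup.pid == first.pid
        eng2.close()

    def test_blocking_keys_persisted(self, tmp_path):
        path = str(tmp_path / "store.db")
        eng = LinkageEngine(mode="plain", store_path=path, blocking=BlockingConfig(method="soundex"))
        eng.insert_record(_raw("SARA", "MEYER", 1, 2, 1990, "r1"))
        stored = eng.store.get_patients([0])[0]
        assert any(k.method == "soundex" and k.value == "S600" for k in stored.keys)
        eng.close()


class TestCandidateRetrieval:
    def test_soundex_candidates(self, small_dataset):
        eng = LinkageEngine(
            mode="plain",
            matching=MatchingConfig(tuple(default_plain_fields()), t1=0.8, t2=0.8),
            blocking=BlockingConfig(method="soundex"),
            keep_candidates=True,
        )
        eng.insert_record(_raw("SARA", "MEYER", 1, 2, 1990, "r1"))
        eng.insert_record(_raw("ZARAH", "KLEIN", 3, 4, 1991, "r2"))
        res = eng.insert_record(_raw("SARAH", "WOLF", 5, 6, 1992, "r3"))
        # shares the first-name Soundex S600 with r1 only
        assert list(res.candidate_ordinals) == [0]

    def test_no_blocking_retrieves_all(self):
        eng = LinkageEngine(mode="plain", keep_candidates=True)
        for i in range(5):
            eng.insert_record(_raw("ANNA", f"KLEIN{i}X", 1, 2, 1990 + i, f"r{i}"))
        res = eng.insert_record(_raw("OTTO", "WOLF", 9, 9, 1955, "q"))
        assert res.candidate_count == 5
        assert list(res.candidate_ordinals) == [0, 1, 2, 3, 4]

    def test_retrieve_candidates_matches_brute_force(self, small_dataset):
        """Database-side retrieval equals a brute-force key-sharing filter."""
        eng = LinkageEngine(
            mode="bloom",
            matching=MatchingConfig(tuple(default_bloom_fields()), t1=0.85, t2=0.85),
            blocking=BlockingConfig(method="field-lsh", seed=4, sample_size=100),
            keep_candidates=True,
        )
        import pprlink.blocking as blk

        key_sets = {}  # test-side mirror of the persisted key table
        plan_before = eng.plan
        for raw in small_dataset.raw_records_a():
            norm = normalize_record(raw)
            enc = encode_record(norm, eng.encoding)
            qkeys = {k.as_tuple() for k in blk.record_keys(eng.blocking, plan_before, None, enc)}
            expected = sorted(o for o, ks in key_sets.items() if ks & qkeys)
            res = eng.insert_record(raw)
            if res.status == "invalid":
                continue
            assert list(res.candidate_ordinals) == expected
            key_sets[res.store_size_before] = qkeys
            if eng.plan is not plan_before:  # recalibration re-keyed the store
                plan_before = eng.plan
                for o in key_sets:
                    enc_o = eng._encoded_of(o)
                    key_sets[o] = {
                        k.as_tuple()
                        for k in blk.record_keys(eng.blocking, plan_before, None, enc_o)
                    }
        eng.close()

    def test_retrieve_candidates_function(self):
        eng = LinkageEngine(mode="plain", blocking=BlockingConfig(method="soundex"))
        eng.insert_record(_raw("SARA", "MEYER", 1, 2, 1990, "r1"))
        eng.insert_record(_raw("OTTO", "WOLF", 3, 4, 1991, "r2"))
        from pprlink.blocking import BlockingKey

        ordinals = retrieve_candidates([BlockingKey("soundex", 0, "S600")], eng.store)
        assert ordinals == [0]
        eng.close()


class TestVectorizedMatcherEquivalence:
    """The packed-bit matcher must reproduce the scalar similarity ops."""

    def _scalar_sim(self, eng, query_norm, stored_norm, mode, enc_cfg):
        sims, weights, present = {}, {}, {}
        if mode == "plain":
            items = [
                ("first_name", "dice"), ("last_name", "dice"),
                ("birth_day", "num"), ("birth_month", "num"), ("birth_year", "num"),
            ]
        else:
            items = [("first_name", "bloom"), ("last_name", "bloom"), ("dob", "bloom")]
            q_enc = encode_record(query_norm, enc_cfg)
            s_enc = encode_record(stored_norm, enc_cfg)
        for fc in eng.matching.fields:
            weights[fc.field_id] = fc.w
        for fld, kind in items:
            if kind == "dice":
                a, b = query_norm.name_components(fld), stored_norm.name_components(fld)
                present[fld] = bool(a) and bool(b)
                sims[fld] = (
                    compound_similarity(a, b, lambda x, y: dice_string(x, y, 2)) if present[fld] else 0.0
                )
            elif kind == "num":
                a, b = getattr(query_norm, fld), getattr(stored_norm, fld)
                present[fld] = a is not None and b is not None
                sims[fld] = numeric_equality(a, b)
            else:
                a, b = q_enc.components(fld), s_enc.components(fld)
                present[fld] = bool(a) and bool(b)
                sims[fld] = (
                    compound_similarity(a, b, dice_bits) if present[fld] else 0.0
                )
        if eng.matching.count_missing_weight:
            return aggregate_similarity(sims, weights)
        used = {f: w for f, w in weights.items() if present[f]}
        if not used:
            return 0.0
        return aggregate_similarity({f: sims[f] for f in used}, used)

    @pytest.mark.parametrize("mode", ["plain", "bloom"])
    @pytest.mark.parametrize("count_missing", [False, True])
    def test_engine_scores_equal_scalar_oracle(self, small_dataset, mode, count_missing):
        fields = default_plain_fields() if mode == "plain" else default_bloom_fields()
        matching = MatchingConfig(tuple(fields), t1=0.8, t2=0.8, count_missing_weight=count_missing)
        enc_cfg = EncodingConfig()
        eng = LinkageEngine(mode=mode, matching=matching, encoding=enc_cfg, keep_candidates=True)
        records = [r for r in small_dataset.raw_records_a()[:40]]
        normed = []
        for r in records:
            res = eng.insert_record(r)
            if res.status != "invalid":
                normed.append(normalize_record(r))
        queries = small_dataset.raw_records_b()[:15]
        for q in queries:
            qn = normalize_record(q)
            query = (
                eng._bloom_query(encode_record(qn, enc_cfg)) if mode == "bloom" else eng._plain_query(qn)
            )
            cand = np.arange(len(normed), dtype=np.int64)
            vec = eng._score(query, cand)
            for i, sn in enumerate(normed):
                expected = self._scalar_sim(eng, qn, sn, mode, enc_cfg)
                assert vec[i] == pytest.approx(expected, abs=1e-9), (q.record_id, i)
        eng.close()


class TestBatchLink:
    def test_empty_input(self):
        eng = LinkageEngine(mode="plain")
        assert eng.batch_link([]) == []

    def test_deterministic_decisions(self, tiny_dataset):
        def run():
            eng = LinkageEngine(
                mode="plain",
                matching=MatchingConfig(tuple(default_plain_fields()), t1=0.8, t2=0.8),
                seed=3,
            )
            res = eng.batch_link(tiny_dataset.raw_records_a())
            res += eng.batch_link(tiny_dataset.raw_records_b())
            eng.close()
            return [(r.record_id, r.status, r.matched_record_id) for r in res]

        assert run() == run()

    def test_pid_transitivity(self):
        """A B-record matching a stored duplicate inherits the cluster PID."""
        eng = LinkageEngine(
            mode="plain",
            matching=MatchingConfig(tuple(default_plain_fields()), t1=0.8, t2=0.8),
        )
        a = eng.insert_record(_raw("STEFANIE", "SCHUMACHER", 3, 7, 1975, "a"))
        b1 = eng.insert_record(_raw("STEFANIE", "SCHUMACHR", 3, 7, 1975, "b1"))
        b2 = eng.insert_record(_raw("STEFANIE", "SCHUMACHER", 3, 7, 1975, "b2"))
        assert b1.pid == a.pid and b2.pid == a.pid
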