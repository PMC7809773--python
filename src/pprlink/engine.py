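"""Incremental pseudonymization engine: validate -> transform/encode ->
retrieve candidates -> match -> assign PID -> persist.

Every inserted record is matched against the stored patients (all of
them, or only those sharing a blocking key), the best-scoring candidate
is classified against the thresholds, and the record receives either
the matched patient's PID or a freshly generated one.  Records, PIDs
and blocking keys are persisted in an embedded SQLite database whose
key table realizes the database-side blocking: candidate retrieval is
an indexed lookup on (method, key index, key value).

Matching is exact but vectorized: per field, the q-gram multisets
(plaintext mode) or Bloom filters (encoded mode) of all stored
component values live in packed-bit matrices, so one insert scores all
candidates with a handful of popcount passes instead of a Python loop.
"""

from __future__ import annotations

import json
import logging
import random
import sqlite3
import time
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import blocking as blk
from .blocking import BlockingConfig, BlockingKey, PositionPlan
from .encoding import (
    BitVector,
    ConfigError,
    EncodedRecord,
    EncodingConfig,
    encode_record,
    extract_qgrams,
)
from .matching import (
    MATCH,
    NON_MATCH,
    POSSIBLE,
    MatchDecision,
    MatchingConfig,
    compound_similarity_matrix,
    default_bloom_fields,
    default_plain_fields,
)
from .preprocessing import NormalizedRecord, RawRecord, normalize_record, validate_record

logger = logging.getLogger(__name__)

__all__ = ["StoredPatient", "InsertResult", "PatientStore", "LinkageEngine", "generate_pid"]

PID_ALPHABET = "ABCDEFGHJKLMNPQRSTUVWXYZ0123456789"
PID_LENGTH = 12


def generate_pid(rng: random.Random, issued: set) -> str:
    """Opaque 12-character alphanumeric pseudonym, never issued before
    by this store (the check-character scheme of the original service is
    deliberately replaced by uniqueness-checked random identifiers)."""
    while True:
        pid = "".join(rng.choice(PID_ALPHABET) for _ in range(PID_LENGTH))
        if pid not in issued:
            issued.add(pid)
            return pid


@dataclass
class StoredPatient:
    ordinal: int
    pid: str
    record_id: Optional[str]
    payload: dict
    keys: list = dc_field(default_factory=list)


@dataclass
class InsertResult:
    """Outcome of one insert: assigned PID, decision and bookkeeping."""

    record_id: Optional[str]
    pid: Optional[str]
    status: str  # "new" | "matched" | "possible" | "invalid"
    similarity: float = 0.0
    matched_record_id: Optional[str] = None
    matched_pid: Optional[str] = None
    candidate_count: int = 0
    store_size_before: int = 0
    timings: Dict[str, float] = dc_field(default_factory=dict)
    findings: list = dc_field(default_factory=list)
    candidate_ordinals: Optional[np.ndarray] = None
    decision: Optional[MatchDecision] = None


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

class PatientStore:
    """Embedded relational patient store (SQLite, single file or memory).

    Tables: patients(ordinal, record_id, pid, status, payload-JSON) and
    bkeys(method, idx, value, patient) with an index on (method, idx,
    value) so candidate retrieval is a lookup, plus a meta table for the
    persisted blocking plan.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self.con = sqlite3.connect(path)
        self.con.executescript(
            """
            CREATE TABLE IF NOT EXISTS patients(
                ordinal INTEGER PRIMARY KEY,
                record_id TEXT, pid TEXT NOT NULL, status TEXT, payload TEXT NOT NULL);
            CREATE TABLE IF NOT EXISTS bkeys(
                method TEXT NOT NULL, idx INTEGER NOT NULL,
                value TEXT NOT NULL, patient INTEGER NOT NULL);
            CREATE INDEX IF NOT EXISTS bkeys_lookup ON bkeys(method, idx, value);
            CREATE TABLE IF NOT EXISTS meta(k TEXT PRIMARY KEY, v TEXT);
            """
        )
        self.con.commit()

    # -- writes ------------------------------------------------------------
    def add_patient(self, ordinal: int, record_id, pid: str, status: str,
                    payload: dict, keys: Sequence[BlockingKey]) -> None:
        self.con.execute(
            "INSERT INTO patients(ordinal, record_id, pid, status, payload) VALUES (?,?,?,?,?)",
            (ordinal, record_id, pid, status, json.dumps(payload)),
        )
        if keys:
            self.con.executemany(
                "INSERT INTO bkeys(method, idx, value, patient) VALUES (?,?,?,?)",
                [(k.method, k.index, k.value, ordinal) for k in keys],
            )
        self.con.commit()

    def replace_lsh_keys(self, per_patient: Dict[int, Sequence[BlockingKey]]) -> None:
        """Re-persist LSH keys of all stored patients after recalibration."""
        self.con.execute("DELETE FROM bkeys WHERE method IN ('flsh','rlsh')")
        rows = [
            (k.method, k.index, k.value, ordinal)
            for ordinal, keys in per_patient.items()
            for k in keys
        ]
        self.con.executemany("INSERT INTO bkeys(method, idx, value, patient) VALUES (?,?,?,?)", rows)
        self.con.commit()

    def set_meta(self, key: str, value: str) -> None:
        self.con.execute("INSERT OR REPLACE INTO meta(k, v) VALUES (?,?)", (key, value))
        self.con.commit()

    def get_meta(self, key: str) -> Optional[str]:
        row = self.con.execute("SELECT v FROM meta WHERE k=?", (key,)).fetchone()
        return row[0] if row else None

    # -- reads -------------------------------------------------------------
    def size(self) -> int:
        return self.con.execute("SELECT COUNT(*) FROM patients").fetchone()[0]

    def patients_with_keys(self, keys: Sequence[BlockingKey]) -> List[int]:
        """Ordinals of stored patients sharing >= 1 key (sorted, distinct)."""
        if not keys:
            return []
        uniq = sorted({k.as_tuple() for k in keys})
        placeholders = ",".join(["(?,?,?)"] * len(uniq))
        params = [x for t in uniq for x in t]
        rows = self.con.execute(
            f"SELECT DISTINCT patient FROM bkeys WHERE (method, idx, value) IN (VALUES {placeholders}) "
            "ORDER BY patient",
            params,
        ).fetchall()
        return [r[0] for r in rows]

    def all_ordinals(self) -> List[int]:
        return [r[0] for r in self.con.execute("SELECT ordinal FROM patients ORDER BY ordinal")]

    def get_patients(self, ordinals: Sequence[int]) -> List[StoredPatient]:
        out = []
        for o in ordinals:
            row = self.con.execute(
                "SELECT ordinal, record_id, pid, payload FROM patients WHERE ordinal=?", (o,)
            ).fetchone()
            if row is None:
                raise KeyError(f"no stored patient with ordinal {o}")
            keys = [
                BlockingKey(m, i, v)
                for m, i, v in self.con.execute(
                    "SELECT method, idx, value FROM bkeys WHERE patient=?", (o,)
                )
            ]
            out.append(StoredPatient(row[0], row[2], row[1], json.loads(row[3]), keys))
        return out

    def iter_patients(self):
        for row in self.con.execute(
            "SELECT ordinal, record_id, pid, status, payload FROM patients ORDER BY ordinal"
        ):
            yield row[0], row[1], row[2], row[3], json.loads(row[4])

    def issued_pids(self) -> set:
        return {r[0] for r in self.con.execute("SELECT pid FROM patients")}

    def close(self):
        self.con.close()


# ---------------------------------------------------------------------------
# vectorized match index
# ---------------------------------------------------------------------------

def _grow(arr: np.ndarray, n: int) -> np.ndarray:
    if n <= len(arr):
        return arr
    new = np.zeros((max(n, 2 * len(arr), 64),) + arr.shape[1:], dtype=arr.dtype)
    new[: len(arr)] = arr
    return new


class _GramVocab:
    """Bijection (q-gram, occurrence index) -> bit position, grown on demand.

    Expanding a multiset into (gram, occurrence) pairs turns multiset
    intersection into a plain set intersection, so Dice over the packed
    indicator vectors is exactly the multiset q-gram Dice.
    """

    def __init__(self):
        self._index: Dict[Tuple[str, int], int] = {}

    def __len__(self):
        return len(self._index)

    def positions(self, grams: Sequence[str]) -> List[int]:
        from collections import Counter

        pos = []
        for gram, cnt in Counter(grams).items():
            for occ in range(cnt):
                key = (gram, occ)
                idx = self._index.get(key)
                if idx is None:
                    idx = len(self._index)
                    self._index[key] = idx
                pos.append(idx)
        return pos


class _DiceIndex:
    """Packed-bit rows (one per field component of each record) with
    per-record row ranges, supporting vectorized Dice against a query."""

    def __init__(self, width_bytes: int, fixed_width: bool):
        self.width = width_bytes
        self.fixed_width = fixed_width
        self.matrix = np.zeros((64, width_bytes), dtype=np.uint8)
        self.sizes = np.zeros(64, dtype=np.int64)  # gram count / cardinality
        self.nrows = 0
        self.ord_start = np.full(64, -1, dtype=np.int64)
        self.ord_ncomp = np.zeros(64, dtype=np.int64)
        self.nrec = 0

    def _ensure_width(self, width_bytes: int):
        if width_bytes > self.width:
            new = np.zeros((len(self.matrix), width_bytes), dtype=np.uint8)
            new[:, : self.width] = self.matrix
            self.matrix = new
            self.width = width_bytes

    def add_record(self, ordinal: int, comps: List[Tuple[np.ndarray, int]]):
        """Append the component rows of one record (ordinals must arrive
        in insertion order; empty comps = field missing)."""
        assert ordinal == self.nrec, "records must be added in ordinal order"
        self.ord_start = _grow(self.ord_start, ordinal + 1)
        self.ord_ncomp = _grow(self.ord_ncomp, ordinal + 1)
        if ordinal + 1 > len(self.ord_start):  # pragma: no cover
            raise AssertionError
        self.ord_start[ordinal] = self.nrows if comps else -1
        self.ord_ncomp[ordinal] = len(comps)
        self.nrec = ordinal + 1
        if not comps:
            return
        need = self.nrows + len(comps)
        self.matrix = _grow(self.matrix, need)
        self.sizes = _grow(self.sizes, need)
        for vec, size in comps:
            if len(vec) > self.width:
                if self.fixed_width:
                    raise ValueError("incompatible encodings: bit-vector length mismatch")
                self._ensure_width(len(vec))
            self.matrix[self.nrows, : len(vec)] = vec
            self.sizes[self.nrows] = size
            self.nrows += 1

    def sims(self, q_comps: List[Tuple[np.ndarray, int]], cand: np.ndarray) -> np.ndarray:
        """Compound field similarity of the query against each candidate."""
        n = len(cand)
        sims = np.zeros(n)
        if not q_comps or n == 0:
            return sims
        ncomp = self.ord_ncomp[cand]
        present = ncomp > 0
        if not present.any():
            return sims
        p_idx = np.flatnonzero(present)
        starts = self.ord_start[cand[p_idx]]
        counts = ncomp[p_idx]
        total = int(counts.sum())
        seg_start = np.concatenate(([0], np.cumsum(counts)[:-1]))
        row_idx = np.repeat(starts, counts) + (np.arange(total) - np.repeat(seg_start, counts))
        sub = self.matrix[row_idx]
        sub_sizes = self.sizes[row_idx]
        nq = len(q_comps)
        per_comp = np.empty((nq, total))
        for c, (vec, qsize) in enumerate(q_comps):
            # grams beyond the stored width were never indexed by any stored
            # row, so truncating the query vector cannot change intersections
            qv = np.zeros(self.width, dtype=np.uint8)
            w = min(len(vec), self.width)
            qv[:w] = vec[:w]
            inter = np.bitwise_count(sub & qv).sum(axis=1)
            denom = sub_sizes + qsize
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.where(denom > 0, 2.0 * inter / np.maximum(denom, 1), 0.0)
            per_comp[c] = d
        row_best = per_comp.max(axis=0)
        seg_best = np.maximum.reduceat(row_best, seg_start)
        if nq > 1:
            # greedy one-to-one assignment needed where both sides are compound
            for s in np.flatnonzero(counts > 1):
                lo = seg_start[s]
                block = per_comp[:, lo : lo + counts[s]]
                seg_best[s] = compound_similarity_matrix(block.tolist())
        sims[p_idx] = seg_best
        return sims

    def row_bits(self, row: int) -> np.ndarray:
        return self.matrix[row, : self.width]

    def record_vectors(self, ordinal: int, m: int) -> List[BitVector]:
        if self.ord_ncomp[ordinal] == 0:
            return []
        start = self.ord_start[ordinal]
        nbytes = (m + 7) // 8
        return [
            BitVector(self.matrix[start + j, :nbytes].copy(), m)
            for j in range(self.ord_ncomp[ordinal])
        ]


class _IntIndex:
    """Integer field values per record with a presence mask."""

    def __init__(self):
        self.values = np.zeros(64, dtype=np.int64)
        self.present = np.zeros(64, dtype=bool)
        self.nrec = 0

    def add_record(self, ordinal: int, value: Optional[int]):
        self.values = _grow(self.values, ordinal + 1)
        self.present = _grow(self.present, ordinal + 1)
        if value is not None:
            self.values[ordinal] = value
            self.present[ordinal] = True
        self.nrec = ordinal + 1

    def sims(self, qv: Optional[int], cand: np.ndarray) -> np.ndarray:
        if qv is None or len(cand) == 0:
            return np.zeros(len(cand))
        return ((self.values[cand] == qv) & self.present[cand]).astype(float)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class LinkageEngine:
    """Incremental record linkage with PID assignment.

    ``mode`` is ``"plain"`` (plaintext IDAT, q-gram Dice + date equality)
    or ``"bloom"`` (field-level Bloom filters, bit-vector Dice).  The
    same aggregation, thresholds and best-match machinery serves both.
    """

    def __init__(
        self,
        mode: str = "plain",
        store_path: str = ":memory:",
        matching: Optional[MatchingConfig] = None,
        encoding: Optional[EncodingConfig] = None,
        blocking: Optional[BlockingConfig] = None,
        seed: int = 0,
        validate: bool = True,
        keep_candidates: bool = False,
    ):
        if mode not in ("plain", "bloom"):
            raise ConfigError(f"unknown mode {mode!r}")
        self.mode = mode
        self.encoding = encoding or EncodingConfig()
        if matching is None:
            if mode == "plain":
                matching = MatchingConfig(tuple(default_plain_fields()), t1=0.9, t2=0.9)
            else:
                matching = MatchingConfig(tuple(default_bloom_fields()), t1=0.95, t2=0.95)
        self.matching = matching
        self.blocking = blocking or BlockingConfig(method=None)
        if self.blocking.method in ("field-lsh", "record-lsh") and mode != "bloom":
            raise ConfigError("LSH blocking operates on Bloom filters (mode='bloom')")
        if self.blocking.method == "soundex" and mode != "plain":
            raise ConfigError("Soundex blocking operates on plaintext names (mode='plain')")
        self.validate = validate
        self.keep_candidates = keep_candidates
        self.store = PatientStore(store_path)
        self._pid_rng = random.Random(seed * 2654435761 % (2**31) + 17)
        self._issued = self.store.issued_pids()
        self._weights = {fc.field_id: fc.w for fc in self.matching.fields}
        self._field_cfgs = {fc.field_id: fc for fc in self.matching.fields}
        self._vocab = _GramVocab()
        self._indexes: Dict[str, object] = {}
        self._ordinal_pid: List[str] = []
        self._ordinal_rid: List[Optional[str]] = []
        for fc in self.matching.fields:
            if fc.kind == "numeric-equality":
                self._indexes[fc.field_id] = _IntIndex()
            elif fc.kind == "string-dice":
                self._indexes[fc.field_id] = _DiceIndex(width_bytes=16, fixed_width=False)
            elif fc.kind == "bloom-dice":
                m = self.encoding.field_encoding(fc.field_id).m
                self._indexes[fc.field_id] = _DiceIndex(width_bytes=(m + 7) // 8, fixed_width=True)
            else:
                raise ConfigError(f"unknown similarity kind {fc.kind!r}")
        self._plan = self._load_or_init_plan()
        self._rehydrate()

    # -- plan persistence --------------------------------------------------
    def _load_or_init_plan(self) -> Optional[PositionPlan]:
        if self.blocking.method not in ("field-lsh", "record-lsh"):
            return None
        raw = self.store.get_meta("lsh_plan")
        if raw:
            d = json.loads(raw)
            plan = PositionPlan(method=d["method"], calibrated=d["calibrated"])
            plan.field_positions = {
                f: [np.asarray(p, dtype=np.int64) for p in lst]
                for f, lst in d["field_positions"].items()
            }
            plan.record_positions = [
                {f: np.asarray(p, dtype=np.int64) for f, p in per.items()}
                for per in d["record_positions"]
            ]
            plan.eligible = {f: np.asarray(p, dtype=np.int64) for f, p in d["eligible"].items()}
            return plan
        plan = blk.initial_plan(self.blocking, self.encoding)
        self._save_plan(plan)
        return plan

    def _save_plan(self, plan: PositionPlan) -> None:
        self.store.set_meta(
            "lsh_plan",
            json.dumps(
                {
                    "method": plan.method,
                    "calibrated": plan.calibrated,
                    "field_positions": {
                        f: [p.tolist() for p in lst] for f, lst in plan.field_positions.items()
                    },
                    "record_positions": [
                        {f: p.tolist() for f, p in per.items()} for per in plan.record_positions
                    ],
                    "eligible": {f: p.tolist() for f, p in plan.eligible.items()},
                }
            ),
        )

    # -- (re)building the in-memory index ----------------------------------
    def _rehydrate(self):
        for ordinal, record_id, pid, _status, payload in self.store.iter_patients():
            self._ordinal_pid.append(pid)
            self._ordinal_rid.append(record_id)
            if self.mode == "plain":
                norm = _norm_from_payload(payload)
                self._index_plain(ordinal, norm)
            else:
                enc = _encoded_from_payload(payload)
                self._index_bloom(ordinal, enc)

    # -- per-field query/storage primitives ---------------------------------
    def _gram_comps(self, comps: Sequence[str], q: int) -> List[Tuple[np.ndarray, int]]:
        out = []
        for comp in comps:
            grams = extract_qgrams(comp, q, padded=False).grams
            if not grams:
                continue
            pos = self._vocab.positions(grams)
            width = (max(pos) // 8 + 1) if pos else 1
            vec = np.zeros(width, dtype=np.uint8)
            for p in pos:
                vec[p >> 3] |= np.uint8(1 << (p & 7))
            out.append((vec, len(grams)))
        return out

    def _plain_query(self, norm: NormalizedRecord) -> Dict[str, object]:
        query = {}
        for fld, fc in self._field_cfgs.items():
            if fc.kind == "string-dice":
                query[fld] = self._gram_comps(norm.name_components(fld), fc.q)
            else:
                query[fld] = getattr(norm, fld)
        return query

    def _bloom_query(self, enc: EncodedRecord) -> Dict[str, object]:
        return {
            fld: [(bv.bits, bv.cardinality()) for bv in enc.components(fld)]
            for fld in self._field_cfgs
        }

    def _index_plain(self, ordinal: int, norm: NormalizedRecord):
        query = self._plain_query(norm)
        for fld, fc in self._field_cfgs.items():
            self._indexes[fld].add_record(ordinal, query[fld])

    def _index_bloom(self, ordinal: int, enc: EncodedRecord):
        query = self._bloom_query(enc)
        for fld in self._field_cfgs:
            self._indexes[fld].add_record(ordinal, query[fld])

    # -- matching -----------------------------------------------------------
    def _score(self, query: Dict[str, object], cand: np.ndarray):
        """Aggregate similarity of the query against each candidate ordinal."""
        total_w = sum(self._weights.values())
        num = np.zeros(len(cand))
        if not self.matching.count_missing_weight:
            den = np.zeros(len(cand))
        for fld, fc in self._field_cfgs.items():
            idx = self._indexes[fld]
            q = query[fld]
            s = idx.sims(q, cand)
            num += self._weights[fld] * s
            if not self.matching.count_missing_weight:
                if isinstance(idx, _IntIndex):
                    both = (q is not None) & idx.present[cand]
                else:
                    both = bool(q) & (idx.ord_ncomp[cand] > 0)
                den += self._weights[fld] * both
        if self.matching.count_missing_weight:
            return num / total_w
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)

    # -- the workflow --------------------------------------------------------
    def insert_record(self, record: Union[RawRecord, EncodedRecord]) -> InsertResult:
        """Full add-patient workflow for one record; returns the assigned
        PID and the match decision."""
        norm: Optional[NormalizedRecord] = None
        enc: Optional[EncodedRecord] = None
        if isinstance(record, RawRecord):
            findings = validate_record(record) if self.validate else []
            errors = [f for f in findings if f.severity == "error"]
            if errors:
                return InsertResult(record.record_id, None, "invalid", findings=findings)
            norm = normalize_record(record)
            if self.mode == "bloom":
                enc = encode_record(norm, self.encoding)
        elif isinstance(record, EncodedRecord):
            if self.mode != "bloom":
                raise ConfigError("cannot insert an encoded record into a plaintext store")
            enc = record
        else:
            raise TypeError(f"unsupported record type {type(record)!r}")

        record_id = record.record_id
        size = len(self._ordinal_pid)

        t0 = time.perf_counter()
        keys = blk.record_keys(self.blocking, self._plan, norm, enc)
        if self.blocking.method is None:
            cand = np.arange(size, dtype=np.int64)
        else:
            cand = np.asarray(self.store.patients_with_keys(keys), dtype=np.int64)
        t1 = time.perf_counter()

        query = self._bloom_query(enc) if self.mode == "bloom" else self._plain_query(norm)
        if len(cand):
            agg = self._score(query, cand)
            best_i = int(np.argmax(agg))  # first max = earliest-inserted ordinal
            best_ord = int(cand[best_i])
            best_sim = float(agg[best_i])
        else:
            best_ord, best_sim = None, 0.0
        if best_ord is None:
            cls = NON_MATCH
        elif best_sim >= self.matching.t1:
            cls = MATCH
        elif best_sim >= self.matching.t2:
            cls = POSSIBLE
        else:
            cls = NON_MATCH
        t2 = time.perf_counter()

        if cls == MATCH:
            pid = self._ordinal_pid[best_ord]
            status = "matched"
        else:
            pid = generate_pid(self._pid_rng, self._issued)
            status = "possible" if cls == POSSIBLE else "new"

        ordinal = size
        payload = _payload_of(norm, enc, self.mode)
        self.store.add_patient(ordinal, record_id, pid, status, payload, keys)
        self._ordinal_pid.append(pid)
        self._ordinal_rid.append(record_id)
        if self.mode == "plain":
            self._index_plain(ordinal, norm)
        else:
            self._index_bloom(ordinal, enc)
        t3 = time.perf_counter()

        if (
            self._plan is not None
            and not self._plan.calibrated
            and len(self._ordinal_pid) >= self.blocking.sample_size
        ):
            self._recalibrate()

        decision = MatchDecision(
            query_id=record_id,
            candidate_id=self._ordinal_rid[best_ord] if best_ord is not None else None,
            similarity=best_sim,
            decision=cls,
        )
        return InsertResult(
            record_id=record_id,
            pid=pid,
            status=status,
            similarity=best_sim,
            matched_record_id=decision.candidate_id if cls == MATCH else None,
            matched_pid=self._ordinal_pid[best_ord] if cls == MATCH else None,
            candidate_count=len(cand),
            store_size_before=size,
            timings={"retrieval": t1 - t0, "matching": t2 - t1, "persistence": t3 - t2},
            candidate_ordinals=cand.copy() if self.keep_candidates else None,
            decision=decision,
        )

    def _encoded_of(self, ordinal: int) -> EncodedRecord:
        filters = {}
        for fld, fc in self._field_cfgs.items():
            if fc.kind != "bloom-dice":
                continue
            m = self.encoding.field_encoding(fld).m
            vecs = self._indexes[fld].record_vectors(ordinal, m)
            if vecs:
                filters[fld] = vecs
        return EncodedRecord(filters=filters, record_id=self._ordinal_rid[ordinal])

    def _recalibrate(self):
        """Prune frequent bit positions on the first-N sample, re-draw key
        positions and re-key every stored patient."""
        n = self.blocking.sample_size
        sample = [self._encoded_of(o) for o in range(min(n, len(self._ordinal_pid)))]
        self._plan = blk.calibrate_positions(sample, self.blocking, self.encoding)
        self._save_plan(self._plan)
        per_patient = {
            o: blk.record_keys(self.blocking, self._plan, None, self._encoded_of(o))
            for o in range(len(self._ordinal_pid))
        }
        self.store.replace_lsh_keys(per_patient)
        logger.info("LSH plan recalibrated on %d records; %d patients re-keyed", n, len(per_patient))

    def batch_link(self, records: Iterable[Union[RawRecord, EncodedRecord]]) -> List[InsertResult]:
        """Sequential insert of a record stream, preserving order.

        Invalid rows are reported in the result list (status "invalid")
        and skipped without persistence.
        """
        results = []
        skipped = 0
        for rec in records:
            res = self.insert_record(rec)
            if res.status == "invalid":
                skipped += 1
                logger.warning("skipped invalid record %s: %s", res.record_id, res.findings)
            results.append(res)
        if skipped:
            logger.info("batch complete: %d records, %d invalid rows skipped", len(results), skipped)
        return results

    @property
    def plan(self) -> Optional[PositionPlan]:
        """The LSH position plan currently in effect (None for Soundex /
        no blocking)."""
        return self._plan

    def size(self) -> int:
        return len(self._ordinal_pid)

    def pid_of_ordinal(self, ordinal: int) -> str:
        return self._ordinal_pid[ordinal]

    def close(self):
        self.store.close()


# ---------------------------------------------------------------------------
# payload (de)serialization
# ---------------------------------------------------------------------------

def _payload_of(norm: Optional[NormalizedRecord], enc: Optional[EncodedRecord], mode: str) -> dict:
    if mode == "plain":
        return {
            "kind": "plain",
            "first_name": norm.first_name,
            "last_name": norm.last_name,
            "birth_day": norm.birth_day,
            "birth_month": norm.birth_month,
            "birth_year": norm.birth_year,
        }
    return {
        "kind": "bloom",
        "fields": {
            fld: [{"m": bv.m, "bits": bv.to_b64()} for bv in bvs]
            for fld, bvs in enc.filters.items()
        },
    }


def _norm_from_payload(payload: dict) -> NormalizedRecord:
    from .preprocessing import split_compound

    first = payload.get("first_name") or None
    last = payload.get("last_name") or None
    return NormalizedRecord(
        first_name=first,
        first_components=tuple(split_compound(first or "")),
        last_name=last,
        last_components=tuple(split_compound(last or "")),
        birth_day=payload.get("birth_day"),
        birth_month=payload.get("birth_month"),
        birth_year=payload.get("birth_year"),
    )


def _encoded_from_payload(payload: dict) -> EncodedRecord:
    return EncodedRecord(
        filters={
            fld: [BitVector.from_b64(d["bits"], d["m"]) for d in lst]
            for fld, lst in payload["fields"].items()
        }
    )
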