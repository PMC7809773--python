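"""Field-level Bloom filter encoding of normalized IDAT (C-IDAT).

Each name component is split into q-grams (q=2 by default, with framing
pad characters) and hashed into its own bit vector of length m with k
keyed hash functions; the three birth-date components share one joint
filter.  Positions come from double hashing under a shared secret:
p_i(e) = (H1(e) + i*H2(e)) mod m, H1/H2 taken from a keyed BLAKE2b
digest, so all data holders with the same config produce bit-identical
encodings.

Bit-order convention: bit i of a vector is bit (i mod 8) of byte
floor(i/8) (little-endian within bytes); serialized as base64 of the
byte string with m recorded alongside.
"""

from __future__ import annotations

import base64
import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np

from .preprocessing import NormalizedRecord

__all__ = [
    "QGramSet",
    "BitVector",
    "FieldEncoding",
    "EncodingConfig",
    "EncodedRecord",
    "extract_qgrams",
    "encode_features",
    "encode_record",
    "dob_feature_string",
    "write_encoded_jsonl",
    "read_encoded_jsonl",
]

BLOOM_FIELDS = ("first_name", "last_name", "dob")


class ConfigError(ValueError):
    """Invalid encoding/matching/blocking configuration."""


@dataclass(frozen=True)
class QGramSet:
    """Multiset of q-grams of a string (gram order is not significant,
    multiplicity is)."""

    grams: tuple
    q: int
    padded: bool

    def counts(self) -> Counter:
        return Counter(self.grams)

    def __len__(self) -> int:
        return len(self.grams)


def extract_qgrams(s: str, q: int = 2, padded: bool = True, pad_char: str = "_") -> QGramSet:
    """Split ``s`` into overlapping substrings of length q.

    With padding the string is framed by q-1 pad characters on each side,
    so every original character occurs in exactly q grams and a padded
    string of length n yields n+q-1 grams.  Empty input yields no grams.
    """
    if q < 1:
        raise ConfigError(f"q must be >= 1, got {q}")
    if not s:
        return QGramSet((), q, padded)
    if padded:
        s = pad_char * (q - 1) + s + pad_char * (q - 1)
    grams = tuple(s[i : i + q] for i in range(len(s) - q + 1))
    return QGramSet(grams, q, padded)


class BitVector:
    """Fixed-length bit vector backed by packed uint8 bytes.

    Index 0 is the leftmost bit of the string form (``to01``), stored as
    the least-significant bit of byte 0.
    """

    __slots__ = ("bits", "m")

    def __init__(self, bits: np.ndarray, m: int):
        if bits.dtype != np.uint8:
            raise TypeError("bits must be uint8")
        if len(bits) != (m + 7) // 8:
            raise ValueError(f"need {(m + 7) // 8} bytes for m={m}, got {len(bits)}")
        self.bits = bits
        self.m = m

    # -- constructors ------------------------------------------------------
    @classmethod
    def zeros(cls, m: int) -> "BitVector":
        return cls(np.zeros((m + 7) // 8, dtype=np.uint8), m)

    @classmethod
    def from_bools(cls, bools) -> "BitVector":
        arr = np.asarray(bools, dtype=np.uint8)
        return cls(np.packbits(arr, bitorder="little"), len(arr))

    @classmethod
    def from01(cls, s: str) -> "BitVector":
        return cls.from_bools([int(c) for c in s])

    @classmethod
    def from_positions(cls, positions: Iterable[int], m: int) -> "BitVector":
        bools = np.zeros(m, dtype=np.uint8)
        pos = np.asarray(list(positions), dtype=np.int64)
        if len(pos):
            if pos.min() < 0 or pos.max() >= m:
                raise ValueError("bit position out of range")
            bools[pos] = 1
        return cls.from_bools(bools)

    # -- views -------------------------------------------------------------
    def to_bools(self) -> np.ndarray:
        return np.unpackbits(self.bits, bitorder="little")[: self.m]

    def to01(self) -> str:
        return "".join("1" if b else "0" for b in self.to_bools())

    def get(self, i: int) -> int:
        if not 0 <= i < self.m:
            raise IndexError(f"bit position {i} out of range for m={self.m}")
        return (self.bits[i >> 3] >> (i & 7)) & 1

    def cardinality(self) -> int:
        return int(np.bitwise_count(self.bits).sum())

    # -- ops ---------------------------------------------------------------
    def __and__(self, other: "BitVector") -> "BitVector":
        if self.m != other.m:
            raise ValueError(f"length mismatch: {self.m} != {other.m}")
        return BitVector(self.bits & other.bits, self.m)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BitVector)
            and self.m == other.m
            and np.array_equal(self.bits, other.bits)
        )

    def __hash__(self):
        return hash((self.m, self.bits.tobytes()))

    def __repr__(self):
        return f"BitVector(m={self.m}, card={self.cardinality()})"

    # -- serialization -----------------------------------------------------
    def to_b64(self) -> str:
        return base64.b64encode(self.bits.tobytes()).decode("ascii")

    @classmethod
    def from_b64(cls, b64: str, m: int) -> "BitVector":
        raw = base64.b64decode(b64)
        return cls(np.frombuffer(raw, dtype=np.uint8).copy(), m)


def _positions(gram: str, m: int, k: int, secret: bytes, salt: str) -> np.ndarray:
    """Double-hashing positions of one feature under the shared secret."""
    msg = f"{salt}\x1f{gram}".encode("utf-8")
    digest = hashlib.blake2b(msg, key=secret, digest_size=16).digest()
    h1 = int.from_bytes(digest[:8], "little")
    h2 = int.from_bytes(digest[8:], "little") | 1  # odd: full cycle for m = 2^r
    i = np.arange(k, dtype=np.uint64)
    return ((h1 + i * h2) % np.uint64(m)).astype(np.int64)


def encode_features(
    features: QGramSet,
    m: int,
    k: int,
    secret: bytes,
    salt: str = "",
) -> BitVector:
    """Map every feature into the bit vector with k keyed hash functions.

    Setting a bit twice has no effect, so the cardinality is at most
    min(m, k * #distinct features).  Deterministic in (features, m, k,
    secret, salt).
    """
    if m < 8 or k < 1:
        raise ConfigError(f"invalid Bloom parameters m={m}, k={k}")
    bools = np.zeros(m, dtype=np.uint8)
    for gram in set(features.grams):
        bools[_positions(gram, m, k, secret, salt)] = 1
    return BitVector(np.packbits(bools, bitorder="little"), m)


@dataclass(frozen=True)
class FieldEncoding:
    """Per-field Bloom encoding parameters."""

    m: int = 512
    k: int = 10
    q: int = 2
    padded: bool = True
    pad_char: str = "_"


@dataclass(frozen=True)
class EncodingConfig:
    """Shared client-side encoding configuration.

    All data holders must use an identical config (including the secret)
    for their encoded records to be comparable.  Default k values are
    calibrated on German-style name data so that the corpus-mean 1-bit
    share sits in the high teens to ~25% band: low enough that the Dice
    noise floor (roughly the fill rate) keeps bit-vector Dice within
    +-0.15 of q-gram Dice on average, high enough for error tolerance.
    """

    secret: bytes = b"pprlink-demo-secret"
    first_name: FieldEncoding = field(default_factory=FieldEncoding)
    last_name: FieldEncoding = field(default_factory=FieldEncoding)
    # 3 whole-value DOB features, so k is high to reach the target fill
    dob: FieldEncoding = field(default_factory=lambda: FieldEncoding(m=256, k=24))
    joint_dob: bool = True

    def field_encoding(self, fld: str) -> FieldEncoding:
        return getattr(self, fld)


@dataclass
class EncodedRecord:
    """C-IDAT: per field an ordered list of component Bloom filters
    (missing fields absent), plus the record id."""

    filters: Dict[str, List[BitVector]]
    record_id: Optional[str] = None

    def components(self, fld: str) -> List[BitVector]:
        return self.filters.get(fld, [])


def dob_feature_string(day: Optional[int], month: Optional[int], year: Optional[int]):
    """Whole-value tagged features for the joint DOB filter, e.g.
    ['D07', 'M05', 'Y1990'].

    Date components carry equality semantics (mirroring the numeric
    comparison on plaintext), so each zero-padded component becomes one
    tagged feature rather than q-grams: two dates share a feature iff a
    component is identical, and unrelated dates share nothing.  Q-grams
    of digit strings would leak century/decade/pad grams (19xx, _0...)
    into near-universal overlap, inflating the similarity of unrelated
    dates.  Missing components are skipped.
    """
    parts = []
    if day is not None:
        parts.append(f"D{day:02d}")
    if month is not None:
        parts.append(f"M{month:02d}")
    if year is not None:
        parts.append(f"Y{year:04d}")
    return parts


def encode_record(r: NormalizedRecord, cfg: EncodingConfig) -> EncodedRecord:
    """Encode a normalized record into field-level Bloom filters.

    One filter per compound component of each name field; day, month and
    year are combined into a single joint filter.  Missing fields are
    omitted entirely.
    """
    filters: Dict[str, List[BitVector]] = {}
    for fld in ("first_name", "last_name"):
        comps = r.name_components(fld)
        if not comps:
            continue
        fe = cfg.field_encoding(fld)
        filters[fld] = [
            encode_features(
                extract_qgrams(comp, fe.q, fe.padded, fe.pad_char),
                fe.m,
                fe.k,
                cfg.secret,
                salt=fld,
            )
            for comp in comps
        ]
    dob_parts = dob_feature_string(r.birth_day, r.birth_month, r.birth_year)
    if dob_parts:
        fe = cfg.dob
        filters["dob"] = [
            encode_features(
                QGramSet(tuple(dob_parts), fe.q, fe.padded), fe.m, fe.k, cfg.secret, salt="dob"
            )
        ]
    return EncodedRecord(filters=filters, record_id=r.record_id)


# -- serialization: one JSON object per line -------------------------------

def write_encoded_jsonl(records: Iterable[EncodedRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "record_id": rec.record_id,
                "fields": {
                    fld: [{"m": bv.m, "bits": bv.to_b64()} for bv in bvs]
                    for fld, bvs in rec.filters.items()
                },
            }
            fh.write(json.dumps(obj) + "\n")


def read_encoded_jsonl(path) -> list:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            filters = {
                fld: [BitVector.from_b64(d["bits"], d["m"]) for d in lst]
                for fld, lst in obj["fields"].items()
            }
            out.append(EncodedRecord(filters=filters, record_id=obj.get("record_id")))
    return out
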