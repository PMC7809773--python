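"""Blocking-key generation: Soundex, field-level and record-level
Hamming-LSH on Bloom filters, plus LSH position calibration.

Two records become match candidates iff they share at least one
(method, key index, key value) triple.  Soundex keys come from the
phonetic codes of first/last name components.  LSH keys sample Psi bit
positions from the Bloom filters: FieldLSH draws all bits of one key
from a single field's filter (Lambda_i keys per field, error-tolerant,
larger blocks), RecordLSH spreads each of its Lambda keys over all
fields (Psi = sum_i Psi_i bits, smaller blocks).  Frequently-0/1 bit
positions are pruned at runtime from a calibration sample of the first
N inserted records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .encoding import BitVector, ConfigError, EncodedRecord, EncodingConfig
from .preprocessing import NormalizedRecord

__all__ = [
    "BlockingConfig",
    "BlockingKey",
    "PositionPlan",
    "soundex",
    "soundex_keys",
    "hlsh_extract",
    "field_lsh_keys",
    "record_lsh_keys",
    "initial_plan",
    "calibrate_positions",
    "record_keys",
    "retrieve_candidates",
]

SOUNDEX_FIELDS_DEFAULT = ("first_name", "last_name")
LSH_FIELDS_DEFAULT = ("first_name", "last_name", "dob")

_SOUNDEX_CODES = {}
for _letters, _code in (
    ("BFPV", "1"),
    ("CGJKQSXZ", "2"),
    ("DT", "3"),
    ("L", "4"),
    ("MN", "5"),
    ("R", "6"),
):
    for _ch in _letters:
        _SOUNDEX_CODES[_ch] = _code


def soundex(name: str) -> str:
    """Standard American Soundex code (letter + 3 digits, zero-padded).

    'SARA' and 'SARAH' both map to S600, 'ZARAH' to Z600, so one typo at
    the start of a name defeats the blocking key.  Empty or non-alphabetic
    input yields an empty code (no key).
    """
    letters = [c for c in name.upper() if "A" <= c <= "Z"]
    if not letters:
        return ""
    first = letters[0]
    code = [first]
    prev = _SOUNDEX_CODES.get(first, "")
    for ch in letters[1:]:
        digit = _SOUNDEX_CODES.get(ch, "")
        if digit and digit != prev:
            code.append(digit)
            if len(code) == 4:
                break
        # H and W are transparent: the previous code survives them;
        # vowels reset it so repeats across vowels are coded again.
        if ch not in "HW":
            prev = digit
    return "".join(code) + "0" * (4 - len(code))


@dataclass(frozen=True)
class BlockingKey:
    """One blocking key of a record; equality of all three parts defines
    candidacy."""

    method: str  # "soundex" | "flsh" | "rlsh"
    index: int
    value: str

    def as_tuple(self) -> Tuple[str, int, str]:
        return (self.method, self.index, self.value)


@dataclass(frozen=True)
class BlockingConfig:
    """Blocking method and its parameters.

    method: None (no blocking), "soundex", "field-lsh" or "record-lsh".
    For field-lsh, ``lambdas`` gives the key count per field and ``psi``
    the key length; for record-lsh, ``lam`` keys each concatenate
    ``psi_per_field[f]`` bits per field.  Calibration uses the first
    ``sample_size`` records and prunes the ``prune_ratio`` fraction of
    positions whose 1-frequency is most extreme.
    """

    method: Optional[str] = None
    soundex_fields: tuple = SOUNDEX_FIELDS_DEFAULT
    lambdas: Optional[Dict[str, int]] = None  # field-lsh keys per field
    psi: int = 36  # field-lsh key length
    lam: int = 9  # record-lsh key count
    psi_per_field: Optional[Dict[str, int]] = None  # record-lsh bits per field
    sample_size: int = 1000
    prune_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.method not in (None, "soundex", "field-lsh", "record-lsh"):
            raise ConfigError(f"unknown blocking method {self.method!r}")
        if not 0 <= self.prune_ratio < 1:
            raise ConfigError("prune ratio must be in [0,1)")

    def effective_lambdas(self) -> Dict[str, int]:
        return dict(self.lambdas) if self.lambdas else {f: 1 for f in LSH_FIELDS_DEFAULT}

    def effective_psis(self) -> Dict[str, int]:
        return dict(self.psi_per_field) if self.psi_per_field else {f: 8 for f in LSH_FIELDS_DEFAULT}


@dataclass
class PositionPlan:
    """Sampled bit positions per LSH key, plus the per-field eligibility
    mask from calibration (None before calibration)."""

    method: str
    # field-lsh: {field: [positions-array per key j]}; key index is global.
    field_positions: Dict[str, List[np.ndarray]] = field(default_factory=dict)
    # record-lsh: per key j, {field: positions-array}
    record_positions: List[Dict[str, np.ndarray]] = field(default_factory=list)
    eligible: Dict[str, np.ndarray] = field(default_factory=dict)
    calibrated: bool = False

    def key_index_of(self, fld: str, j: int, order: Sequence[str]) -> int:
        """Global key index of field-lsh key j of ``fld``."""
        idx = 0
        for f in order:
            if f == fld:
                return idx + j
            idx += len(self.field_positions.get(f, ()))
        raise KeyError(fld)


def hlsh_extract(bv: BitVector, positions: Sequence[int]) -> str:
    """Concatenate the bit values at the given positions (0-based from
    the left of the vector's string form).  The Hamming-LSH hash f_i is
    the single-position case: f_7 of 11011001 returns '1'."""
    return "".join(str(bv.get(int(p))) for p in positions)


def _draw_positions(rng: np.random.Generator, eligible: np.ndarray, n: int, fld: str) -> np.ndarray:
    if len(eligible) < n:
        raise ConfigError(
            f"field {fld!r}: only {len(eligible)} eligible bit positions for a "
            f"{n}-bit key; reduce the key length or the prune ratio"
        )
    return rng.choice(eligible, size=n, replace=False)


def _draw_plan(
    cfg: BlockingConfig,
    enc: EncodingConfig,
    eligible: Dict[str, np.ndarray],
    rng: np.random.Generator,
    calibrated: bool,
) -> PositionPlan:
    plan = PositionPlan(method=cfg.method, eligible=dict(eligible), calibrated=calibrated)
    if cfg.method == "field-lsh":
        for fld, lam_i in cfg.effective_lambdas().items():
            plan.field_positions[fld] = [
                _draw_positions(rng, eligible[fld], cfg.psi, fld) for _ in range(lam_i)
            ]
    elif cfg.method == "record-lsh":
        psis = cfg.effective_psis()
        for _ in range(cfg.lam):
            plan.record_positions.append(
                {fld: _draw_positions(rng, eligible[fld], n, fld) for fld, n in psis.items()}
            )
    return plan


def _all_positions(enc: EncodingConfig) -> Dict[str, np.ndarray]:
    return {fld: np.arange(enc.field_encoding(fld).m) for fld in LSH_FIELDS_DEFAULT}


def initial_plan(cfg: BlockingConfig, enc: EncodingConfig) -> PositionPlan:
    """Uncalibrated plan: every bit position is eligible."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    return _draw_plan(cfg, enc, _all_positions(enc), rng, calibrated=False)


def calibrate_positions(
    sample: Sequence[EncodedRecord],
    cfg: BlockingConfig,
    enc: EncodingConfig,
) -> PositionPlan:
    """Prune frequently-0/1 bit positions and re-draw all key positions.

    Per field, the 1-bit frequency of every position is measured over the
    sample (all component filters); positions are ranked by distance of
    that frequency from 0.5 and the most extreme ``prune_ratio`` fraction
    is excluded.  Key positions are then re-drawn uniformly (seeded) from
    the retained positions.
    """
    eligible: Dict[str, np.ndarray] = {}
    for fld in LSH_FIELDS_DEFAULT:
        m = enc.field_encoding(fld).m
        rows = [bv.to_bools() for rec in sample for bv in rec.components(fld)]
        if not rows:
            eligible[fld] = np.arange(m)
            continue
        freq = np.mean(rows, axis=0)
        keep = max(1, int(round(m * (1.0 - cfg.prune_ratio))))
        order = np.argsort(np.abs(freq - 0.5), kind="stable")
        eligible[fld] = np.sort(order[:keep])
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    return _draw_plan(cfg, enc, eligible, rng, calibrated=True)


def soundex_keys(r: NormalizedRecord, fields: Sequence[str] = SOUNDEX_FIELDS_DEFAULT) -> list:
    """Soundex keys, one per name component; missing fields yield none."""
    keys = []
    for idx, fld in enumerate(fields):
        for comp in r.name_components(fld):
            code = soundex(comp)
            if code:
                keys.append(BlockingKey("soundex", idx, code))
    return keys


def field_lsh_keys(rec: EncodedRecord, plan: PositionPlan) -> list:
    """FieldLSH: all bits of one key come from one field's filter; compound
    fields contribute one key instance per component filter."""
    keys = []
    order = list(plan.field_positions)
    for fld in order:
        for j, positions in enumerate(plan.field_positions[fld]):
            idx = plan.key_index_of(fld, j, order)
            for bv in rec.components(fld):
                keys.append(BlockingKey("flsh", idx, hlsh_extract(bv, positions)))
    return keys


MISSING_SENTINEL = "x"


def record_lsh_keys(rec: EncodedRecord, plan: PositionPlan) -> list:
    """RecordLSH: key j concatenates Psi_i bits from every field's filter
    (first component for compound fields); a missing field contributes a
    fixed sentinel run so key length stays stable."""
    keys = []
    for j, per_field in enumerate(plan.record_positions):
        parts = []
        for fld, positions in per_field.items():
            comps = rec.components(fld)
            if comps:
                parts.append(hlsh_extract(comps[0], positions))
            else:
                parts.append(MISSING_SENTINEL * len(positions))
        keys.append(BlockingKey("rlsh", j, "".join(parts)))
    return keys


def record_keys(
    cfg: BlockingConfig,
    plan: Optional[PositionPlan],
    normalized: Optional[NormalizedRecord],
    encoded: Optional[EncodedRecord],
) -> list:
    """Blocking keys of one record under the configured method."""
    if cfg.method is None:
        return []
    if cfg.method == "soundex":
        if normalized is None:
            raise ConfigError("Soundex blocking requires plaintext records")
        return soundex_keys(normalized, cfg.soundex_fields)
    if encoded is None:
        raise ConfigError("LSH blocking requires encoded records")
    if cfg.method == "field-lsh":
        return field_lsh_keys(encoded, plan)
    return record_lsh_keys(encoded, plan)


def retrieve_candidates(keys: Sequence[BlockingKey], store) -> list:
    """Stored patients sharing at least one blocking key with the query
    (database-side blocking; no duplicates, insertion order preserved).
    With blocking disabled (no keys requested) the caller should use
    ``store.all_patients()`` instead."""
    return store.patients_with_keys(keys)
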