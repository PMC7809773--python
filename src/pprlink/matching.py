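"""Field similarities, weighted aggregation and match classification.

The record similarity is the weight-normalized sum of per-field
similarities, sim(x,y) = sum_i w_i * sim(x_i, y_i) / sum_i w_i, with
field weights derived from mean value frequency f and error rate e as
w = log2((1-e)/f).  String fields use the Dice coefficient over q-gram
multisets; encoded fields use Dice over bit vectors via AND-cardinality;
date components compare by equality.  Classification is three-way
against thresholds t1 >= t2 (match / possible match / non-match) with
best-match selection among candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .encoding import BitVector, ConfigError, extract_qgrams

__all__ = [
    "FieldConfig",
    "MatchDecision",
    "MatchingConfig",
    "dice_string",
    "dice_bits",
    "numeric_equality",
    "field_weight",
    "compound_similarity",
    "compound_similarity_matrix",
    "aggregate_similarity",
    "classify",
    "best_match",
    "default_plain_fields",
    "default_bloom_fields",
    "TABLE_FREQUENCIES",
]

MATCH = "match"
POSSIBLE = "possible"
NON_MATCH = "non-match"

# Default (frequency f, error rate e) per attribute, originating from the
# evaluation of a German cancer registry.
TABLE_FREQUENCIES: Dict[str, Tuple[float, float]] = {
    "first_name": (0.000235, 0.01),
    "last_name": (0.0000271, 0.008),
    "birth_day": (0.0333, 0.005),
    "birth_month": (0.0833, 0.002),
    "birth_year": (0.0286, 0.004),
    "dob": (0.00007, 0.005),
}


def field_weight(f: float, e: float) -> float:
    """Field weight w = log2((1-e)/f): the discriminatory power of a field.

    Rare values (small f) and low error rates give high weights.
    """
    if not 0 < f < 1:
        raise ConfigError(f"frequency must be in (0,1), got {f}")
    if not 0 <= e < 1:
        raise ConfigError(f"error rate must be in [0,1), got {e}")
    return math.log2((1.0 - e) / f)


@dataclass(frozen=True)
class FieldConfig:
    """Similarity settings of one matching field.

    ``kind`` is one of ``string-dice`` (q-gram Dice on plaintext),
    ``bloom-dice`` (Dice on bit vectors) or ``numeric-equality``.
    The weight is derived from (f, e) unless given explicitly.
    """

    field_id: str
    kind: str
    q: int = 2
    f: float = 0.5
    e: float = 0.0
    weight: Optional[float] = None
    compound: bool = False

    @property
    def w(self) -> float:
        if self.weight is not None:
            return self.weight
        return field_weight(self.f, self.e)


def default_plain_fields() -> List[FieldConfig]:
    """Plaintext matching: Dice on names, equality on date components."""
    f, e = TABLE_FREQUENCIES["first_name"]
    cfgs = [FieldConfig("first_name", "string-dice", f=f, e=e, compound=True)]
    f, e = TABLE_FREQUENCIES["last_name"]
    cfgs.append(FieldConfig("last_name", "string-dice", f=f, e=e, compound=True))
    for fld in ("birth_day", "birth_month", "birth_year"):
        f, e = TABLE_FREQUENCIES[fld]
        cfgs.append(FieldConfig(fld, "numeric-equality", f=f, e=e))
    return cfgs


def default_bloom_fields() -> List[FieldConfig]:
    """Encoded matching: Dice on name filters and the joint DOB filter."""
    cfgs = []
    for fld in ("first_name", "last_name"):
        f, e = TABLE_FREQUENCIES[fld]
        cfgs.append(FieldConfig(fld, "bloom-dice", f=f, e=e, compound=True))
    f, e = TABLE_FREQUENCIES["dob"]
    cfgs.append(FieldConfig("dob", "bloom-dice", f=f, e=e))
    return cfgs


@dataclass(frozen=True)
class MatchingConfig:
    """Thresholds and field set for one matching mode.

    With t1 == t2 (the default) the possible-match class is empty and
    every decision is definite.
    """

    fields: tuple
    t1: float = 0.9
    t2: float = 0.9
    # Error tolerance for missing values: by default a field absent on
    # either side is dropped from the weight sum entirely, so records are
    # compared on their shared fields.  Set True for the conservative
    # variant (missing field scores 0 but its weight stays in the
    # denominator, capping the similarity of incomplete records).
    count_missing_weight: bool = False

    def __post_init__(self):
        if self.t1 < self.t2:
            raise ConfigError(f"t1={self.t1} must be >= t2={self.t2}")


# -- similarities ----------------------------------------------------------

def dice_string(a: str, b: str, q: int = 2) -> float:
    """Dice coefficient of the q-gram multisets of two strings
    (2*|intersection| / (|a|+|b|), multiset intersection = sum of min
    counts).  0 if either gram set is empty."""
    ga = extract_qgrams(a, q, padded=False)
    gb = extract_qgrams(b, q, padded=False)
    if not ga.grams or not gb.grams:
        return 0.0
    ca, cb = ga.counts(), gb.counts()
    inter = sum(min(n, cb[g]) for g, n in ca.items())
    return 2.0 * inter / (len(ga) + len(gb))


def dice_bits(a: BitVector, b: BitVector) -> float:
    """Dice similarity of two equal-length bit vectors,
    2*card(a AND b)/(card(a)+card(b)); 0 when both are empty."""
    if a.m != b.m:
        raise ValueError(f"incompatible encodings: m={a.m} vs m={b.m}")
    denom = a.cardinality() + b.cardinality()
    if denom == 0:
        return 0.0
    return 2.0 * (a & b).cardinality() / denom


def numeric_equality(a, b) -> float:
    """1 iff both values are present and equal after integer coercion."""
    if a is None or b is None:
        return 0.0
    try:
        return 1.0 if int(a) == int(b) else 0.0
    except (TypeError, ValueError):
        return 1.0 if a == b else 0.0


def compound_similarity_matrix(sims) -> float:
    """Compound aggregation given the pairwise component similarity matrix
    (rows = side A components, cols = side B components).

    Mean over the shorter side's components of its best similarity
    against the longer side, each longer-side component usable at most
    once, assigned greedily in descending similarity order.  A record
    with last name "PINKETT SMITH" therefore scores 1 against "PINKETT".
    """
    na = len(sims)
    nb = len(sims[0]) if na else 0
    if na == 0 or nb == 0:
        return 0.0
    pairs = sorted(
        ((sims[i][j], i, j) for i in range(na) for j in range(nb)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    n_short = min(na, nb)
    used_a: set = set()
    used_b: set = set()
    total = 0.0
    taken = 0
    for s, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += s
        taken += 1
        if taken == n_short:
            break
    return total / n_short


def compound_similarity(
    components_a: Sequence,
    components_b: Sequence,
    base_sim: Callable,
) -> float:
    """Per-component similarity of two compound field values."""
    if not components_a or not components_b:
        return 0.0
    sims = [[base_sim(a, b) for b in components_b] for a in components_a]
    return compound_similarity_matrix(sims)


# -- aggregation and classification ---------------------------------------

def aggregate_similarity(field_sims: Dict[str, float], weights: Dict[str, float]) -> float:
    """Weight-normalized sum of field similarities over the configured fields."""
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ConfigError("all field weights are zero")
    return sum(weights[f] * field_sims.get(f, 0.0) for f in weights) / total_w


def classify(sim: float, t1: float, t2: float) -> str:
    """Three-way decision: match iff sim >= t1; possible iff t2 <= sim < t1."""
    if t1 < t2:
        raise ConfigError(f"t1={t1} must be >= t2={t2}")
    if sim >= t1:
        return MATCH
    if sim >= t2:
        return POSSIBLE
    return NON_MATCH


@dataclass
class MatchDecision:
    """Outcome of matching one query against a candidate set."""

    query_id: Optional[str]
    candidate_id: Optional[str]
    similarity: float
    decision: str
    field_sims: Dict[str, float] = field(default_factory=dict)


def best_match(
    candidates: Sequence[Tuple[object, float]],
    t1: float,
    t2: float,
    query_id: Optional[str] = None,
) -> MatchDecision:
    """Classify only the highest-scoring candidate (best-match strategy).

    Ties go to the earliest-listed (earliest-inserted) candidate; an
    empty candidate list is a non-match.
    """
    if not candidates:
        return MatchDecision(query_id, None, 0.0, NON_MATCH)
    best_id, best_sim = candidates[0]
    for cid, s in candidates[1:]:
        if s > best_sim:
            best_id, best_sim = cid, s
    return MatchDecision(query_id, best_id, best_sim, classify(best_sim, t1, t2))
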