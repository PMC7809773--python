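"""Synthetic German-style person datasets with ground-truth duplicates.

Emulates the evaluation protocol of an incremental master patient
index: an initial, duplicate-free subset A (default 70% of the records)
is loaded first, then subset B is inserted one by one; half of B
duplicates an A record, with a controlled share of the duplicates
carrying corrupted field values (typos, OCR confusions, phonetic
variants, missing values, compound-name changes).  Name pools are
bundled frequency-weighted lists (first names) and stem x suffix
combinations (surnames) with Zipf-like rank weights, so value-frequency
statistics are plausible without external census files.  Generation is
fully deterministic given the seed, and corruption counts are
stratified exactly (by counts, not coin flips).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import json

import numpy as np
import pandas as pd

from .preprocessing import RawRecord

__all__ = [
    "DatasetSpec",
    "GroundTruth",
    "SyntheticDataset",
    "G_SMALL",
    "D_PROFILE",
    "generate_dataset",
    "corrupt_record",
]

# -- bundled name pools ----------------------------------------------------

FIRST_NAMES = [
    # classic and modern German given names plus names common in Germany's
    # migrant communities, in rough popularity order
    "HANS", "PETER", "MICHAEL", "THOMAS", "ANDREAS", "WOLFGANG", "KLAUS", "JUERGEN",
    "GUENTER", "STEFAN", "CHRISTIAN", "UWE", "WERNER", "HORST", "FRANK", "DIETER",
    "MANFRED", "ALEXANDER", "BERND", "DANIEL", "MARTIN", "KARL", "HEINZ", "GERHARD",
    "MATTHIAS", "HELMUT", "WALTER", "JOACHIM", "MARKUS", "ROLF", "HERBERT", "MARIO",
    "SEBASTIAN", "JAN", "RAINER", "JOSEF", "TOBIAS", "NORBERT", "HARALD", "CHRISTOPH",
    "FLORIAN", "PHILIPP", "MAXIMILIAN", "LUKAS", "FELIX", "JONAS", "DAVID", "SIMON",
    "JULIAN", "FABIAN", "BENJAMIN", "NIKLAS", "MORITZ", "TIM", "LEON", "PAUL",
    "JAKOB", "EMIL", "ANTON", "OSKAR", "ERICH", "KURT", "OTTO", "WILHELM",
    "FRIEDRICH", "HERMANN", "ALBERT", "RICHARD", "ROBERT", "HEINRICH", "ERNST", "ALFRED",
    "ARTHUR", "BRUNO", "EDUARD", "FERDINAND", "GUSTAV", "HUGO", "KONRAD", "LUDWIG",
    "LOTHAR", "DIRK", "VOLKER", "RALF", "HOLGER", "DETLEF", "INGO", "TORSTEN",
    "CARSTEN", "JOERG", "OLAF", "SVEN", "LARS", "MARC", "NILS", "TILL",
    "MARIA", "URSULA", "MONIKA", "PETRA", "ELISABETH", "SABINE", "RENATE", "HELGA",
    "KARIN", "BRIGITTE", "INGRID", "ERIKA", "CLAUDIA", "ANDREA", "GISELA", "SUSANNE",
    "GABRIELE", "CHRISTA", "ANGELIKA", "HILDEGARD", "BARBARA", "ANNA", "MARGARETE", "HANNELORE",
    "ELKE", "MARTINA", "GERTRUD", "BIRGIT", "ANJA", "HEIKE", "KATHRIN", "ANKE",
    "STEFANIE", "SANDRA", "NICOLE", "JULIA", "KATRIN", "SILKE", "MELANIE", "TANJA",
    "NADINE", "KATJA", "SONJA", "SIMONE", "BETTINA", "CORNELIA", "MANUELA", "DANIELA",
    "CHRISTINE", "MARION", "UTE", "IRMGARD", "INGE", "ILSE", "EDITH", "LIESELOTTE",
    "HERTA", "ELFRIEDE", "SOPHIE", "MARIE", "EMMA", "MIA", "HANNAH", "LENA",
    "LEONIE", "LAURA", "LEA", "SARAH", "SARA", "LISA", "JOHANNA", "CHARLOTTE",
    "KLARA", "FRIEDA", "MATHILDE", "GRETA", "PAULA", "MARTHA", "HEDWIG", "ANNELIESE",
    "ROSEMARIE", "WALTRAUD", "SIGRID", "JUTTA", "DAGMAR", "CAROLA", "BEATE", "REGINA",
    "ASTRID", "MIRIAM", "FRANZISKA", "VERENA", "CAROLIN", "THERESA", "VANESSA", "JESSICA",
    "ANTJE", "DOROTHEA", "MAGDALENA", "VERONIKA", "CHRISTIANE", "ALEXANDRA", "KERSTIN", "YVONNE",
    "NINA", "JANA", "MAREN", "SILVIA", "ANITA", "ROSWITHA", "HELENE", "AGNES",
    "THEODOR", "LEOPOLD", "BENEDIKT", "VINZENZ", "AUGUST", "ADOLF", "ALOIS", "BALDUR",
    "EGON", "ERWIN", "GEORG", "GOTTFRIED", "GREGOR", "HARTMUT", "HELLMUT", "HENDRIK",
    "HUBERT", "IGNAZ", "KASPAR", "KILIAN", "KORBINIAN", "LENNART", "LEVIN", "LINUS",
    "LORENZ", "MAGNUS", "MALTE", "MARLON", "MEHMET", "MUSTAFA", "ALI", "HASAN",
    "HUESEYIN", "IBRAHIM", "ISMAIL", "MURAT", "AHMET", "OSMAN", "RAMAZAN", "SUELEYMAN",
    "FATMA", "AYSE", "EMINE", "HATICE", "ZEYNEP", "ELIF", "MERYEM", "OEZLEM",
    "GIOVANNI", "GIUSEPPE", "ANTONIO", "FRANCESCO", "SALVATORE", "MARCO", "LUIGI", "ANGELO",
    "MARIA TERESA", "GIULIA", "FRANCESCA", "ANTONELLA", "PIOTR", "KRZYSZTOF", "ANDRZEJ", "TOMASZ",
    "MAREK", "MICHAL", "PAWEL", "JACEK", "AGNIESZKA", "MALGORZATA", "KATARZYNA", "EWA",
    "MAGDA", "JOANNA", "BARBORA", "IVANA", "SERGEJ", "DMITRI", "ANDREJ", "WLADIMIR",
    "ALEKSANDR", "VIKTOR", "IGOR", "OLEG", "NATALIA", "OLGA", "TATJANA", "SVETLANA",
    "IRINA", "EKATERINA", "ANASTASIA", "JELENA", "MILAN", "DRAGAN", "ZORAN", "GORAN",
    "JOVANA", "MILICA", "ANTE", "IVAN", "JOSIP", "MARIJA", "DUBRAVKA", "VESNA",
    "CARLOS", "JOSE", "JUAN", "MIGUEL", "ANTONIA", "CARMEN", "ISABEL", "PILAR",
    "JOAO", "PEDRO", "TIAGO", "INES", "NGUYEN", "MINH", "LINH", "THI",
    "YUSUF", "EMRE", "BURAK", "KEREM", "DERYA", "SEVIM", "GUEL", "NURAY",
    "AMIR", "OMAR", "KARIM", "SAMIR", "LEILA", "AMIRA", "YASMIN", "NADIA",
    "JEAN", "PIERRE", "MICHEL", "CLAUDE", "NATHALIE", "SYLVIE", "CELINE", "MARGAUX",
    "JOHN", "JAMES", "WILLIAM", "GEORGE", "MARY", "PATRICIA", "LINDA", "SUSAN",
    "LASSE", "MIKKEL", "JESPER", "HENRIK", "FREJA", "SIGNE", "METTE", "KIRSTEN",
    "EERO", "JUHA", "MIKA", "TIMO", "AINO", "HELMI", "SANNA", "TUULA",
    "BASTIAN", "CONSTANTIN", "CORNELIUS", "DAMIAN", "EDGAR", "ELIAS", "EMANUEL", "ENRICO",
    "FALK", "GERD", "GERNOT", "GUIDO", "GUNNAR", "HEIKO", "HELLMUTH",
    "HENNING", "HERIBERT", "HILMAR", "IMMO", "JENS", "KAI", "KNUT", "LUTZ",
    "MEINHARD", "NICO", "OSWALD", "RAIMUND", "REINHARD", "REINHOLD", "RUEDIGER", "SIEGFRIED",
    "SOEREN", "THILO", "THORSTEN", "TILMAN", "UDO", "ULRICH", "VEIT", "WENDELIN",
    "WILFRIED", "WILLI", "WOLFRAM", "XAVER", "ADELE", "ALMA", "AMALIA", "AURELIA",
    "BERTA", "CAECILIA", "CLARA", "CONSTANZE", "CORDULA", "DORIS", "EDELTRAUD", "ELEONORE",
    "ELLA", "ELSA", "ERNA", "FELICITAS", "FLORA", "FRIEDERIKE", "GERDA", "GRETEL",
    "GUDRUN", "HENRIETTE", "IDA", "IRENE", "IRMA", "ISOLDE", "KAETHE", "KORNELIA",
    "LIESEL", "LINA", "LORE", "LUISE", "MARGIT", "MARLENE", "MECHTHILD", "MINNA",
    "NELE", "OTTILIE", "REBEKKA", "RENATA", "RICARDA", "ROSA", "RUTH", "SELMA",
    "THEA", "TRAUDEL", "URSEL", "VIKTORIA", "WILHELMINE", "WIEBKE", "SWANTJE", "FEMKE",
]

_REAL_SURNAMES = [
    "MUELLER", "SCHMIDT", "SCHNEIDER", "FISCHER", "WEBER", "MEYER", "WAGNER", "BECKER",
    "SCHULZ", "HOFFMANN", "SCHAEFER", "KOCH", "BAUER", "RICHTER", "KLEIN", "WOLF",
    "SCHROEDER", "NEUMANN", "SCHWARZ", "ZIMMERMANN", "BRAUN", "KRUEGER", "HOFMANN", "HARTMANN",
    "LANGE", "SCHMITT", "WERNER", "KRAUS", "LEHMANN", "SCHMITZ", "KOEHLER", "HERRMANN",
    "KOENIG", "WALTER", "MAIER", "HUBER", "KAISER", "FUCHS", "PETERS", "LANG",
    "SCHOLZ", "MOELLER", "WEISS", "JUNG", "HAHN", "SCHUBERT", "VOGEL", "FRIEDRICH",
    "KELLER", "GUENTHER", "FRANKE", "BERGER", "WINKLER", "ROTH", "BECK", "LORENZ",
    "BAUMANN", "FRANZ", "ALBRECHT", "SCHUSTER", "SIMON", "LUDWIG", "BOEHM", "WINTER",
    "KRAEMER", "SCHUMACHER", "VOGT", "STEIN", "JAEGER", "OTTO", "SOMMER", "GROSS",
    "SEIDEL", "HEINRICH", "BRANDT", "HAAS", "SCHREIBER", "GRAF", "SCHULTE", "DIETRICH",
    "ZIEGLER", "KUHN", "KUEHN", "POHL", "ENGEL", "HORN", "BUSCH", "BERGMANN",
    "THOMAS", "VOIGT", "SAUER", "ARNOLD", "WOLFF", "PFEIFFER", "SCHMID", "BARTH", "KRAFT", "KUHLMANN", "NOWAK", "SCHENK", "ACKERMANN", "UNGER", "HILDEBRANDT",
    "GEIGER", "HORST", "KESSLER", "THIEL", "ERNST", "PAUL", "HAUCK", "MAY",
    "KRAMER", "HENSEL", "WENDT", "KOLB", "FRITZ", "EBERT", "REUTER", "SEIFERT",
    "BRINKMANN", "GOERTZ", "STAHL", "DITTRICH", "HEINZE", "KUNZ", "BRUNNER", "WITT",
    "HEIN", "ALBERS", "MARX", "FIEDLER", "DOERING", "BRUNS", "STANGE", "GERLACH",
    "BRIESE", "WELSCH", "HAGEN", "HOLZER", "MENZEL", "KRUSE", "JANSEN",
    "HERZOG", "MOHR", "BUCHHOLZ", "BARTSCH", "RUDOLPH", "NAGEL", "WESTPHAL", "HENNIG",
    "LINDNER", "REINHARDT", "EICHHORN", "STOLL", "METZGER", "WAHL", "GEBHARDT", "RIEDEL",
    "WITTE", "STEFFEN", "KONRAD", "KILIAN", "ADAM", "WIRTH", "ULRICH", "SCHIELE",
    "NEUBERT", "GROTH", "HOLZAPFEL", "LAUER", "SPRINGER", "HESSE", "KNAPP", "JACOBI",
    "BODE", "HAUPT", "WEGENER", "RAUCH", "ROSE", "BINDER", "REICH", "HOFER",
    "SCHILLING", "FINK", "WULF", "BUSSE", "DREWS", "HANSEN", "CLAUSEN",
    "PETERSEN", "JENSEN", "NIELSEN", "ANDERSEN", "CHRISTIANSEN", "JOHANNSEN", "CARSTENSEN", "LUND",
    "YILMAZ", "KAYA", "DEMIR", "CELIK", "SAHIN", "YILDIZ", "YILDIRIM", "OEZTUERK",
    "AYDIN", "OEZDEMIR", "ARSLAN", "DOGAN", "KILIC", "ASLAN", "CETIN", "KARA",
    "KOC", "KURT", "OEZKAN", "SIMSEK", "POLAT", "KORKMAZ", "CAKIR", "ERDOGAN",
    "ROSSI", "RUSSO", "FERRARI", "ESPOSITO", "BIANCHI", "ROMANO", "COLOMBO", "RICCI",
    "MARINO", "GRECO", "BRUNO", "GALLO", "CONTI", "DELUCA", "COSTA", "GIORDANO",
    "KOWALSKI", "NOWAKOWSKI", "WISNIEWSKI", "WOJCIK", "KOWALCZYK", "KAMINSKI", "LEWANDOWSKI", "ZIELINSKI",
    "SZYMANSKI", "WOZNIAK", "DABROWSKI", "KOZLOWSKI", "JANKOWSKI", "MAZUR", "KWIATKOWSKI", "KRAWCZYK",
    "IVANOV", "PETROV", "SMIRNOV", "KUZNETSOV", "POPOV", "VOLKOV", "SOKOLOV", "MOROZOV",
    "HORVAT", "KOVACEVIC", "JOVANOVIC", "PETROVIC", "NIKOLIC", "MARKOVIC", "ILIC", "PAVLOVIC",
    "GARCIA", "FERNANDEZ", "GONZALEZ", "RODRIGUEZ", "LOPEZ", "MARTINEZ", "SANCHEZ", "PEREZ",
    "SILVA", "SANTOS", "FERREIRA", "PEREIRA", "OLIVEIRA", "ALMEIDA", "NGUYEN", "TRAN",
]

# toponymic surnames: place stem + habitational suffix (one formation per
# place, alternating, so no near-duplicate surname families arise)
_PLACE_STEMS = [
    "BERLIN", "HAMBURG", "BREMEN", "FRANKFURT", "STUTTGART", "NUERNBERG", "DRESDEN", "LEIPZIG",
    "HANNOVER", "DORTMUND", "ESSEN", "DUISBURG", "BOCHUM", "WUPPERTAL", "BIELEFELD", "BONN",
    "MUENSTER", "KARLSRUHE", "MANNHEIM", "AUGSBURG", "WIESBADEN", "GELSEN", "BRAUNSCHWEIG", "KIEL",
    "CHEMNITZ", "KREFELD", "HALLE", "MAGDEBURG", "OBERHAUSEN", "LUEBECK", "FREIBURG", "ERFURT",
    "ROSTOCK", "KASSEL", "HAMELN", "POTSDAM", "SAARBRUECK", "HEIDELBERG", "DARMSTADT", "REGENSBURG",
    "WUERZBURG", "INGOLSTADT", "ULM", "HEILBRONN", "PFORZHEIM", "GOETTINGEN", "BOTTROP", "TRIER",
    "RECKLING", "REUTLING", "BREMERHAVEN", "KOBLENZ", "BERGISCH", "JENA", "REMSCHEID", "ERLANGEN",
    "MOERS", "SIEGEN", "HILDESHEIM", "SALZGITT", "COTTBUS", "GERA", "WILHELMSHAVEN", "DELMENHORST",
    "BAYREUTH", "BAMBERG", "CELLE", "LANDSHUT", "ASCHAFFEN", "DINSLAKEN", "LIPPSTADT", "HERFORD",
    "KEMPTEN", "PLAUEN", "NEUBRANDEN", "GRIMMA", "FULDA", "WETZLAR", "GOSLAR", "EMDEN",
    "TUEBINGEN", "STRALSUND", "GREIFSWALD", "WISMAR", "EISENACH", "PIRNA", "COBURG", "ANSBACH",
    "SPEYER", "WORMS", "PASSAU", "FREISING", "STADE", "UELZEN", "LUENE", "GIFHORN",
    "RENDSBURG", "HUSUM", "FLENSBURG", "ITZEHOE", "MEISSEN", "TORGAU", "ZWICKAU", "GLAUCHAU",
    "ALTENBURG", "WEIMAR", "GOTHA", "SUHL", "MEININGEN", "RUDOLSTADT", "ARNSTADT", "APOLDA",
    "SONDERSHAUSEN", "NORDHAUSEN", "MUEHLHAUSEN", "EISLEBEN", "BERNBURG", "KOETHEN", "ZERBST", "STENDAL",
]
_PLACE_SUFFIXES = ("ER", "MANN")


def _surnames() -> List[str]:
    names = list(_REAL_SURNAMES)
    for i, place in enumerate(_PLACE_STEMS):
        names.append(place + _PLACE_SUFFIXES[i % 2])
    seen = set()
    out = []
    for n in names:
        if n not in seen:
            seen.add(n)
            out.append(n)
    return out


LAST_NAMES = _surnames()


def _zipf_weights(n: int, s: float = 0.5) -> np.ndarray:
    """Zipf-like rank weights, flatter than classic s=1: an all-ages
    registry mixes many birth cohorts, which flattens name frequencies."""
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()


# -- corruption tables -----------------------------------------------------

OCR_CONFUSIONS = [
    ("I", "L"), ("L", "I"), ("O", "Q"), ("Q", "O"), ("E", "F"), ("F", "E"),
    ("M", "N"), ("N", "M"), ("U", "V"), ("V", "U"), ("G", "C"), ("C", "G"),
    ("B", "R"), ("K", "R"), ("W", "VV"), ("M", "RN"),
]

PHONETIC_RULES = [
    ("PH", "F"), ("F", "PH"), ("TH", "T"), ("DT", "TT"), ("C", "K"), ("K", "C"),
    ("Y", "I"), ("I", "Y"), ("EI", "AI"), ("AI", "EY"), ("SCH", "SH"),
    ("MANN", "MAN"), ("MAN", "MANN"), ("ER", "A"), ("Z", "TZ"), ("TZ", "Z"),
]

ERROR_TYPES = ("typo", "ocr", "phonetic", "missing", "compound", "swap")

# mix over error types (names); date fields only support typo/missing
DEFAULT_ERROR_MIX = {
    "typo": 0.35,
    "ocr": 0.15,
    "phonetic": 0.20,
    "missing": 0.10,
    "compound": 0.15,
    "swap": 0.05,
}


@dataclass(frozen=True)
class DatasetSpec:
    """Stated world of one generated dataset.

    ``errors_per_duplicate`` maps #erroneous fields -> fraction of the
    duplicates; fields are drawn without replacement from (first name,
    last name, date of birth).
    """

    total: int = 10_000
    split_a: float = 0.7
    duplicate_fraction: float = 0.5  # of B records that duplicate an A record
    errors_per_duplicate: Dict[int, float] = field(
        default_factory=lambda: {0: 0.7, 1: 0.2, 2: 0.1}
    )
    error_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ERROR_MIX))
    compound_first_rate: float = 0.10
    compound_last_rate: float = 0.08
    year_range: Tuple[int, int] = (1940, 2005)
    seed: int = 0

    def counts(self) -> Tuple[int, int, int]:
        n_a = int(round(self.total * self.split_a))
        n_b = self.total - n_a
        n_dup = int(round(n_b * self.duplicate_fraction))
        if n_dup > n_b or n_dup > n_a:
            raise ValueError("infeasible spec: more duplicates than records available")
        return n_a, n_b, n_dup


# the small G-family dataset (10k records, 70/30, 50% of B duplicated,
# 30% of duplicates with 1-2 erroneous fields)
G_SMALL = DatasetSpec()

# the "dirty" profile: 40% of duplicates erroneous, 5% with all three fields
D_PROFILE = DatasetSpec(errors_per_duplicate={0: 0.6, 1: 0.2, 2: 0.15, 3: 0.05})


@dataclass
class GroundTruth:
    """True-match pairs (duplicate id -> original id) and the per-duplicate
    corruption log."""

    pairs: Dict[str, str]
    corruption_log: List[dict]


@dataclass
class SyntheticDataset:
    frame_a: pd.DataFrame
    frame_b: pd.DataFrame
    truth: GroundTruth
    spec: DatasetSpec

    def raw_records_a(self) -> List[RawRecord]:
        return _to_records(self.frame_a)

    def raw_records_b(self) -> List[RawRecord]:
        return _to_records(self.frame_b)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame_a.to_csv(outdir / "A.csv", index=False)
        self.frame_b.to_csv(outdir / "B.csv", index=False)
        pd.DataFrame(
            [(b, a) for b, a in sorted(self.truth.pairs.items())],
            columns=["duplicate_id", "original_id"],
        ).to_csv(outdir / "truth.csv", index=False)
        with open(outdir / "log.jsonl", "w", encoding="utf-8") as fh:
            for entry in self.truth.corruption_log:
                fh.write(json.dumps(entry) + "\n")


def _to_records(df: pd.DataFrame) -> List[RawRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            RawRecord(
                first_name=row.first_name or None,
                last_name=row.last_name or None,
                birth_day=int(row.birth_day) if row.birth_day != "" else None,
                birth_month=int(row.birth_month) if row.birth_month != "" else None,
                birth_year=int(row.birth_year) if row.birth_year != "" else None,
                record_id=row.record_id,
            )
        )
    return recs


# -- person sampling -------------------------------------------------------

def _sample_person(rng: np.random.Generator, spec: DatasetSpec,
                   fw: np.ndarray, lw: np.ndarray) -> dict:
    first = FIRST_NAMES[rng.choice(len(FIRST_NAMES), p=fw)]
    if rng.random() < spec.compound_first_rate:
        second = FIRST_NAMES[rng.choice(len(FIRST_NAMES), p=fw)]
        if second != first:
            first = f"{first} {second}"
    last = LAST_NAMES[rng.choice(len(LAST_NAMES), p=lw)]
    if rng.random() < spec.compound_last_rate:
        second = LAST_NAMES[rng.choice(len(LAST_NAMES), p=lw)]
        if second != last:
            last = f"{last}-{second}"
    year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1] + 1))
    return {
        "first_name": first,
        "last_name": last,
        "birth_day": day,
        "birth_month": month,
        "birth_year": year,
    }


# -- corruption ------------------------------------------------------------

def _typo(value: str, rng: np.random.Generator) -> str:
    """One keyboard-style edit: insert, delete, substitute or transpose."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if len(value) < 2:
        return value + letters[rng.integers(26)]
    op = rng.choice(["insert", "delete", "substitute", "transpose"])
    i = int(rng.integers(len(value)))
    if op == "insert":
        return value[:i] + letters[rng.integers(26)] + value[i:]
    if op == "delete":
        return value[:i] + value[i + 1 :]
    if op == "substitute":
        repl = letters[rng.integers(26)]
        while repl == value[i]:
            repl = letters[rng.integers(26)]
        return value[:i] + repl + value[i + 1 :]
    i = min(i, len(value) - 2)
    return value[:i] + value[i + 1] + value[i] + value[i + 2 :]


def _ocr(value: str, rng: np.random.Generator) -> str:
    applicable = [(a, b) for a, b in OCR_CONFUSIONS if a in value]
    if not applicable:
        return _typo(value, rng)
    a, b = applicable[int(rng.integers(len(applicable)))]
    return value.replace(a, b, 1)


def _phonetic(value: str, rng: np.random.Generator) -> str:
    applicable = [(a, b) for a, b in PHONETIC_RULES if a in value]
    if not applicable:
        return _typo(value, rng)
    a, b = applicable[int(rng.integers(len(applicable)))]
    return value.replace(a, b, 1)


def _corrupt_name(value: str, etype: str, rng: np.random.Generator,
                  fw: np.ndarray) -> Optional[str]:
    comps = value.replace("-", " ").split()
    if etype == "missing":
        return None
    if etype == "compound":
        if len(comps) >= 2 and rng.random() < 0.5:
            drop = int(rng.integers(len(comps)))
            comps = [c for i, c in enumerate(comps) if i != drop]
        else:
            comps = comps + [FIRST_NAMES[rng.choice(len(FIRST_NAMES), p=fw)]]
        return " ".join(comps)
    if etype == "swap":
        if len(comps) >= 2:
            comps = comps[::-1]
            return " ".join(comps)
        etype = "typo"
    i = int(rng.integers(len(comps)))
    fn = {"typo": _typo, "ocr": _ocr, "phonetic": _phonetic}[etype]
    comps[i] = fn(comps[i], rng)
    return " ".join(comps)


def _corrupt_date(row: dict, etype: str, rng: np.random.Generator) -> List[str]:
    """Corrupt one date component; returns the names of changed columns."""
    comp = ("birth_day", "birth_month", "birth_year")[int(rng.integers(3))]
    if etype in ("missing",):
        row[comp] = ""
        return [comp]
    value = int(row[comp])
    if comp == "birth_day":
        new = max(1, min(28, value + int(rng.choice([-1, 1, 10, -10]))))
    elif comp == "birth_month":
        new = value % 12 + 1
    else:
        new = value + int(rng.choice([-1, 1, -10, 10]))
    row[comp] = new
    # keep the corrupted date a real calendar date so the duplicate is
    # insertable (plausible-but-wrong, not invalid)
    if row["birth_day"] != "" and row["birth_month"] != "":
        month_days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
        row["birth_day"] = min(int(row["birth_day"]), month_days[int(row["birth_month"]) - 1])
    return [comp]


def corrupt_record(row: dict, n_fields: int, mix: Dict[str, float],
                   rng: np.random.Generator,
                   fw: Optional[np.ndarray] = None) -> Tuple[dict, List[dict]]:
    """Apply exactly ``n_fields`` field-level corruptions to a record dict.

    Fields (first name, last name, date of birth) are drawn without
    replacement; the error type per field is sampled from ``mix``
    (date fields fall back to typo/missing).  Returns the corrupted
    copy and a log of (field, error type) entries.
    """
    if fw is None:
        fw = _zipf_weights(len(FIRST_NAMES))
    out = dict(row)
    log: List[dict] = []
    fields = ["first_name", "last_name", "dob"]
    chosen = list(rng.choice(fields, size=min(n_fields, 3), replace=False))
    types = list(mix)
    probs = np.asarray([mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    for fld in chosen:
        etype = str(types[int(rng.choice(len(types), p=probs))])
        if fld == "dob":
            if etype not in ("typo", "missing"):
                etype = "typo" if rng.random() < 0.7 else "missing"
            changed = _corrupt_date(out, etype, rng)
            log.append({"field": "dob", "type": etype, "columns": changed})
        else:
            new = _corrupt_name(out[fld], etype, rng, fw)
            out[fld] = "" if new is None else new
            log.append({"field": fld, "type": etype})
    return out, log


# -- dataset generation ----------------------------------------------------

def generate_dataset(spec: DatasetSpec = G_SMALL) -> SyntheticDataset:
    """Generate subsets A and B plus ground truth per the spec.

    A is duplicate-free; the duplicate records of B each copy a distinct
    A record and receive their stratified corruption; B is shuffled so
    duplicates and fresh persons interleave.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    n_a, n_b, n_dup = spec.counts()
    fw = _zipf_weights(len(FIRST_NAMES))
    lw = _zipf_weights(len(LAST_NAMES))

    rows_a = []
    for i in range(n_a):
        row = _sample_person(rng, spec, fw, lw)
        row["record_id"] = f"A{i:07d}"
        rows_a.append(row)

    # stratified error counts: exact integers, largest-remainder rounding
    strata = sorted(spec.errors_per_duplicate.items())
    raw = [n_dup * frac for _, frac in strata]
    counts = [int(np.floor(x)) for x in raw]
    rem = n_dup - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for j in range(rem):
        counts[order[j % len(counts)]] += 1
    n_errors_list: List[int] = []
    for (n_err, _), c in zip(strata, counts):
        n_errors_list.extend([n_err] * c)

    dup_sources = rng.choice(n_a, size=n_dup, replace=False)
    rows_b = []
    log: List[dict] = []
    pairs: Dict[str, str] = {}
    for j in range(n_dup):
        src = rows_a[dup_sources[j]]
        dup, entries = corrupt_record(src, n_errors_list[j], spec.error_mix, rng, fw)
        dup = dict(dup)
        rows_b.append(dup)
        log.append({"source": src["record_id"], "fields": entries})
    for j in range(n_b - n_dup):
        rows_b.append(_sample_person(rng, spec, fw, lw))

    perm = rng.permutation(n_b)
    shuffled = []
    for pos, j in enumerate(perm):
        row = dict(rows_b[j])
        rid = f"B{pos:07d}"
        row["record_id"] = rid
        shuffled.append(row)
        if j < n_dup:
            pairs[rid] = log[j]["source"]
            log[j]["duplicate"] = rid

    cols = ["record_id", "first_name", "last_name", "birth_day", "birth_month", "birth_year"]
    frame_a = pd.DataFrame(rows_a)[cols].astype(str)
    frame_b = pd.DataFrame(shuffled)[cols].astype(str)
    return SyntheticDataset(frame_a, frame_b, GroundTruth(pairs, log), spec)
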