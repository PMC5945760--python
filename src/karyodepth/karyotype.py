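"""Karyotype grammar, data model and classification.

A karyotype records, for each of the 12 chromosomes, the deviation of its
copy number from the tetraploid baseline of 4, separately for the whole
chromosome and for each arm (S = short, L = long).  Karyotypes are written
as semicolon-separated terms such as ``"+ 1 Chr. 11"`` (one extra whole
copy of chromosome 11) or ``"- 1L Chr. 11"`` (loss of one long-arm copy).

Classification taxonomy:

* *euploid* — no deviation anywhere;
* *simple gain / simple loss* — exactly one whole chromosome changed by
  ±1 copy, nothing else (multi-copy changes of a single chromosome count
  as compound);
* *compound* — everything else, including arm-level (segmental) changes;
* *hidden* — a compound karyotype whose whole-chromosome gains and losses
  cancel exactly (still 48 chromosomes) with no arm-level terms;
* *segmental* — any karyotype carrying a nonzero arm-level deviation.

The chromosome number (baseline 48) is defined only for karyotypes free of
arm-level terms; how arm fragments should count toward a chromosome total
is not well defined, so such karyotypes report ``None``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "Karyotype",
    "KaryotypeClass",
    "KaryotypeRecord",
    "KaryotypeError",
    "KaryotypeParseError",
    "ChromosomeRangeError",
    "UnsupportedNotationError",
    "parse_karyotype",
    "format_karyotype",
    "classify_karyotype",
    "tabulate_records",
    "load_karyotype_table",
    "study_records",
    "EUPLOID",
    "BASELINE_DOSAGE",
    "BASELINE_CHROMOSOME_NUMBER",
]

BASELINE_DOSAGE = 4
BASELINE_CHROMOSOME_NUMBER = 48
_N = 12


class KaryotypeError(ValueError):
    """Base class for karyotype grammar errors."""


class KaryotypeParseError(KaryotypeError):
    """A term does not match the karyotype grammar."""


class ChromosomeRangeError(KaryotypeError):
    """Chromosome id outside 1..12."""


class UnsupportedNotationError(KaryotypeError):
    """Grammar-adjacent notation the model cannot represent (e.g. '1/2S')."""


@dataclass(frozen=True)
class Karyotype:
    """Per-chromosome copy-number deviations from the tetraploid baseline.

    Each tuple has 12 entries indexed by chromosome id − 1.  ``whole``
    applies to both arms; ``short_arm`` / ``long_arm`` add on top of it.
    """

    whole: tuple[int, ...] = (0,) * _N
    short_arm: tuple[int, ...] = (0,) * _N
    long_arm: tuple[int, ...] = (0,) * _N

    def __post_init__(self) -> None:
        for name, t in (("whole", self.whole), ("short_arm", self.short_arm),
                        ("long_arm", self.long_arm)):
            if len(t) != _N:
                raise ValueError(f"{name} must have {_N} entries")
        for i in range(_N):
            for arm in (self.short_arm[i], self.long_arm[i]):
                if BASELINE_DOSAGE + self.whole[i] + arm < 0:
                    raise ValueError(
                        f"chromosome {i + 1}: dosage below zero "
                        f"(whole {self.whole[i]:+d}, arm {arm:+d})"
                    )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_deltas(
        cls,
        whole: dict[int, int] | None = None,
        short_arm: dict[int, int] | None = None,
        long_arm: dict[int, int] | None = None,
    ) -> "Karyotype":
        """Build from sparse {chromosome id: delta} mappings (ids 1-based)."""

        def expand(d: dict[int, int] | None) -> tuple[int, ...]:
            out = [0] * _N
            for cid, delta in (d or {}).items():
                if not 1 <= cid <= _N:
                    raise ChromosomeRangeError(f"chromosome id {cid} outside 1..{_N}")
                out[cid - 1] = int(delta)
            return tuple(out)

        return cls(expand(whole), expand(short_arm), expand(long_arm))

    # -- queries -----------------------------------------------------------

    @property
    def is_euploid(self) -> bool:
        return not any(self.whole) and not any(self.short_arm) and not any(self.long_arm)

    @property
    def has_arm_terms(self) -> bool:
        return any(self.short_arm) or any(self.long_arm)

    def dosage(self, cid: int, arm: str) -> int:
        """Absolute copy number of one arm region ('S' or 'L') of chromosome cid."""
        i = cid - 1
        arm_delta = self.short_arm[i] if arm == "S" else self.long_arm[i]
        return BASELINE_DOSAGE + self.whole[i] + arm_delta

    def gained_chromosomes(self) -> set[int]:
        """Chromosomes with any positive whole or arm deviation."""
        return {
            i + 1
            for i in range(_N)
            if self.whole[i] > 0 or self.short_arm[i] > 0 or self.long_arm[i] > 0
        }

    def lost_chromosomes(self) -> set[int]:
        return {
            i + 1
            for i in range(_N)
            if self.whole[i] < 0 or self.short_arm[i] < 0 or self.long_arm[i] < 0
        }


EUPLOID = Karyotype()


@dataclass(frozen=True)
class KaryotypeClass:
    """Classification verdict for one karyotype."""

    category: str  # euploid | simple_gain | simple_loss | compound
    is_segmental: bool
    is_hidden: bool
    chromosome_number: int | None


@dataclass(frozen=True)
class KaryotypeRecord:
    """One row of a karyotype summary table.

    ``karyotype`` is ``None`` when the raw string uses notation outside the
    grammar (kept for plant counting, excluded from dosage computations).
    """

    karyotype_id: str
    karyotype_string: str
    n_plants: int
    karyotype: Karyotype | None

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError(f"{self.karyotype_id}: n_plants must be >= 1")

    @property
    def parseable(self) -> bool:
        return self.karyotype is not None


# --------------------------------------------------------------------------
# Grammar
# --------------------------------------------------------------------------

# Canonical term: ([+-])(\d+)(S|L)?Chr(\d{1,2}); the tolerant reader also
# accepts whitespace, a period after "Chr", and the typographic minus sign.
_TERM_RE = re.compile(
    r"^\s*([+\-−–])\s*(\d+(?:\s*/\s*\d+)?)\s*(S|L)?\s*Chr\.?\s*(\d{1,2})\s*$",
    re.IGNORECASE,
)


def parse_karyotype(text: str) -> Karyotype:
    """Parse a karyotype string into a :class:`Karyotype`.

    ``"WT"`` (any case) and the empty string denote the euploid baseline.

    Raises
    ------
    KaryotypeParseError
        for a term not matching the grammar (message names the term);
    ChromosomeRangeError
        for a chromosome id outside 1..12;
    UnsupportedNotationError
        for fractional magnitudes such as ``"1/2S"``.
    """
    text = text.strip()
    if text == "" or text.upper() == "WT":
        return EUPLOID
    whole = [0] * _N
    short = [0] * _N
    long_ = [0] * _N
    for term in text.split(";"):
        if not term.strip():
            raise KaryotypeParseError(f"empty term in karyotype string: {text!r}")
        m = _TERM_RE.match(term)
        if m is None:
            raise KaryotypeParseError(f"malformed karyotype term: {term.strip()!r}")
        sign_s, mag_s, arm, cid_s = m.groups()
        if "/" in mag_s:
            raise UnsupportedNotationError(
                f"fractional magnitude not supported: {term.strip()!r}"
            )
        sign = 1 if sign_s == "+" else -1
        mag = int(mag_s)
        cid = int(cid_s)
        if not 1 <= cid <= _N:
            raise ChromosomeRangeError(
                f"chromosome id {cid} outside 1..{_N} in term {term.strip()!r}"
            )
        delta = sign * mag
        if arm is None:
            whole[cid - 1] += delta
        elif arm.upper() == "S":
            short[cid - 1] += delta
        else:
            long_[cid - 1] += delta
    return Karyotype(tuple(whole), tuple(short), tuple(long_))


def format_karyotype(k: Karyotype) -> str:
    """Render a karyotype in canonical grammar form (``"WT"`` when euploid).

    Terms are ordered by chromosome, whole-chromosome first, then short
    arm, then long arm, and joined with ``"; "``.
    """
    if k.is_euploid:
        return "WT"
    terms = []
    for i in range(_N):
        cid = i + 1
        if k.whole[i]:
            terms.append(f"{k.whole[i]:+d}Chr{cid:02d}")
        if k.short_arm[i]:
            terms.append(f"{k.short_arm[i]:+d}SChr{cid:02d}")
        if k.long_arm[i]:
            terms.append(f"{k.long_arm[i]:+d}LChr{cid:02d}")
    return "; ".join(terms)


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------


def classify_karyotype(k: Karyotype) -> KaryotypeClass:
    """Classify a karyotype into the euploid/simple/compound taxonomy."""
    if k.is_euploid:
        return KaryotypeClass("euploid", False, False, BASELINE_CHROMOSOME_NUMBER)
    segmental = k.has_arm_terms
    altered = [d for d in k.whole if d != 0]
    if not segmental and len(altered) == 1 and altered[0] in (1, -1):
        category = "simple_gain" if altered[0] == 1 else "simple_loss"
        hidden = False
    else:
        category = "compound"
        hidden = (
            not segmental
            and any(d > 0 for d in k.whole)
            and any(d < 0 for d in k.whole)
            and sum(k.whole) == 0
        )
    number = BASELINE_CHROMOSOME_NUMBER + sum(k.whole) if not segmental else None
    return KaryotypeClass(category, segmental, hidden, number)


# --------------------------------------------------------------------------
# Record tables
# --------------------------------------------------------------------------

_ARM_TERM_RE = re.compile(r"[+\-−–]\s*[\d/]+\s*[SL]\s*Chr", re.IGNORECASE)


def _classify_record(rec: KaryotypeRecord) -> KaryotypeClass:
    if rec.karyotype is not None:
        return classify_karyotype(rec.karyotype)
    # Unparseable record: classified from the raw text only as far as the
    # category flags go; treated as compound, segmental iff any arm term
    # appears, never assigned a chromosome number.
    segmental = bool(_ARM_TERM_RE.search(rec.karyotype_string))
    return KaryotypeClass("compound", segmental, False, None)


def tabulate_records(records: Iterable[KaryotypeRecord]) -> dict:
    """Aggregate a karyotype table into population-level summary counts.

    Returns a dict with plant totals per category, segmental and hidden
    plant totals, the number of distinct aneuploid karyotypes, the range of
    defined chromosome numbers, and per-chromosome gain/loss/combined
    involvement counts (each record contributes its ``n_plants`` weight to
    every chromosome its karyotype involves; unparseable records are
    excluded from involvement counts).
    """
    records = list(records)
    seen: set[str] = set()
    for rec in records:
        if rec.karyotype_id in seen:
            raise ValueError(f"duplicate karyotype_id: {rec.karyotype_id}")
        seen.add(rec.karyotype_id)

    category_plants = {"euploid": 0, "simple_gain": 0, "simple_loss": 0, "compound": 0}
    segmental_plants = 0
    hidden_plants = 0
    aneuploid_plants = 0
    distinct = 0
    numbers: list[int] = []
    gain_counts = {c: 0 for c in range(1, _N + 1)}
    loss_counts = {c: 0 for c in range(1, _N + 1)}
    combined_counts = {c: 0 for c in range(1, _N + 1)}

    for rec in records:
        cls = _classify_record(rec)
        category_plants[cls.category] += rec.n_plants
        if cls.category == "euploid":
            continue
        distinct += 1
        aneuploid_plants += rec.n_plants
        if cls.is_segmental:
            segmental_plants += rec.n_plants
        if cls.is_hidden:
            hidden_plants += rec.n_plants
        if cls.chromosome_number is not None:
            numbers.append(cls.chromosome_number)
        if rec.karyotype is None:
            continue
        gained = rec.karyotype.gained_chromosomes()
        lost = rec.karyotype.lost_chromosomes()
        for c in gained:
            gain_counts[c] += rec.n_plants
        for c in lost:
            loss_counts[c] += rec.n_plants
        for c in gained | lost:
            combined_counts[c] += rec.n_plants

    return {
        "total_plants": sum(r.n_plants for r in records),
        "aneuploid_plants": aneuploid_plants,
        "distinct_karyotypes": distinct,
        "category_plants": category_plants,
        "segmental_plants": segmental_plants,
        "hidden_plants": hidden_plants,
        "chromosome_number_min": min(numbers) if numbers else None,
        "chromosome_number_max": max(numbers) if numbers else None,
        "gain_counts": gain_counts,
        "loss_counts": loss_counts,
        "combined_counts": combined_counts,
    }


def load_karyotype_table(path: str | Path) -> list[KaryotypeRecord]:
    """Read a karyotype table CSV (``karyotype_id,karyotype_string,n_plants``).

    Rows whose karyotype string uses unsupported notation are retained with
    ``karyotype=None``; malformed terms and out-of-range chromosome ids are
    errors (a typo, not a notation the grammar deliberately excludes).
    """
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = row["karyotype_string"]
            try:
                k: Karyotype | None = parse_karyotype(raw)
            except UnsupportedNotationError:
                k = None
            out.append(
                KaryotypeRecord(
                    karyotype_id=row["karyotype_id"],
                    karyotype_string=raw,
                    n_plants=int(row["n_plants"]),
                    karyotype=k,
                )
            )
    return out


def study_records() -> list[KaryotypeRecord]:
    """The bundled 55-karyotype aneuploid summary table (124 plants)."""
    ref = resources.files("karyodepth.data") / "study_karyotypes.csv"
    with resources.as_file(ref) as path:
        return load_karyotype_table(path)
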