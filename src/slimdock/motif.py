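"""Short linear motif (SLiM) grammar, proteome scanning and enrichment.

The pattern dialect is a dash-separated PROSITE-like grammar:

``p[ST]-P-x(4,10)-[RK]-V-x-x-[VI]-R``

* a single uppercase letter is a fixed residue,
* ``[ABC]`` is a residue class,
* ``x`` is a wildcard, ``x(m,n)`` a variable-length wildcard gap,
* a leading ``p`` on exactly one letter/class marks the phosphoacceptor
  (the Ser/Thr whose phosphate the phosphatase removes).

The basic anchor element (the ``[RK]`` that contacts the B55α groove,
D197 in particular) is identified as the first R/K-only element after the
first gap.  A hit records both the phosphoacceptor and anchor positions;
their spacing (residues strictly between them) is the quantity that varies
between substrates (5 in p107, 7 in TAU, 11 in MAP2).

Hit identity: one hit per distinct (phospho_pos, anchor_pos) pair.  With a
single variable gap between phosphoacceptor and anchor this also makes
hits unique per (start, gap length).  The alternative convention -- one
hit per distinct phosphoacceptor position -- is exposed via
``scan_sequence(..., hit_identity="phospho")``.

Ambiguity letters: X/B/Z/U never satisfy a fixed residue or a residue
class; X (unknown residue) does satisfy wildcard and gap positions.
"""

from __future__ import annotations

import itertools
import json
import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import hypergeom

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_WILDCARD_OK = _AA_SET | {"X"}  # unknown residue may sit in non-constrained positions

__all__ = [
    "MotifPattern",
    "ProteinRecord",
    "MotifHit",
    "ScanSummary",
    "EnrichmentResult",
    "PatternError",
    "parse_pattern",
    "scan_sequence",
    "scan_proteome",
    "spacing_distribution",
    "enrich",
]


class PatternError(ValueError):
    """Raised for a malformed motif pattern, naming the offending token."""


# ---------------------------------------------------------------------------
# pattern elements


@dataclass(frozen=True)
class Fixed:
    letter: str

    def matches(self, ch: str) -> bool:
        return ch == self.letter

    def format(self) -> str:
        return self.letter


@dataclass(frozen=True)
class ResidueClass:
    letters: tuple[str, ...]

    def matches(self, ch: str) -> bool:
        return ch in self.letters

    def format(self) -> str:
        return "[" + "".join(self.letters) + "]"


@dataclass(frozen=True)
class Wildcard:
    def matches(self, ch: str) -> bool:
        return ch in _WILDCARD_OK

    def format(self) -> str:
        return "x"


@dataclass(frozen=True)
class Gap:
    min_len: int
    max_len: int

    def format(self) -> str:
        return f"x({self.min_len},{self.max_len})"


Element = Fixed | ResidueClass | Wildcard | Gap


@dataclass(frozen=True)
class MotifPattern:
    """A parsed SLiM consensus."""

    elements: tuple[Element, ...]
    phospho_element_index: int
    anchor_element_index: int
    source_text: str

    def format(self) -> str:
        toks = []
        for i, el in enumerate(self.elements):
            tok = el.format()
            if i == self.phospho_element_index:
                tok = "p" + tok
            toks.append(tok)
        return "-".join(toks)

    @property
    def min_length(self) -> int:
        return sum(el.min_len if isinstance(el, Gap) else 1 for el in self.elements)


_TOKEN_RE = re.compile(
    r"^(?P<ph>p)?(?:(?P<fixed>[A-Z])|\[(?P<cls>[A-Z]+)\])$"
)
_GAP_RE = re.compile(r"^x\((?P<lo>\d+),(?P<hi>\d+)\)$")


def parse_pattern(pattern_text: str) -> MotifPattern:
    """Parse the dash-separated SLiM dialect into a :class:`MotifPattern`."""
    if not pattern_text or not pattern_text.strip():
        raise PatternError("empty pattern")
    elements: list[Element] = []
    phospho_idx: int | None = None
    for tok in pattern_text.strip().split("-"):
        if tok == "x":
            elements.append(Wildcard())
            continue
        m = _GAP_RE.match(tok)
        if m:
            lo, hi = int(m.group("lo")), int(m.group("hi"))
            if lo > hi:
                raise PatternError(f"gap bounds inverted in token '{tok}'")
            elements.append(Gap(lo, hi))
            continue
        m = _TOKEN_RE.match(tok)
        if m is None:
            raise PatternError(f"malformed token '{tok}'")
        if m.group("fixed"):
            letters = m.group("fixed")
            el: Element = Fixed(letters)
        else:
            letters = m.group("cls")
            if not letters:
                raise PatternError(f"empty residue class in token '{tok}'")
            el = ResidueClass(tuple(dict.fromkeys(letters)))
        bad = set(letters) - _AA_SET
        if bad:
            raise PatternError(
                f"non-amino-acid letter(s) {sorted(bad)} in token '{tok}'"
            )
        if m.group("ph"):
            if phospho_idx is not None:
                raise PatternError(
                    f"second phosphoacceptor marker at token '{tok}'"
                )
            phospho_idx = len(elements)
            acceptor = set(letters)
            if not acceptor <= {"S", "T", "Y"}:
                raise PatternError(
                    f"phosphoacceptor token '{tok}' must be over S/T/Y"
                )
        elements.append(el)
    if phospho_idx is None:
        raise PatternError("no phosphoacceptor ('p'-prefixed) element")

    first_gap = next(
        (i for i, el in enumerate(elements) if isinstance(el, Gap)), None
    )
    anchor_idx = None
    if first_gap is not None:
        for i in range(first_gap + 1, len(elements)):
            el = elements[i]
            letters = (
                {el.letter} if isinstance(el, Fixed)
                else set(el.letters) if isinstance(el, ResidueClass)
                else set()
            )
            if letters and letters <= {"R", "K"}:
                anchor_idx = i
                break
    if anchor_idx is None:
        raise PatternError("no basic [RK] anchor element after the gap")
    if phospho_idx >= anchor_idx:
        raise PatternError("phosphoacceptor must precede the anchor element")
    return MotifPattern(tuple(elements), phospho_idx, anchor_idx, pattern_text.strip())


# ---------------------------------------------------------------------------
# sequences and hits


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        seq = self.sequence.upper()
        if seq != self.sequence:
            warnings.warn(
                f"sequence of {self.id} contained lowercase letters; uppercased",
                stacklevel=3,
            )
            object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """A located SLiM instance (1-based inclusive coordinates)."""

    protein_id: str
    start: int
    end: int
    phospho_pos: int
    anchor_pos: int
    gap_len: int
    matched_seq: str

    def __post_init__(self):
        if not (self.start <= self.phospho_pos < self.anchor_pos <= self.end):
            raise ValueError("hit positions violate start <= phospho < anchor <= end")
        if len(self.matched_seq) != self.end - self.start + 1:
            raise ValueError("matched_seq length disagrees with span")

    @property
    def spacing(self) -> int:
        """Residues strictly between phosphoacceptor and anchor."""
        return self.anchor_pos - self.phospho_pos - 1


@dataclass(frozen=True)
class ScanSummary:
    n_hits: int
    n_proteins_with_hit: int
    n_proteins_total: int

    @property
    def fraction_with_hit(self) -> float:
        return self.n_proteins_with_hit / self.n_proteins_total

    def to_dict(self) -> dict:
        return {
            "n_hits": self.n_hits,
            "n_proteins_with_hit": self.n_proteins_with_hit,
            "n_proteins_total": self.n_proteins_total,
            "fraction_with_hit": self.fraction_with_hit,
        }


def _iter_matches(pattern: MotifPattern, seq: str, start0: int):
    """Yield (positions, gap_total) for every realization anchored at start0.

    ``positions`` maps element index -> 0-based start of that element in seq.
    Gap lengths are enumerated smallest-first so the first realization seen
    for a given (phospho, anchor) pair has the shortest leading gaps.
    """
    gaps = [i for i, el in enumerate(pattern.elements) if isinstance(el, Gap)]
    gap_ranges = [
        range(pattern.elements[i].min_len, pattern.elements[i].max_len + 1)
        for i in gaps
    ]
    for lens in itertools.product(*gap_ranges):
        gap_len_of = dict(zip(gaps, lens))
        pos = start0
        positions: dict[int, int] = {}
        ok = True
        for i, el in enumerate(pattern.elements):
            positions[i] = pos
            if isinstance(el, Gap):
                n = gap_len_of[i]
                chunk = seq[pos : pos + n]
                if len(chunk) < n or any(c not in _WILDCARD_OK for c in chunk):
                    ok = False
                    break
                pos += n
            else:
                if pos >= len(seq) or not el.matches(seq[pos]):
                    ok = False
                    break
                pos += 1
        if ok:
            yield positions, pos - start0, sum(lens)


def scan_sequence(
    pattern: MotifPattern,
    record: ProteinRecord,
    offset: int = 0,
    hit_identity: str = "phospho_anchor",
) -> list[MotifHit]:
    """Find every motif instance in one sequence.

    ``offset`` shifts reported 1-based positions to author numbering (e.g.
    offset 611 maps local position 4 to p107 residue 615).

    ``hit_identity`` is "phospho_anchor" (default: one hit per distinct
    (phospho_pos, anchor_pos) pair) or "phospho" (one hit per distinct
    phosphoacceptor position).
    """
    if hit_identity not in ("phospho_anchor", "phospho"):
        raise ValueError(f"unknown hit identity rule {hit_identity!r}")
    seq = record.sequence
    seen: dict[tuple, MotifHit] = {}
    for start0 in range(0, len(seq) - pattern.min_length + 1):
        for positions, span, gap_total in _iter_matches(pattern, seq, start0):
            phospho = positions[pattern.phospho_element_index] + 1
            anchor = positions[pattern.anchor_element_index] + 1
            key = (phospho,) if hit_identity == "phospho" else (phospho, anchor)
            if key in seen:
                continue
            seen[key] = MotifHit(
                protein_id=record.id,
                start=start0 + 1 + offset,
                end=start0 + span + offset,
                phospho_pos=phospho + offset,
                anchor_pos=anchor + offset,
                gap_len=gap_total,
                matched_seq=seq[start0 : start0 + span],
            )
    return sorted(seen.values(), key=lambda h: (h.phospho_pos, h.anchor_pos))


def scan_proteome(
    pattern: MotifPattern,
    records: Sequence[ProteinRecord],
    hit_identity: str = "phospho_anchor",
) -> tuple[list[MotifHit], ScanSummary]:
    """Scan a whole proteome; returns all hits plus per-proteome counts."""
    if not records:
        raise ValueError("empty proteome")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dupes[:5]}")
    hits: list[MotifHit] = []
    n_pos = 0
    for rec in records:
        h = scan_sequence(pattern, rec, hit_identity=hit_identity)
        hits.extend(h)
        n_pos += bool(h)
    return hits, ScanSummary(len(hits), n_pos, len(records))


def spacing_distribution(hits: Iterable[MotifHit]) -> Counter:
    """Histogram of phospho-to-anchor spacings over a hit list."""
    return Counter(h.spacing for h in hits)


# ---------------------------------------------------------------------------
# enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    n_background: int
    k_background_positive: int
    n_target: int
    k_target_positive: int
    odds_ratio: float
    p_value: float
    direction: str  # enriched | depleted | none

    @property
    def fraction_target(self) -> float:
        return self.k_target_positive / self.n_target

    @property
    def fraction_background(self) -> float:
        return self.k_background_positive / self.n_background

    def to_dict(self) -> dict:
        d = {
            "n_background": self.n_background,
            "k_background_positive": self.k_background_positive,
            "n_target": self.n_target,
            "k_target_positive": self.k_target_positive,
            "fraction_target": self.fraction_target,
            "fraction_background": self.fraction_background,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "direction": self.direction,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def enrich(
    pattern: MotifPattern,
    target_ids: set[str],
    background: Sequence[ProteinRecord],
) -> EnrichmentResult:
    """One-sided Fisher exact test for motif enrichment in an interactor set.

    A protein counts as positive iff it carries at least one motif hit.
    The target set is drawn from the background (hypergeometric null); the
    p-value is the exact tail P(X >= k) for enrichment, or the mirror tail
    P(X <= k) for depletion.  Equal fractions give direction "none", p = 1.
    """
    if not target_ids:
        raise ValueError("empty target set")
    bg_ids = {r.id for r in background}
    missing = set(target_ids) - bg_ids
    if missing:
        raise ValueError(f"target ids not in background: {sorted(missing)[:5]}")
    positive_ids = {
        r.id for r in background if scan_sequence(pattern, r)
    }
    return enrichment_from_counts(
        n_background=len(background),
        k_background_positive=len(positive_ids),
        n_target=len(target_ids),
        k_target_positive=len(target_ids & positive_ids),
    )


def enrichment_from_counts(
    n_background: int,
    k_background_positive: int,
    n_target: int,
    k_target_positive: int,
) -> EnrichmentResult:
    """Exact hypergeometric test from positive/total counts."""
    N, K, n, k = n_background, k_background_positive, n_target, k_target_positive
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError("inconsistent enrichment counts")
    f_t = k / n
    f_b = K / N
    if f_t > f_b:
        direction = "enriched"
        p = float(hypergeom.sf(k - 1, N, K, n))
    elif f_t < f_b:
        direction = "depleted"
        p = float(hypergeom.cdf(k, N, K, n))
    else:
        direction = "none"
        p = 1.0
    a, b = k, n - k
    c, d = K - k, (N - n) - (K - k)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(N, K, n, k, odds, min(p, 1.0), direction)
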