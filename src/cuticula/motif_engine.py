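"""Degenerate-motif parsing and matching for cuticular-protein diagnostics.

CP families are recognised by short degenerate patterns: consensus strings
with wildcard positions (the R&R chitin-binding consensus of the CPR family),
cysteine-spacing patterns with bounded wildcard runs (the ChtBD2 patterns of
CPAP1/CPAP3, the C-x(5)-C of CPCFC), short repeats (GGxGG for the
glycine-rich CPG family, AAP[AVL] for CPH), and dipeptide densities (PV/PY
for CPLCP). This module parses the field's motif notation into
:class:`MotifSpec` objects and matches them against protein sequences.

Match semantics: fixed residues and alternative sets may be substituted up
to ``max_mismatches`` times; wildcards and bounded gaps never count
mismatches; an ``X`` (unknown residue) in the protein never matches a fixed
or alternative element and therefore costs a mismatch.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import yaml

from cuticula.sequence_io import AMINO_ACIDS, ProteinRecord

MOTIF_KINDS = ("consensus", "spacing", "repeat", "dipeptide")

# Pattern elements: ("res", "A") fixed residue; ("alt", frozenset) alternative
# set; ("gap", lo, hi) bounded run of wildcards (a single wildcard is gap(1,1)).
Element = tuple


@dataclass(frozen=True)
class MotifSpec:
    """A parsed degenerate motif with computable min/max match lengths."""

    name: str
    kind: str
    elements: tuple[Element, ...]
    max_mismatches: int = 0
    source: str = ""

    def __post_init__(self):
        if self.kind not in MOTIF_KINDS:
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if not self.elements:
            raise ValueError(f"{self.name}: empty element list")
        if self.max_mismatches < 0:
            raise ValueError(f"{self.name}: max_mismatches must be >= 0")

    @property
    def min_length(self) -> int:
        return sum(e[1] if e[0] == "gap" else 1 for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e[2] if e[0] == "gap" else 1 for e in self.elements)

    @property
    def n_informative(self) -> int:
        """Number of fixed/alternative positions (the scorable ones)."""
        return sum(1 for e in self.elements if e[0] in ("res", "alt"))

    def with_mismatches(self, k: int) -> "MotifSpec":
        return MotifSpec(self.name, self.kind, self.elements, k, self.source)


@dataclass(frozen=True)
class MotifHit:
    """One match of a motif in a protein: [start, end) window, 0-based."""

    motif: str
    start: int
    end: int
    mismatches: int
    matched_text: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("hit must span at least one residue")


def parse_motif(text: str, kind: str, name: str = "",
                max_mismatches: int = 0) -> MotifSpec:
    """Parse a motif written in the field's notation into a :class:`MotifSpec`.

    Accepted notation (see module docstring): ``GxFxY``, ``C-X5-C``,
    ``Cx(14-16)C``, ``KX_4-5_FIKAP``, ``K[YF]``, ``V/I``.
    """
    elements: list[Element] = []
    i, n = 0, len(text)

    def read_int(j: int) -> tuple[int, int]:
        k = j
        while k < n and text[k].isdigit():
            k += 1
        return int(text[j:k]), k

    while i < n:
        c = text[i]
        if c in "-_ .":
            i += 1
            continue
        if c == "[":
            j = text.find("]", i)
            if j == -1:
                raise ValueError(f"{text!r}: unterminated '[' at position {i}")
            alts = frozenset(text[i + 1:j].upper())
            if not alts or not alts.issubset(set(AMINO_ACIDS)):
                raise ValueError(f"{text!r}: bad alternative set {text[i+1:j]!r}")
            elements.append(("alt", alts))
            i = j + 1
            continue
        if c in "xX":
            j = i + 1
            while j < n and text[j] == "_":
                j += 1
            if j < n and text[j] == "(":
                k = text.find(")", j)
                if k == -1:
                    raise ValueError(f"{text!r}: unterminated '(' at {j}")
                lo, hi = _parse_range(text[j + 1:k], text)
                elements.append(("gap", lo, hi))
                i = k + 1
            elif j < n and text[j].isdigit():
                lo, j = read_int(j)
                hi = lo
                if j < n and text[j] == "-" and j + 1 < n and text[j + 1].isdigit():
                    hi, j = read_int(j + 1)
                if lo > hi:
                    raise ValueError(f"{text!r}: malformed range {lo}-{hi}")
                elements.append(("gap", lo, hi))
                i = j
            else:
                elements.append(("gap", 1, 1))
                i += 1
            continue
        if c.isalpha() and c.upper() in AMINO_ACIDS:
            res = c.upper()
            if i + 2 < n and text[i + 1] == "/" and text[i + 2].isalpha():
                other = text[i + 2].upper()
                if other not in AMINO_ACIDS:
                    raise ValueError(f"{text!r}: bad alternative {other!r}")
                elements.append(("alt", frozenset({res, other})))
                i += 3
            else:
                elements.append(("res", res))
                i += 1
            continue
        raise ValueError(f"{text!r}: unknown character {c!r} at position {i}")

    return MotifSpec(name or text, kind, tuple(elements), max_mismatches, text)


def _parse_range(body: str, ctx: str) -> tuple[int, int]:
    parts = body.split("-")
    try:
        if len(parts) == 1:
            lo = hi = int(parts[0])
        elif len(parts) == 2:
            lo, hi = int(parts[0]), int(parts[1])
        else:
            raise ValueError
    except ValueError:
        raise ValueError(f"{ctx!r}: malformed gap range ({body!r})") from None
    if not (0 <= lo <= hi):
        raise ValueError(f"{ctx!r}: gap bounds must satisfy 0 <= min <= max")
    return lo, hi


def match_window(motif: MotifSpec, window: str) -> Optional[int]:
    """Minimal mismatch count to match `window` exactly end-to-end, or None.

    Anchored at both ends: the motif's elements must consume the entire
    window. Used by :func:`scan` and directly testable against brute force.
    """
    window = window.upper()
    elements = motif.elements
    n_el, n_w = len(elements), len(window)
    memo: dict[tuple[int, int], Optional[int]] = {}

    def go(e: int, p: int) -> Optional[int]:
        if e == n_el:
            return 0 if p == n_w else None
        key = (e, p)
        if key in memo:
            return memo[key]
        el = elements[e]
        best: Optional[int] = None
        if el[0] == "gap":
            for w in range(el[1], el[2] + 1):
                if p + w > n_w:
                    break
                sub = go(e + 1, p + w)
                if sub is not None and (best is None or sub < best):
                    best = sub
        else:
            if p < n_w:
                ch = window[p]
                if el[0] == "res":
                    cost = 0 if ch == el[1] else 1
                else:
                    cost = 0 if (ch in el[1] and ch != "X") else 1
                sub = go(e + 1, p + 1)
                if sub is not None:
                    best = sub + cost
        memo[key] = best
        return best

    return go(0, 0)


def _match_ends(motif: MotifSpec, seq: str, start: int) -> dict[int, int]:
    """Forward DP from `start`: end offset -> minimal mismatches.

    States exceeding the motif's mismatch budget are pruned, which keeps
    the state set tiny on non-matching sequence. Equivalent to running
    :func:`match_window` on every window starting at `start` (the property
    tests check this equivalence against brute force).
    """
    budget = motif.max_mismatches
    states: dict[int, int] = {start: 0}
    n = len(seq)
    for el in motif.elements:
        nxt: dict[int, int] = {}
        if el[0] == "gap":
            lo, hi = el[1], el[2]
            for p, cost in states.items():
                for w in range(lo, hi + 1):
                    q = p + w
                    if q > n:
                        break
                    if q not in nxt or cost < nxt[q]:
                        nxt[q] = cost
        else:
            for p, cost in states.items():
                if p >= n:
                    continue
                ch = seq[p]
                if el[0] == "res":
                    step = 0 if ch == el[1] else 1
                else:
                    step = 0 if (ch in el[1] and ch != "X") else 1
                total = cost + step
                if total <= budget and (p + 1 not in nxt or total < nxt[p + 1]):
                    nxt[p + 1] = total
        states = nxt
        if not states:
            break
    return states


def scan(protein: ProteinRecord, motif: MotifSpec) -> list[MotifHit]:
    """All windows of `protein` matching `motif` within its mismatch budget.

    Every matching window is reported (overlaps included), sorted by start
    then end; mismatches is the minimal substitution count for that window.
    """
    seq = protein.sequence
    hits: list[MotifHit] = []
    for start in range(len(seq)):
        for end, mm in sorted(_match_ends(motif, seq, start).items()):
            if end > start:
                hits.append(MotifHit(motif.name, start, end, mm, seq[start:end]))
    return hits


def count_nonoverlapping(protein: ProteinRecord, motif: MotifSpec) -> int:
    """Greedy left-to-right count of non-overlapping motif occurrences.

    Consecutive occurrences may share exactly one bounding residue: tandem
    repeats of cysteine-anchored motifs (C-x(5)-C-x(5)-C) chain on the
    shared cysteine and count as two repeats.
    """
    count, cursor = 0, 0
    for hit in scan(protein, motif):
        if hit.start >= cursor:
            count += 1
            cursor = max(hit.start + 1, hit.end - 1)
    return count


def count_dipeptide(protein: ProteinRecord, dipeptide: str) -> int:
    """Count (possibly overlapping) occurrences of a 2-residue word."""
    if len(dipeptide) != 2:
        raise ValueError("dipeptide must be exactly 2 residues")
    dp = dipeptide.upper()
    seq = protein.sequence
    return sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == dp)


def composition(protein: ProteinRecord) -> dict[str, float]:
    """Residue fractions over the sequence, unknown residues (X) excluded."""
    informative = [c for c in protein.sequence if c != "X"]
    if not informative:
        raise ValueError(f"{protein.id}: no informative residues (all X)")
    total = len(informative)
    out: dict[str, float] = {}
    for c in informative:
        out[c] = out.get(c, 0.0) + 1.0
    return {c: k / total for c, k in sorted(out.items())}


def best_consensus_score(protein: ProteinRecord, motif: MotifSpec
                         ) -> tuple[float, Optional[int]]:
    """Best fraction of consensus fixed/alternative positions matched.

    The consensus is slid along the protein with all gaps at minimal width;
    at each offset the score is (matched informative positions) / (total
    informative positions). Returns (max score, offset of the first maximum),
    or (0.0, None) when the protein is shorter than the consensus.
    """
    if motif.kind != "consensus":
        raise ValueError(f"{motif.name}: best_consensus_score needs a consensus motif")
    # expand to a fixed-width template: None = wildcard slot
    template: list = []
    for el in motif.elements:
        if el[0] == "gap":
            template.extend([None] * el[1])
        else:
            template.append(el)
    L = len(template)
    n_inf = motif.n_informative
    seq = protein.sequence
    if len(seq) < L or n_inf == 0:
        return 0.0, None
    best, best_off = -1.0, None
    for off in range(len(seq) - L + 1):
        matched = 0
        for j, el in enumerate(template):
            if el is None:
                continue
            ch = seq[off + j]
            if ch == "X":
                continue
            if el[0] == "res":
                matched += ch == el[1]
            else:
                matched += ch in el[1]
        score = matched / n_inf
        if score > best:
            best, best_off = score, off
    return best, best_off


def _load_default_motifs() -> dict[str, MotifSpec]:
    text = (importlib.resources.files("cuticula") / "data" / "motifs.yaml").read_text()
    spec = yaml.safe_load(text)
    return {
        name: parse_motif(entry["pattern"], entry["kind"], name=name,
                          max_mismatches=int(entry.get("max_mismatches", 0)))
        for name, entry in spec["motifs"].items()
    }


def load_motifs(path) -> dict[str, MotifSpec]:
    """Load motif definitions from a YAML file (same schema as the bundled one)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return {
        name: parse_motif(entry["pattern"], entry["kind"], name=name,
                          max_mismatches=int(entry.get("max_mismatches", 0)))
        for name, entry in spec["motifs"].items()
    }


#: The bundled motif set (family-defining diagnostics listed in data/motifs.yaml).
DEFAULT_MOTIFS: dict[str, MotifSpec] = _load_default_motifs()
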