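"""Pairwise global identity and reciprocal-best-hit (RBH) orthology.

Family membership by homology and ortholog-based naming both rest on
percent identity between full-length proteins. Identity is computed from an
optimal global (Needleman-Wunsch) alignment with affine gap penalties under
a standard substitution matrix, with terminal gap columns excluded from the
denominator — the least length-punitive convention for proteins of unequal
length, and the one used throughout this package.

Orthology uses the classic RBH rule: a query/reference pair is a 1:1
ortholog when each is the other's unique best hit at or above a minimum
identity. Best-hit edges that fail the reciprocity test are grouped into
connected components and reported as co-ortholog groups, the signature of
lineage-specific family expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from cuticula.config import RunConfig
from cuticula.sequence_io import ProteinRecord

_DEFAULT = RunConfig()


@dataclass(frozen=True)
class AlignmentResult:
    query: str
    subject: str
    identity: float
    score: float

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must lie in [0, 1]")


@dataclass
class OrthologMap:
    """RBH output: 1:1 pairs plus co-ortholog groups of ambiguous best hits."""

    #: (query id, reference id, identity, relation); relation is "1:1" or
    #: "co-ortholog-group <k>"
    pairs: list[tuple[str, str, float, str]] = field(default_factory=list)
    #: group index -> (sorted query ids, sorted reference ids)
    groups: dict[int, tuple[list[str], list[str]]] = field(default_factory=dict)

    def one_to_one(self) -> dict[str, str]:
        """query id -> reference id for the 1:1 pairs."""
        return {q: r for q, r, _, rel in self.pairs if rel == "1:1"}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("query\treference\tidentity\trelation\n")
            for q, r, ident, rel in self.pairs:
                fh.write(f"{q}\t{r}\t{ident:.4f}\t{rel}\n")


def _aligner(config: RunConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(config.substitution_matrix)
    aligner.open_gap_score = -abs(config.gap_open)
    aligner.extend_gap_score = -abs(config.gap_extend)
    return aligner


def global_identity(a: ProteinRecord, b: ProteinRecord,
                    config: RunConfig = _DEFAULT) -> AlignmentResult:
    """Optimal global alignment identity between two proteins.

    Identity = matching columns / aligned columns, where the leading and
    trailing columns in which either sequence is gapped are excluded.
    Symmetric by construction: the pair is canonically ordered before
    alignment, so identity(a, b) == identity(b, a).
    """
    first, second = a, b
    if (b.sequence, b.id) < (a.sequence, a.id):
        first, second = b, a
    aligner = _aligner(config)
    alignment = aligner.align(first.sequence, second.sequence)[0]
    row0, row1 = str(alignment[0]), str(alignment[1])
    ncol = len(row0)
    lo = 0
    while lo < ncol and (row0[lo] == "-" or row1[lo] == "-"):
        lo += 1
    hi = ncol
    while hi > lo and (row0[hi - 1] == "-" or row1[hi - 1] == "-"):
        hi -= 1
    core = hi - lo
    if core == 0:
        identity = 0.0
    else:
        matches = sum(
            1 for i in range(lo, hi)
            if row0[i] == row1[i] and row0[i] != "-"
        )
        identity = matches / core
    return AlignmentResult(a.id, b.id, identity, float(alignment.score))


def identity_matrix(queries, references, config: RunConfig = _DEFAULT
                    ) -> dict[tuple[str, str], float]:
    """Identity for every (query, reference) pair, keyed by id pair."""
    out: dict[tuple[str, str], float] = {}
    for q in queries:
        for r in references:
            out[(q.id, r.id)] = global_identity(q, r, config).identity
    return out


def best_identity(query: ProteinRecord, references,
                  config: RunConfig = _DEFAULT) -> tuple[float, str | None]:
    """Highest identity of `query` to any reference (0.0, None when empty)."""
    best, best_id = 0.0, None
    for r in references:
        ident = global_identity(query, r, config).identity
        if ident > best or (ident == best and best_id is not None and r.id < best_id):
            best, best_id = ident, r.id
    return best, best_id


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def reciprocal_best_hits(queries, references, config: RunConfig = _DEFAULT,
                         min_identity: float | None = None) -> OrthologMap:
    """RBH orthology between a query proteome and a reference set.

    A pair (q, r) is 1:1 iff r is q's unique best reference hit, q is r's
    unique best query hit, and identity >= `min_identity`. All other
    best-hit edges at or above the threshold are grouped into connected
    components, reported as co-ortholog groups numbered in order of their
    lexicographically smallest query id.
    """
    if min_identity is None:
        min_identity = config.rbh_min_identity
    queries = sorted(queries, key=lambda p: p.id)
    references = sorted(references, key=lambda p: p.id)
    if not queries or not references:
        return OrthologMap()
    ident = identity_matrix(queries, references, config)

    def bests(items, others, key):
        out = {}
        for a in items:
            vals = [(ident[key(a.id, b.id)], b.id) for b in others]
            top = max(v for v, _ in vals)
            out[a.id] = (top, sorted(b for v, b in vals if v == top))
        return out

    q_best = bests(queries, references, lambda q, r: (q, r))
    r_best = bests(references, queries, lambda r, q: (q, r))

    pairs: list[tuple[str, str, float, str]] = []
    matched_q: set[str] = set()
    matched_r: set[str] = set()
    for q in queries:
        top, hits = q_best[q.id]
        if top < min_identity or len(hits) != 1:
            continue
        r = hits[0]
        r_top, r_hits = r_best[r]
        if len(r_hits) == 1 and r_hits[0] == q.id:
            pairs.append((q.id, r, top, "1:1"))
            matched_q.add(q.id)
            matched_r.add(r)

    # ambiguous best-hit edges -> co-ortholog components
    uf = _UnionFind()
    edges: list[tuple[str, str, float]] = []
    for q in queries:
        if q.id in matched_q:
            continue
        top, hits = q_best[q.id]
        if top < min_identity:
            continue
        for r in hits:
            edges.append((q.id, r, top))
            uf.union("Q:" + q.id, "R:" + r)
    for r in references:
        if r.id in matched_r:
            continue
        top, hits = r_best[r.id]
        if top < min_identity:
            continue
        for q in hits:
            if q in matched_q:
                continue
            edges.append((q, r.id, top))
            uf.union("Q:" + q, "R:" + r.id)

    comp_members: dict[str, tuple[set[str], set[str]]] = {}
    for q, r, _ in edges:
        root = uf.find("Q:" + q)
        qs, rs = comp_members.setdefault(root, (set(), set()))
        qs.add(q)
        rs.add(r)
    groups: dict[int, tuple[list[str], list[str]]] = {}
    root_to_k: dict[str, int] = {}
    for k, root in enumerate(
            sorted(comp_members, key=lambda rt: min(comp_members[rt][0])), start=1):
        qs, rs = comp_members[root]
        groups[k] = (sorted(qs), sorted(rs))
        root_to_k[root] = k
    seen_edges = set()
    for q, r, top in sorted(edges):
        if (q, r) in seen_edges:
            continue
        seen_edges.add((q, r))
        k = root_to_k[uf.find("Q:" + q)]
        pairs.append((q, r, ident[(q, r)], f"co-ortholog-group {k}"))

    return OrthologMap(sorted(pairs), groups)
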