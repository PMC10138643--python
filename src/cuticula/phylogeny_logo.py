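"""Neighbor-joining phylogenies with Poisson distances, bootstrap, and logos.

The CPR, CPAP and Tweedle families are classified phylogenetically:
full-length (or consensus-region) sequences are aligned, pairwise distances
are computed under the Poisson correction d = -ln(1 - p) with pairwise
deletion of gap columns, an unrooted tree is built by neighbor joining
(Saitou-Nei Q-criterion), and internal-edge support is estimated by
bootstrap resampling of alignment columns. Per-column residue frequencies
and information content (the numbers behind a sequence logo) are computed
for conserved regions such as the R&R consensus.

Conventions stated here because the reference desktop tools leave them
implicit: NJ ties are broken toward the lexicographically smallest label
pair; negative NJ branch-length estimates are clamped to zero and logged;
columns where either sequence is gapped or X are dropped per pair
(pairwise deletion); p = 1 yields an infinite distance which NJ refuses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from Bio import Align, SeqIO
from cuticula.config import RunConfig
from cuticula.motif_engine import MotifSpec, best_consensus_score
from cuticula.sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

_DEFAULT = RunConfig()

GAP = "-"


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows, unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in MSA")
        if self.rows:
            length = len(self.rows[0])
            if any(len(r) != length for r in self.rows):
                raise ValueError("all MSA rows must have the same length")
        self.rows = [r.upper() for r in self.rows]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def sample_columns(self, columns) -> "Msa":
        return Msa(list(self.ids), ["".join(r[c] for c in columns) for r in self.rows])

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match id count")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite]):
            raise ValueError("matrix must be symmetric")
        if np.any(m[finite] < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def has_infinite(self) -> bool:
        return bool(np.any(np.isinf(self.matrix)))


@dataclass
class TreeNode:
    """Node of an (unrooted, trifurcating-root) NJ tree."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Canonical leaf-set of each internal edge (smaller side; ties by
        lexicographic order)."""
        all_leaves = frozenset(self.root.leaves())
        out: set[frozenset] = set()

        def walk(node: TreeNode, at_root: bool):
            for child in node.children:
                if not child.is_leaf():
                    side = frozenset(child.leaves())
                    other = all_leaves - side
                    if side and other:
                        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
                        out.add(frozenset(canon))
                walk(child, False)

        walk(self.root, True)
        return out


def poisson_distance(msa: Msa, id_a: str, id_b: str) -> float:
    """Poisson-corrected distance -ln(1 - p) with pairwise deletion.

    p is the proportion of differing residues over columns where both rows
    are ungapped and not X. Identical shared columns give 0; p = 1 gives
    +inf (flagged to the caller; NJ refuses infinite entries).
    """
    a, b = msa.row(id_a), msa.row(id_b)
    shared = diffs = 0
    for ca, cb in zip(a, b):
        if ca in (GAP, "X") or cb in (GAP, "X"):
            continue
        shared += 1
        diffs += ca != cb
    if shared == 0:
        raise ValueError(f"no shared ungapped columns for pair ({id_a}, {id_b})")
    p = diffs / shared
    if p >= 1.0:
        logger.warning("pair (%s, %s): all shared columns differ; distance infinite",
                       id_a, id_b)
        return math.inf
    return -math.log(1.0 - p)


def poisson_distance_matrix(msa: Msa, truncate: bool = False) -> DistanceMatrix:
    """All-pairs Poisson distances. With `truncate`, p is capped just below
    1 so every entry stays finite (used inside bootstrap replicates)."""
    n = len(msa)
    chars = np.frombuffer("".join(msa.rows).encode("ascii"),
                          dtype=np.uint8).reshape(n, -1)
    valid = (chars != ord(GAP)) & (chars != ord("X"))
    m = np.zeros((n, n))
    for i in range(n):
        shared = valid[i] & valid[i + 1:]
        n_shared = shared.sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            if n_shared[k] == 0:
                raise ValueError(
                    f"no shared ungapped columns for pair ({msa.ids[i]}, {msa.ids[j]})")
        diffs = ((chars[i] != chars[i + 1:]) & shared).sum(axis=1)
        with np.errstate(divide="ignore"):
            p = diffs / n_shared
            if truncate:
                p = np.minimum(p, 1.0 - 1e-6)
            for k, j in enumerate(range(i + 1, n)):
                if p[k] >= 1.0:
                    logger.warning("pair (%s, %s): p = 1, infinite distance",
                                   msa.ids[i], msa.ids[j])
                    m[i, j] = m[j, i] = math.inf
                else:
                    m[i, j] = m[j, i] = -math.log(1.0 - p[k])
    return DistanceMatrix(list(msa.ids), m)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking.

    Q-criterion ties are resolved toward the lexicographically smallest
    (label, label) pair, where an internal node carries the smallest leaf
    name beneath it. Negative branch-length estimates are clamped to 0.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if dm.has_infinite():
        raise ValueError(
            "distance matrix contains infinite entries; exclude those taxa first")
    nodes = [TreeNode(name=i) for i in dm.ids]
    labels = list(dm.ids)
    D = dm.matrix.copy()

    def clamp(x: float, context: str) -> float:
        if x < 0:
            if x < -1e-9:
                logger.info("negative NJ branch length %.4g at %s clamped to 0",
                            x, context)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i in range(m) for j in range(i + 1, m)
            if Q[i, j] <= qmin + 1e-12
        ]
        _, i, j = min(candidates)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        pair = f"({labels[i]},{labels[j]})"
        nodes[i].length = clamp(li, pair)
        nodes[j].length = clamp(lj, pair)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_label = min(labels[i], labels[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = clamp((d01 + d02 - d12) / 2, "final")
    nodes[1].length = clamp((d01 + d12 - d02) / 2, "final")
    nodes[2].length = clamp((d02 + d12 - d01) / 2, "final")
    return Tree(TreeNode(children=nodes))


def bootstrap_support(msa: Msa, replicates: int, seed: int,
                      truncate_replicates: bool = True) -> Tree:
    """Full-data NJ tree with bootstrap support on internal edges.

    Alignment columns are resampled with replacement `replicates` times;
    support = percentage of replicate trees containing each internal
    bipartition of the full-data tree. Deterministic given `seed`.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    dm = poisson_distance_matrix(msa)
    if np.all(dm.matrix == 0):
        logger.warning("all pairwise distances are zero; tree is unresolved")
    tree = nj_tree(dm)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = msa.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_msa = msa.sample_columns(cols)
        try:
            rep_dm = poisson_distance_matrix(rep_msa, truncate=truncate_replicates)
        except ValueError:
            continue  # a pair lost all shared columns in this replicate
        rep_bps = nj_tree(rep_dm).bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1

    all_leaves = frozenset(tree.root.leaves())

    def annotate(node: TreeNode):
        for child in node.children:
            if not child.is_leaf():
                side = frozenset(child.leaves())
                canon = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
                canon = frozenset(canon)
                if canon in counts:
                    child.support = 100.0 * counts[canon] / replicates
            annotate(child)

    annotate(tree.root)
    return tree


@dataclass
class LogoMatrix:
    """Per-column residue frequencies and information content in bits."""

    frequencies: list[dict[str, float] | None]
    information: list[float]  # NaN where the column is all-gap

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tinformation_bits\tfrequencies\n")
            for i, (freq, info) in enumerate(zip(self.frequencies, self.information)):
                pairs = "" if freq is None else ",".join(
                    f"{r}:{f:.4f}" for r, f in sorted(freq.items()))
                fh.write(f"{i}\t{info if not math.isnan(info) else 'NA'}\t{pairs}\n")


def logo_matrix(msa: Msa) -> LogoMatrix:
    """Column frequencies and information R = log2(20) - H (bits).

    Gap and X characters are ignored per column; an all-gap column has no
    defined information and is reported as NaN.
    """
    if len(msa) < 2:
        raise ValueError("logo needs at least 2 rows")
    max_bits = math.log2(20)
    freqs: list[dict[str, float] | None] = []
    info: list[float] = []
    for c in range(msa.n_columns):
        residues = [r[c] for r in msa.rows if r[c] not in (GAP, "X")]
        if not residues:
            freqs.append(None)
            info.append(math.nan)
            continue
        total = len(residues)
        counts: dict[str, int] = {}
        for res in residues:
            counts[res] = counts.get(res, 0) + 1
        f = {res: k / total for res, k in counts.items()}
        H = -sum(p * math.log2(p) for p in f.values())
        freqs.append(f)
        info.append(max(0.0, max_bits - H))
    return LogoMatrix(freqs, info)


def write_newick(tree: Tree) -> str:
    """Serialize with branch lengths; integer bootstrap supports become
    internal node labels. Re-parsing reproduces the topology."""
    if tree.root.is_leaf() and tree.root.name is None:
        raise ValueError("empty tree")

    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return f"{node.name}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else str(int(round(node.support)))
        return f"({inner}){label}:{node.length:.6g}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    return f"({inner});"


def extract_consensus_region(protein: ProteinRecord, motif: MotifSpec,
                             flank: int = 10) -> str:
    """The best-scoring consensus window plus `flank` residues each side."""
    _, offset = best_consensus_score(protein, motif)
    if offset is None:
        return protein.sequence
    width = sum(e[1] if e[0] == "gap" else 1 for e in motif.elements)
    lo = max(0, offset - flank)
    hi = min(len(protein.sequence), offset + width + flank)
    return protein.sequence[lo:hi]


def star_align(records: list[ProteinRecord], config: RunConfig = _DEFAULT) -> Msa:
    """Center-star progressive alignment (approximate; logged as such).

    The longest sequence (ties: smallest id) is the center; every other
    sequence is globally aligned to it and the pairwise alignments are
    merged on center coordinates. Adequate for desk-scale trees; an
    externally built alignment can be supplied instead wherever an Msa is
    accepted.
    """
    if not records:
        raise ValueError("no sequences to align")
    if len(records) == 1:
        return Msa([records[0].id], [records[0].sequence])
    logger.info("star_align: approximate center-star alignment of %d sequences",
                len(records))
    center = min(records, key=lambda r: (-len(r.sequence), r.id))
    others = [r for r in records if r.id != center.id]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    from Bio.Align import substitution_matrices
    aligner.substitution_matrix = substitution_matrices.load(config.substitution_matrix)
    aligner.open_gap_score = -abs(config.gap_open)
    aligner.extend_gap_score = -abs(config.gap_extend)

    L = len(center.sequence)
    # insertions[i] = residues of each sequence falling before center position i
    pairwise: list[tuple[str, list[list[str]]]] = []
    max_ins = [0] * (L + 1)
    for rec in others:
        aln = aligner.align(center.sequence, rec.sequence)[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        slots: list[list[str]] = [[] for _ in range(L + 1)]
        cpos = 0
        aligned_to: list[str] = [GAP] * L
        for cc, sc in zip(c_row, s_row):
            if cc == GAP:
                slots[cpos].append(sc)
            else:
                aligned_to[cpos] = sc
                cpos += 1
        pairwise.append((rec.id, [slots, aligned_to]))
        for i in range(L + 1):
            max_ins[i] = max(max_ins[i], len(slots[i]))

    ids = [center.id]
    rows = []
    center_row = []
    for i in range(L):
        center_row.append(GAP * max_ins[i] + center.sequence[i])
    center_row.append(GAP * max_ins[L])
    rows.append("".join(center_row))
    for rid, (slots, aligned_to) in pairwise:
        row = []
        for i in range(L):
            ins = "".join(slots[i])
            row.append(ins + GAP * (max_ins[i] - len(ins)) + aligned_to[i])
        ins = "".join(slots[L])
        row.append(ins + GAP * (max_ins[L] - len(ins)))
        ids.append(rid)
        rows.append("".join(row))
    return Msa(ids, rows)
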