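"""Generators for proteomes, layouts, alignments and FPKM tables with truth.

Every stage of the pipeline is exercisable without downloads: proteins are
built by planting the family-defining diagnostics (R&R consensus with
randomized wildcard positions, one vs three ChtBD2 cysteine spacings,
ordered Tweedle blocks, C-x(5)-C repeats, PV/PY-dense proline runs, GGxGG
repeats in glycine-rich background, AAP[AVL] repeats, or mutated copies of
reference-catalog members for the homology-called families) into random
flanks, and every generated gene carries its planted truth label. Decoys
are rejection-sampled until the classifier calls them not-CP, so false
positives measured on them are real classifier behaviour, not generator
leakage. Planted proteins are verified to classify correctly *before*
mutation; the mutated copies are what the recovery experiments see.

All generators are byte-reproducible given (spec, seed). The reference
catalog produced here is a synthetic stand-in for a curated catalog of
verified cuticular proteins; its entries are labelled "Ref*" and carry no
real sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cuticula.config import RunConfig
from cuticula.cp_classifier import classify_protein
from cuticula.expression_profile import BIN_EDGES, EXPRESSION_BINS, ExpressionMatrix
from cuticula.motif_engine import DEFAULT_MOTIFS, MotifSpec
from cuticula.phylogeny_logo import Msa
from cuticula.sequence_io import (
    AMINO_ACIDS,
    GeneLocus,
    ProteinRecord,
    ReferenceCatalog,
    ReferenceEntry,
)

_DEFAULT = RunConfig()

#: Planted groups of the default synthetic proteome: five genes in each of
#: twelve family/subfamily groups (sixty planted CPs).
DEFAULT_PROTEOME_SPEC: dict[str, int] = {
    "RR-1": 5, "RR-2": 5, "RR-3": 5, "CPAP1": 5, "CPAP3": 5, "CPT": 5,
    "CPCFC": 5, "CPLCP": 5, "CPG": 5, "CPH": 5, "CPF": 5, "CPFL": 5,
}

_MAX_RETRIES = 60


def _random_seq(rng: np.random.Generator, length: int,
                weights: np.ndarray | None = None) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=weights)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < rate:
            alternatives = [a for a in AMINO_ACIDS if a != c]
            chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _instantiate(rng: np.random.Generator, motif: MotifSpec) -> str:
    """A concrete sequence matching `motif` exactly (wildcards randomized)."""
    parts: list[str] = []
    for el in motif.elements:
        if el[0] == "res":
            parts.append(el[1])
        elif el[0] == "alt":
            options = sorted(el[1])
            parts.append(options[rng.integers(len(options))])
        else:
            width = int(rng.integers(el[1], el[2] + 1))
            parts.append(_random_seq(rng, width))
    return "".join(parts)


def make_reference_catalog(seed: int = 0) -> ReferenceCatalog:
    """A synthetic reference catalog (stand-in for a curated CP catalog).

    Carries labelled exemplars for every family the classifier needs:
    consensus-bearing RR-1/RR-2 entries, RR-3 exemplars, and random
    full-length entries for the homology-called families.
    """
    rng = np.random.default_rng(seed)
    entries: list[ReferenceEntry] = []

    def add(fam: str, sub: str | None, name: str, seq: str):
        entries.append(ReferenceEntry(
            ProteinRecord(f"REF_{name}", seq, "synthetic reference"), fam, sub, name))

    for i in range(2):
        seq = (_random_seq(rng, 30)
               + _instantiate(rng, DEFAULT_MOTIFS["rr1_consensus"])
               + _random_seq(rng, 30))
        add("CPR", "RR-1", f"RefCPR{i + 1}", seq)
    for i in range(2):
        seq = (_random_seq(rng, 30)
               + _instantiate(rng, DEFAULT_MOTIFS["rr2_consensus"])
               + _random_seq(rng, 30))
        add("CPR", "RR-2", f"RefCPR{i + 3}", seq)
    for i in range(2):
        add("CPR", "RR-3", f"RefCPR{i + 5}", _random_seq(rng, 140))
    add("CPF", None, "RefCPF", _random_seq(rng, 160))
    for i in range(2):
        add("CPFL", None, f"RefCPFL{i + 1}", _random_seq(rng, 150))
    add("18aa", None, "Ref18aa1", _random_seq(rng, 130))
    add("CPLCA", None, "RefCPLCA1", _random_seq(rng, 130))
    glycine_weights = _biased_weights("G", 0.35)
    for i in range(2):
        add("CPG", None, f"RefCPG{i + 1}", _random_seq(rng, 140, glycine_weights))
    for i in range(2):
        add("CPH", None, f"RefCPH{i + 1}", _random_seq(rng, 140))
    return ReferenceCatalog(entries)


def _biased_weights(residue: str, fraction: float) -> np.ndarray:
    weights = np.full(len(AMINO_ACIDS), (1.0 - fraction) / (len(AMINO_ACIDS) - 1))
    weights[AMINO_ACIDS.index(residue)] = fraction
    return weights


def _plant(rng: np.random.Generator, group: str,
           reference: ReferenceCatalog) -> str:
    """Unmutated planted sequence for one family/subfamily group."""
    flank = lambda n: _random_seq(rng, n)
    if group == "RR-1":
        return (flank(30) + _instantiate(rng, DEFAULT_MOTIFS["rr1_consensus"])
                + flank(40))
    if group == "RR-2":
        return (flank(30) + _instantiate(rng, DEFAULT_MOTIFS["rr2_consensus"])
                + flank(40))
    if group == "RR-3":
        exemplars = reference.by_subfamily("RR-3")
        pick = exemplars[rng.integers(len(exemplars))]
        return _mutate(rng, pick.record.sequence, 0.08)
    if group == "CPAP1":
        return (flank(25) + _instantiate(rng, DEFAULT_MOTIFS["cpap1_spacing"])
                + flank(35))
    if group == "CPAP3":
        domains = [_instantiate(rng, DEFAULT_MOTIFS["cpap3_spacing"])
                   for _ in range(3)]
        linker = lambda: _random_seq(rng, 10)
        return (flank(15) + domains[0] + linker() + domains[1] + linker()
                + domains[2] + flank(15))
    if group == "CPT":
        blocks = [_instantiate(rng, DEFAULT_MOTIFS[f"tweedle_block_{i}"])
                  for i in (1, 2, 3, 4)]
        out = flank(15)
        for b in blocks:
            out += b + _random_seq(rng, 12)
        return out + flank(10)
    if group == "CPCFC":
        unit = lambda: _instantiate(rng, DEFAULT_MOTIFS["cpcfc_repeat"])
        return flank(25) + unit() + flank(12) + unit() + flank(12) + unit() + flank(20)
    if group == "CPLCP":
        parts = [flank(10)]
        for _ in range(16):
            parts.append("PV" if rng.random() < 0.5 else "PY")
            parts.append("P" + _random_seq(rng, 2))
        parts.append(flank(10))
        return "".join(parts)
    if group == "CPG":
        gly = _biased_weights("G", 0.30)
        parts = [_random_seq(rng, 20, gly)]
        for _ in range(4):
            parts.append("GG" + AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] + "GG")
            parts.append(_random_seq(rng, 12, gly))
        return "".join(parts)
    if group == "CPH":
        parts = [flank(20)]
        for _ in range(5):
            parts.append("AAP" + "AVL"[rng.integers(3)])
            parts.append(_random_seq(rng, 8))
        parts.append(flank(15))
        return "".join(parts)
    if group in ("CPF", "CPFL", "18aa", "CPLCA"):
        members = reference.by_family(group)
        pick = members[rng.integers(len(members))]
        return _mutate(rng, pick.record.sequence, 0.10)
    raise ValueError(f"unknown planted group {group!r}")


def _truth_family(group: str) -> tuple[str, str | None]:
    if group in ("RR-1", "RR-2", "RR-3"):
        return "CPR", group
    return group, None


def make_proteome(n_per_family: dict[str, int] | None = None,
                  mutation_rate: float = 0.02, seed: int = 7,
                  n_decoys: int = 10,
                  reference: ReferenceCatalog | None = None,
                  config: RunConfig = _DEFAULT
                  ) -> tuple[list[ProteinRecord], ReferenceCatalog, pd.DataFrame]:
    """Generate a proteome of planted CPs plus motif-free decoys.

    Returns (records, reference catalog, truth table). Each planted
    protein is verified to classify as its planted group before mutation
    (resampled otherwise); decoys are rejection-sampled until the
    classifier calls them not-CP. Truth columns: gene_id, family,
    subfamily, group, ortholog, seed.
    """
    if not (0.0 <= mutation_rate <= 1.0):
        raise ValueError("mutation_rate must lie in [0, 1]")
    if n_per_family is None:
        n_per_family = dict(DEFAULT_PROTEOME_SPEC)
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = make_reference_catalog(seed=seed + 1)

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    index = 0
    for group in sorted(n_per_family):
        fam, sub = _truth_family(group)
        for _ in range(n_per_family[group]):
            index += 1
            gene_id = f"SYN{index:03d}"
            for attempt in range(_MAX_RETRIES):
                seq = _plant(rng, group, reference)
                call = classify_protein(ProteinRecord(gene_id, seq), reference, config)
                if call.family == fam and call.subfamily == sub:
                    break
            else:
                raise RuntimeError(
                    f"could not generate a valid {group} protein in "
                    f"{_MAX_RETRIES} attempts; lower the composition bias")
            seq = _mutate(rng, seq, mutation_rate)
            records.append(ProteinRecord(gene_id, seq, f"synthetic {group}"))
            truth_rows.append({
                "gene_id": gene_id, "family": fam, "subfamily": sub or "",
                "group": group, "seed": seed,
            })
    for _ in range(n_decoys):
        index += 1
        gene_id = f"SYN{index:03d}"
        for attempt in range(_MAX_RETRIES):
            seq = _random_seq(rng, int(rng.integers(90, 160)))
            call = classify_protein(ProteinRecord(gene_id, seq), reference, config)
            if call.family == "not-CP":
                break
        else:
            raise RuntimeError(
                f"could not generate a decoy in {_MAX_RETRIES} attempts; "
                f"lower the composition bias")
        records.append(ProteinRecord(gene_id, seq, "synthetic decoy"))
        truth_rows.append({
            "gene_id": gene_id, "family": "not-CP", "subfamily": "",
            "group": "decoy", "seed": seed,
        })
    return records, reference, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class ArraySpec:
    """One requested tandem array: family/subfamily, size, placement."""

    family: str  # "RR-1"/"RR-2"/... group name, as in make_proteome
    size: int
    chromosome: str
    spacing_kb: float
    members: tuple[str, ...] | None = None  # explicit gene ids, optional


def make_layout(arrays_spec: list[ArraySpec], seed: int = 0,
                n_decoys_per_chromosome: int = 2,
                gene_length: int = 2000
                ) -> tuple[list[GeneLocus], pd.DataFrame]:
    """Place requested tandem arrays on chromosomes, decoys between them.

    Consecutive array members are `spacing_kb` apart start-to-start;
    separate arrays on one chromosome are placed >1 Mb apart so they never
    merge under default detection settings. RR-1 and RR-2 arrays are never
    co-planted in one array by construction of the spec type (one group
    per array). Truth columns: gene_id, chromosome, start, array_id, group.
    """
    for spec in arrays_spec:
        if spec.size < 1:
            raise ValueError("array size must be >= 1")
        if spec.members is not None and len(spec.members) != spec.size:
            raise ValueError("explicit member list must match array size")
        if spec.spacing_kb * 1000 < gene_length:
            raise ValueError(
                f"spacing {spec.spacing_kb} kb < gene length {gene_length} bp: "
                f"placements would overlap")
    rng = np.random.default_rng(seed)
    loci: list[GeneLocus] = []
    truth_rows: list[dict] = []
    cursors: dict[str, int] = {}
    auto = 0
    for array_id, spec in enumerate(arrays_spec, start=1):
        start = cursors.get(spec.chromosome, 100_000)
        for k in range(spec.size):
            if spec.members is not None:
                gene_id = spec.members[k]
            else:
                auto += 1
                gene_id = f"LOC{auto:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(GeneLocus(gene_id, spec.chromosome, start,
                                  start + gene_length - 1, strand))
            truth_rows.append({
                "gene_id": gene_id, "chromosome": spec.chromosome,
                "start": start, "array_id": array_id, "group": spec.family,
            })
            start += int(spec.spacing_kb * 1000)
        cursors[spec.chromosome] = start + 1_000_000
    for chrom in sorted(cursors):
        start = cursors[chrom]
        for _ in range(n_decoys_per_chromosome):
            auto += 1
            gene_id = f"DEC{auto:03d}"
            loci.append(GeneLocus(gene_id, chrom, start, start + gene_length - 1))
            truth_rows.append({
                "gene_id": gene_id, "chromosome": chrom, "start": start,
                "array_id": 0, "group": "decoy",
            })
            start += 500_000
    return loci, pd.DataFrame(truth_rows)


def make_expression(genes: list[str], tissues: list[str],
                    bin_targets: pd.DataFrame | None = None,
                    seed: int = 0) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """FPKM table drawn log-uniformly within per-gene per-tissue target bins.

    `bin_targets` is a gene x tissue frame of bin names; when omitted,
    bins are drawn uniformly from the six categories. The lowest bin
    [0, 1) is sampled log-uniformly on [0.01, 1) (log of 0 is undefined);
    the top bin is capped at 1e5. Binning the generated table reproduces
    the targets exactly. Returns (matrix, truth frame of bins).
    """
    rng = np.random.default_rng(seed)
    if bin_targets is None:
        choices = rng.integers(0, len(EXPRESSION_BINS),
                               size=(len(genes), len(tissues)))
        bin_targets = pd.DataFrame(
            [[EXPRESSION_BINS[c] for c in row] for row in choices],
            index=genes, columns=tissues)
    lows = {EXPRESSION_BINS[0]: 0.01}
    highs = {EXPRESSION_BINS[-1]: 1e5}
    values = pd.DataFrame(0.0, index=genes, columns=tissues)
    for g in genes:
        for t in tissues:
            b = bin_targets.at[g, t]
            i = EXPRESSION_BINS.index(b)
            lo = lows[b] if b in lows else BIN_EDGES[i]
            hi = highs[b] if b in highs else BIN_EDGES[i + 1]
            u = rng.uniform(math.log10(lo), math.log10(hi))
            values.at[g, t] = 10.0 ** u
    return ExpressionMatrix(values), bin_targets.copy()


def make_clade_msa(n_clades: int, per_clade: int, within_divergence: float,
                   between_divergence: float, length: int = 200,
                   seed: int = 0) -> tuple[Msa, pd.DataFrame]:
    """Alignment of `n_clades` planted clades with known memberships.

    A random root is mutated at `between_divergence` to give each clade's
    ancestor; leaves are the ancestor mutated at `within_divergence`.
    Requires within < between for recoverable clades (within == between is
    the documented negative control). Truth columns: leaf_id, clade.
    """
    if not (0.0 <= within_divergence <= between_divergence <= 1.0):
        raise ValueError("need 0 <= within <= between <= 1")
    rng = np.random.default_rng(seed)
    root = _random_seq(rng, length)
    ids, rows, truth = [], [], []
    for c in range(n_clades):
        ancestor = _mutate(rng, root, between_divergence)
        for k in range(per_clade):
            leaf_id = f"clade{c + 1}_leaf{k + 1}"
            ids.append(leaf_id)
            rows.append(_mutate(rng, ancestor, within_divergence))
            truth.append({"leaf_id": leaf_id, "clade": c + 1})
    return Msa(ids, rows), pd.DataFrame(truth)
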