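"""Core record types and readers for the standard formats the pipeline touches.

Proteomes arrive as FASTA (one predicted protein per gene model), gene
coordinates as GFF3, and the reference cuticular-protein catalog as a FASTA
plus a label TSV. Coordinates follow the GFF3 convention throughout:
1-based, fully closed intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils.iterators

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus X (unknown residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Closed vocabulary of cuticular-protein family labels.
FAMILIES = (
    "CPR", "CPAP1", "CPAP3", "CPF", "CPFL", "CPT",
    "CPCFC", "CPLCP", "CPLCA", "CPG", "CPH", "18aa",
)

#: CPR subfamilies: soft-cuticle RR-1, hard-cuticle RR-2, RR-3, and
#: RR-NC ("not classified") for consensus-bearing proteins that cannot be
#: confidently placed in RR-1/RR-2/RR-3.
CPR_SUBFAMILIES = ("RR-1", "RR-2", "RR-3", "RR-NC")


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: unique accession, uppercase amino-acid sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"{self.id}: sequence must have length >= 1")
        bad = set(seq) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: disallowed residue(s) {sorted(bad)}; "
                f"allowed are the 20 amino acids plus X"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """Gene coordinates: 1-based closed interval on a named chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1 (1-based)")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.gene_id}: strand must be one of + - .")


@dataclass(frozen=True)
class ReferenceEntry:
    """A verified reference CP: sequence, family label, optional subfamily, name."""

    record: ProteinRecord
    family: str
    subfamily: str | None
    name: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"{self.record.id}: unknown family {self.family!r}; "
                f"permitted labels: {', '.join(FAMILIES)}"
            )
        if self.subfamily is not None:
            if self.family != "CPR":
                raise ValueError(
                    f"{self.record.id}: subfamily only allowed for CPR, "
                    f"got family {self.family!r}"
                )
            if self.subfamily not in CPR_SUBFAMILIES:
                raise ValueError(
                    f"{self.record.id}: unknown CPR subfamily {self.subfamily!r}; "
                    f"permitted: {', '.join(CPR_SUBFAMILIES)}"
                )


@dataclass
class ReferenceCatalog:
    """The verified reference CP set used for homology calls and naming."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_family(self, *families: str) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.family in families]

    def by_subfamily(self, subfamily: str) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.subfamily == subfamily]


def _normalize_sequence(raw: str, rec_id: str) -> str:
    seq = str(raw).upper().rstrip("*")
    if "*" in seq:
        raise ValueError(
            f"{rec_id}: internal stop codon '*' — broken gene model; "
            f"only trailing stops are stripped"
        )
    return seq


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects, order preserved.

    Sequences are uppercased and trailing stop symbols (``*``) stripped.
    Duplicate ids are a hard error; an empty file yields an empty list with
    a logged warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(rec.id, _normalize_sequence(rec.seq, rec.id), desc))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write :class:`ProteinRecord` objects as FASTA (wrap at `width` columns)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_gff3(path) -> list[GeneLocus]:
    """Read gene features from a GFF3 file as 1-based closed :class:`GeneLocus`.

    Only features of type ``gene`` are returned; each must carry an ``ID``
    attribute. Coordinates are preserved as written.
    """
    loci: list[GeneLocus] = []
    for i, feat in enumerate(gffutils.iterators.DataIterator(str(path)), start=1):
        if feat.featuretype != "gene":
            continue
        ids = feat.attributes.get("ID", [])
        if not ids:
            raise ValueError(f"{path}: gene feature #{i} has no ID attribute")
        if feat.end < feat.start:
            raise ValueError(
                f"{path}: gene {ids[0]}: start {feat.start} > end {feat.end}"
            )
        strand = feat.strand if feat.strand in {"+", "-"} else "."
        loci.append(GeneLocus(ids[0], feat.seqid, feat.start, feat.end, strand))
    return loci


def write_gff3(loci, path) -> None:
    """Write loci as a minimal GFF3 of gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                f"{loc.chromosome}\tcuticula\tgene\t{loc.start}\t{loc.end}"
                f"\t.\t{loc.strand}\t.\tID={loc.gene_id}\n"
            )


def read_reference_catalog(fasta_path, labels_path) -> ReferenceCatalog:
    """Load a reference catalog from a FASTA and a label TSV.

    The TSV needs a header row with columns ``id``, ``family``, ``subfamily``
    and ``name``; ``subfamily`` may be empty (and must be, except for CPR).
    Every labelled id must be present in the FASTA.
    """
    records = {r.id: r for r in read_fasta(fasta_path)}
    entries: list[ReferenceEntry] = []
    with open(labels_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"id", "family", "subfamily", "name"}
        if not required.issubset(header):
            raise ValueError(
                f"{labels_path}: header must contain columns {sorted(required)}"
            )
        col = {name: header.index(name) for name in header}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rid = parts[col["id"]]
            if rid not in records:
                raise ValueError(f"{labels_path}: id {rid} absent from {fasta_path}")
            sub = parts[col["subfamily"]] or None
            entries.append(
                ReferenceEntry(records[rid], parts[col["family"]], sub, parts[col["name"]])
            )
    return ReferenceCatalog(entries)
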