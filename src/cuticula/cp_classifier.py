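"""Family assignment cascade for cuticular proteins.

Each protein is tested against the family diagnostics in a fixed order and
receives exactly one verdict (a :class:`FamilyCall`), with the evidence
that produced it. The cascade:

1. CPAP — one ChtBD2 cysteine-spacing motif is CPAP1, three or more is
   CPAP3. Checked first: a ChtBD2-bearing protein belongs to the CPAP
   superfamily even if it also carries weak R&R-like signal.
2. CPR — scored against the extended R&R consensus strings for RR-1 and
   RR-2; the stronger consensus wins the subfamily, near-ties fall to
   RR-NC ("CPR not classified"), and strong identity to a reference RR-3
   exemplar overrides the consensus evidence.
3. CPT (Tweedle) — at least `tweedle_min_blocks` of the four Tweedle
   blocks present in order I < II < III < IV.
4. Low-complexity families, first rule wins: CPCFC (>= 2 C-x(5)-C
   repeats); CPF/CPFL/18aa/CPLCA by reference identity; CPLCP (PV+PY
   dipeptide density with proline-rich composition); CPG (glycine-rich
   with GGxGG repeats); CPH (identity to CPG/CPH references or AAP[AVL]
   repeats).
5. Anything else is not-CP.

Every threshold lives in :class:`cuticula.config.RunConfig`; manual
curation (e.g. reassignment of a single gene on synteny evidence) enters
through an explicit override table, never through code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from cuticula.config import RunConfig
from cuticula.homology import global_identity
from cuticula.motif_engine import (
    DEFAULT_MOTIFS,
    MotifSpec,
    best_consensus_score,
    composition,
    count_dipeptide,
    count_nonoverlapping,
    scan,
)
from cuticula.sequence_io import ProteinRecord, ReferenceCatalog

logger = logging.getLogger(__name__)

_DEFAULT = RunConfig()


@dataclass
class FamilyCall:
    """The classifier's verdict for one protein, with its evidence trail."""

    protein_id: str
    family: str  # a catalog family label or "not-CP"
    subfamily: Optional[str] = None
    evidence: list[tuple[str, object]] = field(default_factory=list)
    assigned_name: Optional[str] = None
    override: bool = False

    def __post_init__(self):
        if (self.subfamily is not None) != (self.family == "CPR"):
            raise ValueError(
                f"{self.protein_id}: subfamily present iff family is CPR "
                f"(family={self.family}, subfamily={self.subfamily})")
        if self.family != "not-CP" and not self.evidence:
            raise ValueError(f"{self.protein_id}: family call requires evidence")


def classify_cpr(protein: ProteinRecord,
                 rr1_motif: MotifSpec = None,
                 rr2_motif: MotifSpec = None,
                 reference: ReferenceCatalog | None = None,
                 config: RunConfig = _DEFAULT) -> Optional[FamilyCall]:
    """CPR call from R&R consensus scores and RR-3 exemplar identity."""
    rr1_motif = rr1_motif or DEFAULT_MOTIFS["rr1_consensus"]
    rr2_motif = rr2_motif or DEFAULT_MOTIFS["rr2_consensus"]
    s1, _ = best_consensus_score(protein, rr1_motif)
    s2, _ = best_consensus_score(protein, rr2_motif)

    rr3_best, rr3_ref = 0.0, None
    if reference is not None:
        for entry in reference.by_subfamily("RR-3"):
            ident = global_identity(protein, entry.record, config).identity
            if ident > rr3_best:
                rr3_best, rr3_ref = ident, entry.name

    consensus_best = max(s1, s2)
    if rr3_best >= config.rr3_identity_min and rr3_best > consensus_best:
        return FamilyCall(protein.id, "CPR", "RR-3",
                          [("rr3_identity", (rr3_ref, round(rr3_best, 4)))])
    if consensus_best < config.cpr_score_min:
        return None
    evidence = [("rr1_score", round(s1, 4)), ("rr2_score", round(s2, 4))]
    if abs(s1 - s2) < config.cpr_tie_margin:
        sub = "RR-NC"
    else:
        sub = "RR-1" if s1 > s2 else "RR-2"
    return FamilyCall(protein.id, "CPR", sub, evidence)


def classify_cpap(protein: ProteinRecord,
                  cpap1_spacing: MotifSpec = None,
                  cpap3_spacing: MotifSpec = None,
                  config: RunConfig = _DEFAULT) -> Optional[FamilyCall]:
    """CPAP3 on >= 3 non-overlapping ChtBD2 spacings, else CPAP1 on >= 1."""
    cpap1_spacing = cpap1_spacing or DEFAULT_MOTIFS["cpap1_spacing"]
    cpap3_spacing = cpap3_spacing or DEFAULT_MOTIFS["cpap3_spacing"]
    n3 = count_nonoverlapping(protein, cpap3_spacing)
    if n3 >= config.cpap3_min_domains:
        return FamilyCall(protein.id, "CPAP3", None, [("chtbd2_domains", n3)])
    n1 = count_nonoverlapping(protein, cpap1_spacing)
    if n1 >= config.cpap1_min_domains:
        return FamilyCall(protein.id, "CPAP1", None, [("chtbd2_domains", n1)])
    return None


def classify_tweedle(protein: ProteinRecord,
                     blocks: list[MotifSpec] | None = None,
                     config: RunConfig = _DEFAULT) -> Optional[FamilyCall]:
    """CPT when enough Tweedle blocks hit in order I < II < III < IV."""
    if blocks is None:
        blocks = [DEFAULT_MOTIFS[f"tweedle_block_{i}"] for i in (1, 2, 3, 4)]
    cursor = 0
    found: list[tuple[str, int]] = []
    for block in blocks:
        hit_pos = None
        for hit in scan(protein, block):
            if hit.start >= cursor:
                hit_pos = hit.start
                cursor = hit.end
                break
        if hit_pos is not None:
            found.append((block.name, hit_pos))
    if len(found) >= config.tweedle_min_blocks:
        return FamilyCall(protein.id, "CPT", None, [("tweedle_blocks", found)])
    return None


def classify_low_complexity(protein: ProteinRecord,
                            reference: ReferenceCatalog,
                            config: RunConfig = _DEFAULT) -> Optional[FamilyCall]:
    """Ordered low-complexity rules: CPCFC, homology families, CPLCP, CPG, CPH."""
    n_cfc = count_nonoverlapping(protein, DEFAULT_MOTIFS["cpcfc_repeat"])
    if n_cfc >= config.cpcfc_min_repeats:
        return FamilyCall(protein.id, "CPCFC", None, [("cx5c_repeats", n_cfc)])

    best_fam, best_ident, best_name = None, 0.0, None
    for entry in reference.by_family("CPF", "CPFL", "18aa", "CPLCA"):
        ident = global_identity(protein, entry.record, config).identity
        if ident > best_ident:
            best_fam, best_ident, best_name = entry.family, ident, entry.name
    if best_fam is not None and best_ident >= config.family_identity_min:
        return FamilyCall(protein.id, best_fam, None,
                          [("reference_identity", (best_name, round(best_ident, 4)))])

    comp = composition(protein)
    n_pv = count_dipeptide(protein, "PV")
    n_py = count_dipeptide(protein, "PY")
    if (n_pv + n_py >= config.cplcp_dipeptide_min
            and comp.get("P", 0.0) >= config.cplcp_proline_min):
        return FamilyCall(protein.id, "CPLCP", None,
                          [("pv_py_dipeptides", (n_pv, n_py)),
                           ("proline_fraction", round(comp.get("P", 0.0), 4))])

    n_gg = count_nonoverlapping(protein, DEFAULT_MOTIFS["cpg_repeat"])
    if comp.get("G", 0.0) >= config.glycine_rich_min and n_gg >= config.cpg_min_repeats:
        return FamilyCall(protein.id, "CPG", None,
                          [("glycine_fraction", round(comp.get("G", 0.0), 4)),
                           ("ggxgg_repeats", n_gg)])

    cph_best, cph_name = 0.0, None
    for entry in reference.by_family("CPG", "CPH"):
        ident = global_identity(protein, entry.record, config).identity
        if ident > cph_best:
            cph_best, cph_name = ident, entry.name
    n_aap = count_nonoverlapping(protein, DEFAULT_MOTIFS["cph_repeat"])
    if cph_best >= config.cph_identity_min:
        return FamilyCall(protein.id, "CPH", None,
                          [("reference_identity", (cph_name, round(cph_best, 4)))])
    if n_aap >= config.cph_min_repeats:
        return FamilyCall(protein.id, "CPH", None, [("aap_repeats", n_aap)])
    return None


def classify_protein(protein: ProteinRecord, reference: ReferenceCatalog,
                     config: RunConfig = _DEFAULT) -> FamilyCall:
    """Run the full cascade on one protein; always returns a verdict."""
    for rule in (
        lambda: classify_cpap(protein, config=config),
        lambda: classify_cpr(protein, reference=reference, config=config),
        lambda: classify_tweedle(protein, config=config),
        lambda: classify_low_complexity(protein, reference, config=config),
    ):
        call = rule()
        if call is not None:
            return call
    return FamilyCall(protein.id, "not-CP")


def classify_all(proteome: list[ProteinRecord], reference: ReferenceCatalog,
                 config: RunConfig = _DEFAULT) -> list[FamilyCall]:
    """Classify every protein; deterministic for a fixed config.

    One call per input record, input order preserved; per-family summary
    counts are logged.
    """
    calls = [classify_protein(p, reference, config) for p in proteome]
    counts: dict[str, int] = {}
    for call in calls:
        key = call.family if call.subfamily is None else f"CPR/{call.subfamily}"
        counts[key] = counts.get(key, 0) + 1
    logger.info("classification summary: %s",
                ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    return calls


def apply_overrides(calls: list[FamilyCall], overrides_path) -> list[FamilyCall]:
    """Apply a manual-curation TSV (id, family, subfamily) after classification.

    Manual reassignments (synteny- or curation-based) must be explicit
    input; each applied override is logged and flagged on the call.
    """
    table: dict[str, tuple[str, Optional[str]]] = {}
    with open(overrides_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: header.index(name) for name in header}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            table[parts[col["id"]]] = (
                parts[col["family"]],
                parts[col["subfamily"]] or None if "subfamily" in col else None,
            )
    out = []
    for call in calls:
        if call.protein_id in table:
            fam, sub = table[call.protein_id]
            logger.info("override: %s %s/%s -> %s/%s", call.protein_id,
                        call.family, call.subfamily, fam, sub)
            out.append(FamilyCall(call.protein_id, fam, sub,
                                  call.evidence + [("manual_override", (fam, sub))],
                                  call.assigned_name, override=True))
        else:
            out.append(call)
    return out


def assign_names(calls: list[FamilyCall], reference: ReferenceCatalog,
                 orthology, loci=None,
                 config: RunConfig = _DEFAULT) -> list[FamilyCall]:
    """Name proteins: 1:1 orthologs inherit the reference name stem, the
    rest are numbered per family in genomic annotation order.

    A 1:1 RBH partner's reference name has its species prefix (anything
    before the family stem, e.g. "Bmor") replaced by `config.name_prefix`.
    Remaining CPs get "<prefix><family><k>" with k increasing along the
    genome (or input order when no loci are given). Names must be unique.
    """
    ref_names = {e.record.id: e.name for e in reference}
    one_to_one = orthology.one_to_one() if orthology is not None else {}
    locus_order: dict[str, tuple] = {}
    if loci:
        for loc in loci:
            locus_order[loc.gene_id] = (loc.chromosome, loc.start, loc.gene_id)

    def order_key(call: FamilyCall):
        return locus_order.get(call.protein_id,
                               ("~", 0, call.protein_id))

    used: dict[str, str] = {}
    named: dict[str, str] = {}
    for call in calls:
        if call.family == "not-CP":
            continue
        partner = one_to_one.get(call.protein_id)
        if partner is not None and partner in ref_names:
            stem = _strip_species_prefix(ref_names[partner])
            name = f"{config.name_prefix}{stem}"
            if name in used:
                raise ValueError(
                    f"name collision: {name} assigned to both {used[name]} "
                    f"and {call.protein_id} (duplicated ortholog assignment)")
            used[name] = call.protein_id
            named[call.protein_id] = name

    counters: dict[str, int] = {}
    for call in sorted((c for c in calls if c.family != "not-CP"), key=order_key):
        if call.protein_id in named:
            continue
        fam_stem = call.family if call.family != "CPR" else "CPR"
        k = counters.get(fam_stem, 0) + 1
        name = f"{config.name_prefix}{fam_stem}{k}"
        while name in used:
            k += 1
            name = f"{config.name_prefix}{fam_stem}{k}"
        counters[fam_stem] = k
        used[name] = call.protein_id
        named[call.protein_id] = name

    out = []
    for call in calls:
        name = named.get(call.protein_id)
        out.append(FamilyCall(call.protein_id, call.family, call.subfamily,
                              list(call.evidence), name, call.override))
    return out


def _strip_species_prefix(ref_name: str) -> str:
    """Drop a leading species tag (e.g. 'BmorCPG24' -> 'CPG24')."""
    for stem in ("CPAP3", "CPAP1", "CPCFC", "CPLCP", "CPLCA", "CPFL",
                 "CPF", "CPT", "CPG", "CPH", "CPR", "18aa"):
        idx = ref_name.find(stem)
        if idx >= 0:
            return ref_name[idx:]
    return ref_name


def write_calls_tsv(calls: list[FamilyCall], path, config: RunConfig = _DEFAULT) -> None:
    with open(path, "w") as fh:
        fh.write(f"# expressed/classification thresholds: cpr_score_min="
                 f"{config.cpr_score_min} cpr_tie_margin={config.cpr_tie_margin} "
                 f"family_identity_min={config.family_identity_min} "
                 f"cph_identity_min={config.cph_identity_min}\n")
        fh.write("id\tfamily\tsubfamily\tname\tevidence\toverride\n")
        for call in calls:
            ev = ";".join(f"{k}={v}" for k, v in call.evidence)
            fh.write(f"{call.protein_id}\t{call.family}\t{call.subfamily or ''}"
                     f"\t{call.assigned_name or ''}\t{ev}\t"
                     f"{'yes' if call.override else 'no'}\n")
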