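"""Run configuration: every tunable threshold of the pipeline in one place.

The family rules are qualitative in the literature ("glycine-rich", "high
density of PV and PY", "sequence similarity to known members"); every number
that operationalises such a rule lives here with its default, is serialized
into every output directory, and is printed in report headers, so a run is
always reproducible from its own artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    # --- CPR (R&R consensus) detection ---------------------------------
    #: minimal fraction of consensus fixed positions matched to call CPR
    cpr_score_min: float = 0.5
    #: if RR-1 and RR-2 scores both pass and differ by less than this
    #: margin, the protein is called RR-NC (CPR not classified)
    cpr_tie_margin: float = 0.05
    #: identity to a reference RR-3 exemplar required for an RR-3 call
    rr3_identity_min: float = 0.50

    # --- CPAP (ChtBD2 cysteine spacing) --------------------------------
    cpap3_min_domains: int = 3
    cpap1_min_domains: int = 1

    # --- Tweedle --------------------------------------------------------
    #: number of the four Tweedle blocks that must hit, in order
    tweedle_min_blocks: int = 3

    # --- low-complexity families ---------------------------------------
    cpcfc_min_repeats: int = 2
    #: identity threshold for homology-called families (CPF/CPFL/18aa/CPLCA)
    family_identity_min: float = 0.40
    cplcp_dipeptide_min: int = 10
    cplcp_proline_min: float = 0.10
    glycine_rich_min: float = 0.20
    cpg_min_repeats: int = 2
    #: identity floor to CPG/CPH references for a CPH call (the weakest
    #: published identity to a reference in this family class is 36%)
    cph_identity_min: float = 0.36
    cph_min_repeats: int = 3

    # --- homology / orthology ------------------------------------------
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    rbh_min_identity: float = 0.30

    # --- phylogeny ------------------------------------------------------
    bootstrap_replicates: int = 100
    #: flank (aa) kept on each side of the R&R consensus window for
    #: subfamily trees
    consensus_flank: int = 10

    # --- genome layout --------------------------------------------------
    max_gap_kb: float = 100.0
    max_intervening: int = 1

    # --- expression -----------------------------------------------------
    #: FPKM at or above which a gene is called expressed
    expressed_min_fpkm: float = 1.0
    heatmap_pseudocount: float = 1.0
    #: row ordering for heat-map matrices: "cluster" or "genomic"
    heatmap_order: str = "cluster"
    tissue_specific_min_ratio: float = 0.8

    # --- naming ---------------------------------------------------------
    #: species prefix for de-novo names of proteins without 1:1 orthologs
    name_prefix: str = "Ap"

    # --- misc -----------------------------------------------------------
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
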