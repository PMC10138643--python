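"""Published cuticular-protein catalog counts for the two silkworm species.

Bundled per-family counts of CP genes identified in the genomes of the wild
silkworm *Antheraea pernyi* (217 genes; six transcriptome tissues: larval
epidermis Ep, prothoracic gland PG, haemolymph He, midgut Mg, female/male
antenna FA/MA) and the domestic silkworm *Bombyx mori* (236 genes; Ep, PG
and corpus allatum CA), with the number expressed per tissue. These printed
counts are inputs to the reporting code (totals, percentages,
not-expressed counts); they let the arithmetic of the summary tables be
validated without any genome or transcriptome download.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

SPECIES = ("A_pernyi", "B_mori")


def load_published_counts(species: str) -> pd.DataFrame:
    """Per-family genome/expressed counts for one species.

    Returns a DataFrame indexed by family stratum with a "Genome" column
    and one integer column per profiled tissue (tissues not profiled for
    the species are dropped).
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; have {SPECIES}")
    text = (importlib.resources.files("cuticula") / "data"
            / "published_counts.tsv").read_text()
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", na_values="NA")
    df = df[df["species"] == species].drop(columns="species").set_index("family")
    df = df.dropna(axis=1, how="all")
    return df.astype(int)
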