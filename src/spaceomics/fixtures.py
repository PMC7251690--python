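"""Packaged reference tables transcribed from the published study.

Three small tables ship with the package so the cross-omics worked example
runs without any external download:

* ``load_overlap_table`` — the 17 loci significant in both the transcript
  and protein layers, with per-fraction protein p-values and log2 fold
  changes plus the gene-level log2FC and FDR.
* ``load_phosphopeptide_table`` — the 16 peptides called differentially
  phosphorylated between flight and ground (p <= 0.1).
* ``load_extracellular_table`` — the 8 extracellular-localised soluble
  proteins down-regulated in flight.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_overlap_table",
    "load_phosphopeptide_table",
    "load_extracellular_table",
    "overlap_table_as_diff_records",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("spaceomics.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_overlap_table() -> pd.DataFrame:
    return _read("overlap_loci.tsv")


def load_phosphopeptide_table() -> pd.DataFrame:
    """The published differential phosphopeptides; every row passed p <= 0.1."""
    tab = _read("phosphopeptides.tsv")
    tab["modification"] = "phospho"
    tab["passes"] = True
    return tab


def load_extracellular_table() -> pd.DataFrame:
    return _read("extracellular_soluble_down.tsv")


def overlap_table_as_diff_records() -> dict[str, pd.DataFrame]:
    """Re-shape the overlap table into per-layer differential records.

    Returns ``{"rna": ..., "membrane": ..., "soluble": ...}`` in the schema
    the callers (:func:`spaceomics.rnaseq_de.call_rna_degs`,
    :func:`spaceomics.proteomics_de.call_daps`) expect, so the published
    worked example can be pushed through the same decision rules as any
    fresh dataset.
    """
    tab = load_overlap_table().set_index("tair_id")
    rna = pd.DataFrame(
        {
            "layer": "rna",
            "log2fc": tab["gene_log2fc"],
            "p_value": tab["gene_fdr"],  # published table reports FDR directly
            "fdr": tab["gene_fdr"],
            "passes": False,
        },
        index=tab.index.rename("feature_id"),
    )
    out = {"rna": rna}
    for fraction in ("membrane", "soluble"):
        sub = tab.dropna(subset=[f"{fraction}_log2fc"])
        out[fraction] = pd.DataFrame(
            {
                "layer": fraction,
                "log2fc": sub[f"{fraction}_log2fc"],
                "t_stat": float("nan"),
                "p_value": sub[f"{fraction}_p"],
                "fdr": float("nan"),
                "passes": False,
            },
            index=sub.index.rename("feature_id"),
        )
    return out
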