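"""Differential protein abundance and PTM testing for iTRAQ-style data.

Input is a peptide-level quantification table: one row per peptide ion with
its parent protein, modification annotation (none / phospho / oxidation /
deamidation), site string, search-engine ion score, and one log2 intensity
per labelling channel.  Channels map to conditions (three flight and three
ground replicates per protein fraction in the design emulated here).

Stages
------
1.  Protein inference: a protein is reportable only if it has at least two
    distinct peptides with ion score strictly greater than 20.
2.  Protein-level differential abundance: unmodified peptide intensities are
    rolled up to a per-channel protein abundance (unweighted mean by
    default) and compared between conditions with a classic equal-variance
    Student's t-test.  Called at |log2FC| >= 0.2 and p <= 0.05.
3.  PTM testing: each modified peptide is tested individually with the same
    t machinery at the relaxed threshold p <= 0.1 (no phospho-enrichment,
    so modified peptides are sparse and under-sampled).
4.  Oxidation prevalence: per-fraction summary of how many oxidized
    peptides shifted significantly and in which direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rnaseq_de import DEThresholds

__all__ = [
    "QuantTable",
    "ProteinInferenceParams",
    "infer_reportable_proteins",
    "protein_ttest",
    "call_daps",
    "ptm_differential",
    "oxidation_prevalence_summary",
]

logger = logging.getLogger(__name__)

MODIFICATIONS = ("none", "phospho", "oxidation", "deamidation")
META_COLUMNS = ["protein_id", "peptide_seq", "modification", "site", "ion_score"]


@dataclass
class QuantTable:
    """Peptide-level log2 intensities with channel -> condition mapping."""

    data: pd.DataFrame
    channel_map: dict[str, str]
    fraction: str = "soluble"
    treatment: str = "flight"

    def __post_init__(self) -> None:
        missing = set(META_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"quant table missing columns {sorted(missing)}")
        unknown = set(self.data["modification"].unique()) - set(MODIFICATIONS)
        if unknown:
            raise ValueError(f"unknown modification labels {sorted(unknown)}")
        if (self.data["ion_score"] < 0).any():
            raise ValueError("ion scores must be non-negative")
        for ch in self.channels:
            if ch not in self.channel_map:
                raise ValueError(f"channel {ch!r} not mapped to a condition")
        conditions = set(self.channel_map.values())
        if self.treatment not in conditions or len(conditions) != 2:
            raise ValueError(f"channel map must cover two conditions incl. {self.treatment!r}, got {conditions}")

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    def condition_channels(self, condition: str) -> list[str]:
        return [c for c in self.channels if self.channel_map[c] == condition]

    @property
    def reference(self) -> str:
        return next(c for c in set(self.channel_map.values()) if c != self.treatment)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, channel_map: dict[str, str], fraction: str, treatment: str = "flight") -> "QuantTable":
        return cls(pd.read_csv(path, sep="\t"), channel_map, fraction, treatment)


@dataclass(frozen=True)
class ProteinInferenceParams:
    """At least ``min_peptides`` peptides with score strictly > ``min_score``."""

    min_peptides: int = 2
    min_score: float = 20.0

    def __post_init__(self) -> None:
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")


def infer_reportable_proteins(table: QuantTable, params: ProteinInferenceParams = ProteinInferenceParams()) -> set[str]:
    """Proteins with >= min_peptides distinct peptides scoring > min_score."""
    df = table.data
    good = df[df["ion_score"] > params.min_score]
    n_pep = good.groupby("protein_id")["peptide_seq"].nunique()
    return set(n_pep[n_pep >= params.min_peptides].index)


def _student_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t; degenerate zero-variance cases handled."""
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return np.inf * np.sign(np.mean(x) - np.mean(y)), float(np.finfo(float).tiny)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def rollup_protein_abundance(table: QuantTable, method: str = "mean") -> pd.DataFrame:
    """Per-channel protein abundance from unmodified peptides.

    Returns a DataFrame indexed by protein id with one column per channel.
    Modified peptide rows are excluded so that PTM stoichiometry shifts do
    not leak into the total-abundance estimate.
    """
    if method not in ("mean", "median"):
        raise ValueError("rollup method must be 'mean' or 'median'")
    unmod = table.data[table.data["modification"] == "none"]
    grouped = unmod.groupby("protein_id")[table.channels]
    return grouped.mean() if method == "mean" else grouped.median()


def protein_ttest(
    table: QuantTable,
    params: ProteinInferenceParams = ProteinInferenceParams(),
    rollup: str = "mean",
) -> pd.DataFrame:
    """Per-protein differential abundance records for one fraction.

    Only reportable proteins (see :func:`infer_reportable_proteins`) are
    tested.  log2fc is mean(treatment channels) - mean(reference channels).
    """
    t_ch = table.condition_channels(table.treatment)
    r_ch = table.condition_channels(table.reference)
    if len(t_ch) < 2 or len(r_ch) < 2:
        raise ValueError("need at least two channels per condition")
    reportable = infer_reportable_proteins(table, params)
    abundance = rollup_protein_abundance(table, rollup)
    abundance = abundance.loc[abundance.index.isin(reportable)]

    rows = []
    for pid, row in abundance.iterrows():
        x = row[t_ch].to_numpy(dtype=float)
        y = row[r_ch].to_numpy(dtype=float)
        t, p = _student_t(x, y)
        rows.append(
            {
                "feature_id": pid,
                "layer": table.fraction,
                "log2fc": float(x.mean() - y.mean()),
                "t_stat": t,
                "p_value": p,
                "fdr": np.nan,
                "passes": False,
            }
        )
    out = pd.DataFrame(rows, columns=["feature_id", "layer", "log2fc", "t_stat", "p_value", "fdr", "passes"])
    return out.set_index("feature_id")


def call_daps(records: pd.DataFrame, thresholds: DEThresholds = DEThresholds()) -> pd.DataFrame:
    """Protein decision rule: |log2fc| >= 0.2 and p <= 0.05, boundaries inclusive."""
    rec = records.copy()
    rec["passes"] = (rec["log2fc"].abs() >= thresholds.protein_lfc) & (rec["p_value"] <= thresholds.protein_p)
    out = rec[rec["passes"]].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def ptm_differential(
    table: QuantTable,
    alpha: float = 0.1,
    modifications: tuple[str, ...] = ("phospho", "oxidation", "deamidation"),
) -> pd.DataFrame:
    """Peptide-level t-tests for modified peptides at the relaxed threshold.

    One record per modified peptide row; ``passes`` iff p <= alpha.  Peptides
    with fewer than two quantified channels in either condition are skipped
    with a log entry.
    """
    t_ch = table.condition_channels(table.treatment)
    r_ch = table.condition_channels(table.reference)
    mod_rows = table.data[table.data["modification"].isin(modifications)]
    rows = []
    for idx, row in mod_rows.iterrows():
        x = row[t_ch].to_numpy(dtype=float)
        y = row[r_ch].to_numpy(dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            logger.info(
                "skipping PTM peptide %s/%s: <2 channels per condition", row["protein_id"], row["peptide_seq"]
            )
            continue
        t, p = _student_t(x, y)
        rows.append(
            {
                "feature_id": row["protein_id"],
                "peptide_seq": row["peptide_seq"],
                "modification": row["modification"],
                "site": row["site"],
                "layer": "ptm",
                "log2fc": float(x.mean() - y.mean()),
                "p_value": p,
                "passes": p <= alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "peptide_seq", "modification", "site", "layer", "log2fc", "p_value", "passes"],
    )


def oxidation_prevalence_summary(table: QuantTable, alpha: float = 0.05) -> dict:
    """Prevalence shift of the oxidized proteome in one fraction.

    Each oxidized peptide's own channel intensities are tested (Student's t);
    among peptides significant at ``alpha``, the fraction with a positive
    log2fc (more oxidized form under treatment) is reported.  Returns
    ``{"fraction", "n_oxidized_tested", "n_significant",
    "fraction_increased_in_treatment"}``; the fraction is NaN when nothing
    was tested or significant.
    """
    recs = ptm_differential(table, alpha=alpha, modifications=("oxidation",))
    n_tested = len(recs)
    sig = recs[recs["p_value"] <= alpha]
    n_sig = len(sig)
    frac_up = float((sig["log2fc"] > 0).mean()) if n_sig else float("nan")
    return {
        "fraction": table.fraction,
        "n_oxidized_tested": n_tested,
        "n_significant": n_sig,
        "fraction_increased_in_treatment": frac_up,
    }
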