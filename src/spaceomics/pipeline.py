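"""End-to-end orchestration: simulate -> per-layer DE -> artifact filter ->
cross-layer integration -> enrichment/localization -> report.

Every stage writes a TSV into the run directory and contributes counts to a
machine-readable ``run_summary.json`` (which also records the full
configuration and its hash, so a run directory is self-describing).
Re-running with an identical configuration reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import control_filter, enrichment, fixtures, integration, proteomics_de, rnaseq_de, synthetic_data
from .proteomics_de import ProteinInferenceParams
from .rnaseq_de import DEThresholds

__all__ = ["PipelineConfig", "run_pipeline", "run_paper_tables_profile", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "spaceomics_run"
    seed: int = 0
    simulation: synthetic_data.SimulationConfig | None = None
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    inference: ProteinInferenceParams = field(default_factory=ProteinInferenceParams)
    genome_size: int = integration.ARABIDOPSIS_GENOME_SIZE
    overlap_mode: str = "point"       # "point" reproduces the published statistic
    rollup: str = "mean"
    enrichment_params: enrichment.EnrichmentParams = field(default_factory=enrichment.EnrichmentParams)
    obo_path: str | None = None
    annotation_path: str | None = None       # gene_id<TAB>term_id
    localization_path: str | None = None     # feature_id<TAB>location

    def __post_init__(self) -> None:
        if self.overlap_mode not in ("point", "tail"):
            raise ValueError("overlap_mode must be 'point' or 'tail'")
        if self.simulation is None:
            self.simulation = synthetic_data.SimulationConfig(seed=self.seed)

    def config_hash(self) -> str:
        # output location is not part of the analysis identity
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(_jsonable(payload), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, int, float, bool)):
        return _jsonable(vars(obj))
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-data pipeline; returns the run summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash(), "stages": {}}
    partial_marker = out / "PARTIAL"
    partial_marker.write_text("run in progress; outputs may be incomplete\n")

    try:
        logger.info("stage=simulate seed=%d", config.seed)
        sim = synthetic_data.simulate_all(config.simulation)
        cm, truth = sim["counts"], sim["truth"]
        cm.to_tsv(out / "counts.tsv", out / "conditions.tsv")
        summary["stages"]["simulate"] = {
            "n_genes": config.simulation.n_genes,
            "n_true_de_rna": int(truth.rna["is_de"].sum()),
        }

        logger.info("stage=de-rna")
        disp = rnaseq_de.estimate_dispersion(cm)
        records = rnaseq_de.nb_lrt(cm, disp)
        records["fdr"] = rnaseq_de.adjust_bh(records["p_value"].to_numpy())
        degs = rnaseq_de.call_rna_degs(records, config.thresholds)
        records.to_csv(out / "de_rna.tsv", sep="\t")
        summary["stages"]["de_rna"] = {
            "dispersion_common": disp.common,
            "n_tested": len(records),
            "n_deg": len(degs),
            "n_up": int((degs["direction"] == "up").sum()),
            "n_down": int((degs["direction"] == "down").sum()),
        }

        logger.info("stage=de-protein")
        dap_frames = {}
        for fraction, table in sim["peptides"].items():
            prot = proteomics_de.protein_ttest(table, config.inference, config.rollup)
            daps = proteomics_de.call_daps(prot, config.thresholds)
            prot.to_csv(out / f"de_protein_{fraction}.tsv", sep="\t")
            dap_frames[fraction] = daps
            summary["stages"][f"de_protein_{fraction}"] = {
                "n_reportable": len(prot),
                "n_dap": len(daps),
                "n_up": int((daps["direction"] == "up").sum()),
                "n_down": int((daps["direction"] == "down").sum()),
            }

        logger.info("stage=ptm")
        ptm_all = []
        for fraction, table in sim["peptides"].items():
            ptm = proteomics_de.ptm_differential(table, alpha=config.thresholds.ptm_p)
            ptm["fraction"] = fraction
            ptm_all.append(ptm)
            ox = proteomics_de.oxidation_prevalence_summary(table)
            summary["stages"][f"oxidation_{fraction}"] = ox
        ptm_records = pd.concat(ptm_all, ignore_index=True)
        ptm_records.to_csv(out / "ptm.tsv", sep="\t", index=False)
        summary["stages"]["ptm"] = {
            "n_tested": len(ptm_records),
            "n_passing": int(ptm_records["passes"].sum()),
        }

        logger.info("stage=filter-controls")
        retained, audit = control_filter.filter_candidates(degs, sim["controls"])
        audit.to_csv(out / "control_audit.tsv", sep="\t", index=False)
        retained.to_csv(out / "retained_rna.tsv", sep="\t")
        summary["stages"]["control_filter"] = {
            "n_candidates": len(degs),
            "n_retained": len(retained),
            "n_excluded": len(degs) - len(retained),
        }

        logger.info("stage=integrate")
        protein_sets = [set(df.index) for df in dap_frames.values()]
        overlap_ids = integration.intersect_layers(set(retained.index), protein_sets)
        conc_records = _concordance_frame(retained, dap_frames, overlap_ids)
        osum = integration.overlap_summary(
            set(retained.index), protein_sets, conc_records, config.genome_size
        )
        conc_records.to_csv(out / "overlap.tsv", sep="\t")
        summary["stages"]["integration"] = osum

        if config.obo_path and config.annotation_path:
            logger.info("stage=enrich")
            onto = enrichment.load_obo(config.obo_path)
            ann = pd.read_csv(config.annotation_path, sep="\t")
            ann = enrichment.propagate_annotations(ann, onto)
            background = [str(f) for f in cm.feature_ids]
            enr_out = {}
            for direction in ("up", "down"):
                de = [g for g in retained.index[retained["direction"] == direction] if g in set(background)]
                recs = enrichment.enrich(de, background, ann, onto, config.enrichment_params)
                recs = enrichment.thin_terms(recs, onto, config.enrichment_params)
                recs.to_csv(out / f"enrichment_{direction}.tsv", sep="\t", index=False)
                enr_out[direction] = {
                    "n_tested": len(recs),
                    "n_retained": int((recs["status"] == "retained").sum()),
                }
            summary["stages"]["enrichment"] = enr_out

        if config.localization_path:
            logger.info("stage=localize")
            loc_tab = pd.read_csv(config.localization_path, sep="\t")
            assign, dist = enrichment.assign_localizations(list(retained.index), loc_tab)
            assign.to_csv(out / "localizations.tsv", sep="\t", index=False)
            dist.to_csv(out / "localization_distribution.tsv", sep="\t", index=False)
            summary["stages"]["localization"] = {"n_assigned": len(assign)}
    except Exception as exc:  # pragma: no cover - error path
        stage = summary["stages"].keys()
        logger.error("pipeline aborted after stages %s: %s", list(stage), exc)
        raise

    partial_marker.unlink()
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _concordance_frame(retained: pd.DataFrame, dap_frames: dict[str, pd.DataFrame], overlap_ids) -> pd.DataFrame:
    rows = {}
    for fid in sorted(overlap_ids):
        row = {"rna_log2fc": float(retained.at[fid, "log2fc"])}
        for fraction, daps in dap_frames.items():
            if fid in daps.index:
                row[f"{fraction}_log2fc"] = float(daps.at[fid, "log2fc"])
                row[f"{fraction}_p"] = float(daps.at[fid, "p_value"])
            else:
                row[f"{fraction}_log2fc"] = float("nan")
                row[f"{fraction}_p"] = float("nan")
        rows[fid] = row
    cols = ["rna_log2fc", "membrane_log2fc", "membrane_p", "soluble_log2fc", "soluble_p"]
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols).rename_axis("feature_id")


def run_paper_tables_profile(genome_size: int = integration.ARABIDOPSIS_GENOME_SIZE,
                             k: int = 968, n: int = 210) -> dict:
    """The packaged worked example: published tables through the full rules.

    The packaged overlap table is pushed through the transcript and protein
    decision rules, concordance is classified, and the overlap statistic is
    evaluated at the published list sizes (k RNA candidates, n protein
    candidates pooled over fractions).  The packaged phosphopeptide table is
    re-emitted as passing PTM records.
    """
    recs = fixtures.overlap_table_as_diff_records()
    thresholds = DEThresholds()
    degs = rnaseq_de.call_rna_degs(recs["rna"], thresholds)
    daps = {f: proteomics_de.call_daps(recs[f], thresholds) for f in ("membrane", "soluble")}
    overlap = integration.intersect_layers(set(degs.index), [set(d.index) for d in daps.values()])
    conc_records = _concordance_frame(degs, daps, overlap)
    conc, disc = integration.classify_concordance(conc_records)
    p_concordant = integration.hypergeometric_point_probability(
        integration.OverlapSpec(N=genome_size, k=k, n=n, x=len(conc))
    )
    p_all = integration.hypergeometric_point_probability(
        integration.OverlapSpec(N=genome_size, k=k, n=n, x=len(overlap))
    )
    ptm = fixtures.load_phosphopeptide_table()
    return {
        "overlap": len(overlap),
        "concordant": len(conc),
        "discordant": len(disc),
        "p_point_concordant": p_concordant,
        "p_point_all": p_all,
        "ptm_count": int(ptm["passes"].sum()),
    }


def validate_inputs(config: PipelineConfig, counts_path=None, conditions_path=None,
                    quant_paths: dict | None = None, control_paths: dict | None = None) -> list[str]:
    """Schema checks on the TSV dialects; returns a list of violations."""
    violations: list[str] = []
    if counts_path is not None:
        try:
            counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        except Exception as exc:
            return [f"counts: unreadable ({exc})"]
        num = counts.select_dtypes("number")
        if num.shape[1] != counts.shape[1]:
            violations.append("counts: non-numeric columns present")
        bad = (num < 0) | (num != num.round())
        if bad.any().any():
            col = bad.any()[bad.any()].index[0]
            row = bad[col][bad[col]].index[0]
            violations.append(f"counts: negative or non-integer entry at row {row!r}, column {col!r}")
        if conditions_path is not None:
            cond = pd.read_csv(conditions_path, sep="\t")
            if set(cond.columns) != {"sample_id", "condition"}:
                violations.append("conditions: expected columns sample_id, condition")
            else:
                missing = set(counts.columns) - set(cond["sample_id"])
                for m in sorted(missing):
                    violations.append(f"conditions: sample {m!r} has no condition label")
                if cond["condition"].nunique() != 2:
                    violations.append("conditions: expected exactly two condition levels")
    if quant_paths:
        for fraction, (path, channel_map) in quant_paths.items():
            try:
                df = pd.read_csv(path, sep="\t")
            except Exception as exc:
                violations.append(f"quant[{fraction}]: unreadable ({exc})")
                continue
            missing_cols = set(proteomics_de.META_COLUMNS) - set(df.columns)
            if missing_cols:
                violations.append(f"quant[{fraction}]: missing columns {sorted(missing_cols)}")
                continue
            channels = [c for c in df.columns if c not in proteomics_de.META_COLUMNS]
            for ch in channels:
                if ch not in channel_map:
                    violations.append(f"quant[{fraction}]: channel {ch!r} not mapped to a condition")
    if control_paths:
        for name, path in control_paths.items():
            try:
                tab = pd.read_csv(path, sep="\t")
            except Exception as exc:
                violations.append(f"control[{name}]: unreadable ({exc})")
                continue
            missing_cols = set(control_filter.CONTROL_TABLE_COLUMNS) - set(tab.columns)
            if missing_cols:
                violations.append(f"control[{name}]: missing columns {sorted(missing_cols)}")
    return violations
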