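"""Synthetic multi-omics data with known ground truth.

Emulates the statistical structure of a spaceflight seedling experiment:
three biological replicates per condition (flight vs ground) for bulk
RNA-seq counts; iTRAQ-8plex-style log2 intensity channels (3 + 3) for two
protein fractions (membrane and soluble); peptide tables carrying
phospho/oxidation/deamidation annotations and search-engine ion scores; and
two control studies (flight hardware, RNA preservative) whose perturbations
partially overlap the treatment effects so the artifact-exclusion rule has
non-trivial work.

Counts are negative-binomial with ``Var = mu + alpha * mu**2``; condition
means of spiked genes differ by exactly the true log2 fold change.  Library
sizes vary log-normally (about +/-20%) so offset handling downstream is
exercised.  Each generator draws from its own RNG stream derived from the
master seed by a fixed offset, so adding one generator never perturbs the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .proteomics_de import QuantTable
from .rnaseq_de import CountMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_counts", "simulate_protein_layers",
           "simulate_peptides", "simulate_control_studies", "simulate_all"]

# fixed per-generator stream offsets (master seed spawns independent streams)
_STREAM_COUNTS = 0
_STREAM_PROTEIN = 1
_STREAM_PEPTIDE = 2
_STREAM_CONTROL = 3

FRACTIONS = ("membrane", "soluble")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated experiment.

    Defaults mirror the emulated design: a 27,000-gene genome, 3 replicates
    per condition, roughly 3.6% of genes truly differential at |log2FC| >= 1,
    ~1,300 quantified proteins per fraction, and control studies touching
    about a quarter of the treatment DE genes.
    """

    n_genes: int = 27000
    n_replicates: int = 3
    baseline_log_mean: float = 4.5     # natural-log mean of the NB baseline (median ~90 counts)
    baseline_log_sd: float = 1.2
    dispersion: float = 0.1            # NB alpha: Var = mu + alpha * mu^2
    library_size_sd: float = 0.2       # log-normal sd of size factors (~±20%)
    frac_de: float = 0.036
    effect_size_min: float = 1.0       # spiked |log2FC| = min + Exp(scale)
    effect_size_scale: float = 1.0

    n_proteins_per_fraction: int = 1300
    rna_protein_coupling: float = 0.3  # P(RNA-DE gene is protein-DE | quantified)
    discordant_fraction: float = 5 / 17  # P(protein sign opposes RNA sign | coupled)
    protein_effect_min: float = 0.3
    protein_effect_max: float = 1.0
    protein_baseline_mean: float = 15.0
    protein_baseline_sd: float = 2.0
    protein_noise_sd: float = 0.2

    peptides_per_protein: int = 3
    peptide_score_mean: float = 35.0
    peptide_score_sd: float = 10.0
    frac_ptm: float = 0.03             # fraction of proteins with a phospho peptide
    frac_oxidized: float = 0.15
    frac_deamidated: float = 0.02
    frac_ptm_de: float = 0.10          # fraction of modified peptides truly shifted
    ptm_effect_min: float = 0.3
    ptm_effect_max: float = 1.2
    oxidation_up_fraction_membrane: float = 0.79
    oxidation_up_fraction_soluble: float = 0.12

    control_frac: float = 0.02         # genes perturbed per control study
    control_overlap_fraction: float = 0.27  # share drawn from treatment DE genes
    control_effect_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates < 2:
            raise ValueError("need n_genes > 0 and n_replicates >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name in ("frac_de", "rna_protein_coupling", "discordant_fraction", "frac_ptm",
                     "frac_oxidized", "frac_deamidated", "frac_ptm_de", "control_frac",
                     "control_overlap_fraction", "oxidation_up_fraction_membrane",
                     "oxidation_up_fraction_soluble"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size_min < 1.0:
            raise ValueError("spiked RNA effect magnitudes must be >= the DE threshold (1)")
        if self.n_proteins_per_fraction > self.n_genes:
            raise ValueError("cannot quantify more proteins than genes")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load overrides from a flat key-value YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """True effects per feature and layer; zero log2FC iff not flagged DE."""

    rna: pd.DataFrame                      # feature_id-indexed: is_de, true_log2fc
    protein: dict = field(default_factory=dict)   # fraction -> DataFrame(is_de, true_log2fc)
    ptm: dict = field(default_factory=dict)       # fraction -> peptide-level truth table
    controls: dict = field(default_factory=dict)  # control -> DataFrame(is_control_affected, true_log2fc)

    def validate(self) -> None:
        tables = [self.rna, *self.protein.values()]
        for tab in tables:
            spiked = tab["is_de"]
            if (tab.loc[spiked, "true_log2fc"] == 0).any():
                raise AssertionError("spiked feature with zero true effect")
            if (tab.loc[~spiked, "true_log2fc"] != 0).any():
                raise AssertionError("non-spiked feature with nonzero true effect")


def _feature_ids(n: int) -> list[str]:
    return [f"SIM{i:05d}" for i in range(n)]


def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    flight = [f"flight_{i + 1}" for i in range(config.n_replicates)]
    ground = [f"ground_{i + 1}" for i in range(config.n_replicates)]
    return flight, ground


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """NB count matrix for the two-condition design plus the truth table."""
    rng = config.rng(_STREAM_COUNTS)
    ids = _feature_ids(config.n_genes)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)

    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    lfc = np.zeros(config.n_genes)
    if n_de:
        mag = config.effect_size_min + rng.exponential(config.effect_size_scale, n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = mag * sign

    flight, ground = _sample_names(config)
    size_factors = rng.lognormal(0.0, config.library_size_sd, 2 * config.n_replicates)
    # condition means split the fold change symmetrically on the log2 scale
    mu_f = baseline * np.exp2(lfc / 2.0)
    mu_g = baseline * np.exp2(-lfc / 2.0)
    alpha = config.dispersion
    r = 1.0 / alpha

    cols = {}
    for j, name in enumerate(flight + ground):
        mu = (mu_f if j < config.n_replicates else mu_g) * size_factors[j]
        cols[name] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="feature_id"))
    conditions = pd.Series(
        ["flight"] * config.n_replicates + ["ground"] * config.n_replicates, index=flight + ground
    )
    cm = CountMatrix(counts=counts, conditions=conditions, treatment="flight")
    truth = GroundTruth(
        rna=pd.DataFrame({"is_de": lfc != 0, "true_log2fc": lfc}, index=counts.index)
    )
    return cm, truth


def simulate_protein_layers(config: SimulationConfig, truth: GroundTruth) -> dict[str, QuantTable]:
    """Peptide-level quantification tables for the two protein fractions.

    Each quantified protein receives ``peptides_per_protein`` unmodified
    peptide rows.  Channel intensity = protein baseline + peptide offset
    +/- effect/2 + Gaussian noise.  A protein is truly differential iff its
    gene is RNA-DE and the coupling coin (probability
    ``rna_protein_coupling``) lands heads; the protein sign matches the RNA
    sign except for a ``discordant_fraction`` share.
    """
    rng = config.rng(_STREAM_PROTEIN)
    genes = truth.rna.index.to_numpy()
    if len(genes) != config.n_genes:
        raise ValueError("truth table does not match the configured feature universe")
    flight, ground = _sample_names(config)
    channels = [f"ch_{c}" for c in flight + ground]
    channel_map = dict(zip(channels, ["flight"] * config.n_replicates + ["ground"] * config.n_replicates))

    out: dict[str, QuantTable] = {}
    for fraction in FRACTIONS:
        chosen = rng.choice(len(genes), size=config.n_proteins_per_fraction, replace=False)
        chosen.sort()
        pids = genes[chosen]
        rna_de = truth.rna.loc[pids, "is_de"].to_numpy()
        rna_sign = np.sign(truth.rna.loc[pids, "true_log2fc"].to_numpy())

        coupled = rna_de & (rng.random(len(pids)) < config.rna_protein_coupling)
        mag = rng.uniform(config.protein_effect_min, config.protein_effect_max, len(pids))
        flip = np.where(rng.random(len(pids)) < config.discordant_fraction, -1.0, 1.0)
        effect = np.where(coupled, mag * rna_sign * flip, 0.0)

        baseline = rng.normal(config.protein_baseline_mean, config.protein_baseline_sd, len(pids))
        rows = []
        n_rep = config.n_replicates
        for i, pid in enumerate(pids):
            pep_offsets = rng.normal(0.0, 0.5, config.peptides_per_protein)
            for k in range(config.peptides_per_protein):
                scores = rng.normal(config.peptide_score_mean, config.peptide_score_sd)
                intensities = (
                    baseline[i]
                    + pep_offsets[k]
                    + np.concatenate([np.full(n_rep, effect[i] / 2.0), np.full(n_rep, -effect[i] / 2.0)])
                    + rng.normal(0.0, config.protein_noise_sd, 2 * n_rep)
                )
                rows.append([pid, f"{pid}_pep{k}", "none", "", max(0.0, scores), *intensities])
        data = pd.DataFrame(rows, columns=["protein_id", "peptide_seq", "modification", "site", "ion_score", *channels])
        out[fraction] = QuantTable(data=data, channel_map=channel_map, fraction=fraction, treatment="flight")
        truth.protein[fraction] = pd.DataFrame(
            {"is_de": effect != 0, "true_log2fc": effect}, index=pd.Index(pids, name="feature_id")
        )
    return out


def simulate_peptides(
    config: SimulationConfig,
    truth: GroundTruth,
    base: dict[str, QuantTable] | None = None,
) -> dict[str, QuantTable]:
    """Full peptide tables: unmodified rows plus modified peptide rows.

    Modified rows (phospho, oxidation, deamidation) are appended to the
    unmodified tables from :func:`simulate_protein_layers` (generated here
    if not supplied).  A ``frac_ptm_de`` share of modified peptides carries
    a true modification-level shift; oxidation signs follow the per-fraction
    asymmetry (``oxidation_up_fraction_*``), phospho/deamidation signs are
    symmetric.
    """
    if base is None:
        base = simulate_protein_layers(config, truth)
    rng = config.rng(_STREAM_PEPTIDE)
    up_frac = {
        "membrane": config.oxidation_up_fraction_membrane,
        "soluble": config.oxidation_up_fraction_soluble,
    }
    out: dict[str, QuantTable] = {}
    for fraction, table in base.items():
        channels = table.channels
        n_rep = config.n_replicates
        pids = truth.protein[fraction].index.to_numpy()
        rows = []
        truth_rows = []
        for mod, frac_mod in (
            ("phospho", config.frac_ptm),
            ("oxidation", config.frac_oxidized),
            ("deamidation", config.frac_deamidated),
        ):
            n_mod = int(round(frac_mod * len(pids)))
            if n_mod == 0:
                continue
            chosen = rng.choice(len(pids), size=n_mod, replace=False)
            chosen.sort()
            residue = {"phospho": "S", "oxidation": "M", "deamidation": "N"}[mod]
            for i in chosen:
                pid = pids[i]
                is_de = rng.random() < config.frac_ptm_de
                if is_de:
                    mag = rng.uniform(config.ptm_effect_min, config.ptm_effect_max)
                    if mod == "oxidation":
                        sign = 1.0 if rng.random() < up_frac[fraction] else -1.0
                    else:
                        sign = rng.choice([-1.0, 1.0])
                    eff = mag * sign
                else:
                    eff = 0.0
                site = f"{residue}{rng.integers(1, 400)}"
                baseline = rng.normal(config.protein_baseline_mean, config.protein_baseline_sd)
                intensities = (
                    baseline
                    + np.concatenate([np.full(n_rep, eff / 2.0), np.full(n_rep, -eff / 2.0)])
                    + rng.normal(0.0, config.protein_noise_sd, 2 * n_rep)
                )
                score = max(0.0, rng.normal(config.peptide_score_mean, config.peptide_score_sd))
                pep = f"{pid}_{mod}"
                rows.append([pid, pep, mod, site, score, *intensities])
                truth_rows.append({"protein_id": pid, "peptide_seq": pep, "modification": mod,
                                   "is_de": bool(is_de), "true_log2fc": eff})
        mod_df = pd.DataFrame(rows, columns=["protein_id", "peptide_seq", "modification", "site", "ion_score", *channels])
        data = pd.concat([table.data, mod_df], ignore_index=True)
        out[fraction] = QuantTable(data=data, channel_map=table.channel_map, fraction=fraction, treatment=table.treatment)
        truth.ptm[fraction] = pd.DataFrame(truth_rows, columns=["protein_id", "peptide_seq", "modification", "is_de", "true_log2fc"])
    return out


def simulate_control_studies(config: SimulationConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Hardware-like and preservative-like control DE tables.

    Each control study perturbs ``control_frac`` of the genome;
    ``control_overlap_fraction`` of the perturbed genes are drawn from the
    treatment DE set with effects that are identical, attenuated (x0.5) or
    inflated (x1.5) relative to the treatment effect, so the retention rule
    faces easy and hard cases.  Output tables have columns
    (feature_id, log2fc, significant) with significant always True.
    """
    rng = config.rng(_STREAM_CONTROL)
    genes = truth.rna.index.to_numpy()
    de_genes = truth.rna.index[truth.rna["is_de"]].to_numpy()
    non_de = truth.rna.index[~truth.rna["is_de"]].to_numpy()
    n_affected = int(round(config.control_frac * config.n_genes))

    out: dict[str, pd.DataFrame] = {}
    for control in ("hardware", "preservative"):
        n_overlap = min(int(round(config.control_overlap_fraction * n_affected)), len(de_genes))
        n_rest = n_affected - n_overlap
        overlap = rng.choice(de_genes, size=n_overlap, replace=False) if n_overlap else np.array([], dtype=object)
        rest = rng.choice(non_de, size=n_rest, replace=False) if n_rest else np.array([], dtype=object)

        multipliers = rng.choice([1.0, 0.5, 1.5], size=n_overlap, p=[0.4, 0.3, 0.3])
        lfc_overlap = truth.rna.loc[overlap, "true_log2fc"].to_numpy() * multipliers
        lfc_rest = rng.normal(0.0, config.control_effect_sd, n_rest)
        lfc_rest = np.where(np.abs(lfc_rest) < 0.5, np.sign(lfc_rest + 1e-12) * 0.5, lfc_rest)

        table = pd.DataFrame(
            {
                "feature_id": np.concatenate([overlap, rest]),
                "log2fc": np.concatenate([lfc_overlap, lfc_rest]),
                "significant": True,
            }
        )
        out[control] = table.sort_values("feature_id", kind="stable").reset_index(drop=True)
        truth.controls[control] = pd.DataFrame(
            {
                "is_control_affected": pd.Series(genes, index=genes).isin(table["feature_id"]).to_numpy(),
                "true_log2fc": pd.Series(0.0, index=genes)
                .add(pd.Series(table["log2fc"].to_numpy(), index=table["feature_id"]), fill_value=0.0)
                .reindex(genes)
                .to_numpy(),
            },
            index=pd.Index(genes, name="feature_id"),
        )
    return out


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator; returns counts, quant tables, controls and truth."""
    cm, truth = simulate_counts(config)
    protein = simulate_protein_layers(config, truth)
    peptides = simulate_peptides(config, truth, base=protein)
    controls = simulate_control_studies(config, truth)
    truth.validate()
    return {"counts": cm, "protein": protein, "peptides": peptides, "controls": controls, "truth": truth}
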