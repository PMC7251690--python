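"""Count-based two-group differential expression.

Negative-binomial model with a log link and library-size offsets, in the
style of the classic exact/GLM count pipelines: a shared dispersion is
estimated by profile likelihood, each gene is tested with a likelihood-ratio
test (full model: one mean per condition; null model: a single mean), and
Benjamini-Hochberg correction yields per-gene FDR values.

The NB is parameterised by its mean mu and dispersion alpha with
``Var(Y) = mu + alpha * mu**2`` (alpha -> 0 recovers the Poisson).  For a
sample with library-size factor ``s`` the modelled mean is ``mu = s * q``
where ``q`` is the condition-level relative abundance; the reported fold
change is ``log2(q_treatment / q_reference)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEThresholds",
    "DispersionEstimate",
    "estimate_dispersion",
    "nb_lrt",
    "adjust_bh",
    "call_rna_degs",
]

# Dispersion values below this are indistinguishable from Poisson for the
# replicate numbers this design supports; the profile search is floored here.
_ALPHA_FLOOR = 1e-6
_ALPHA_CEIL = 10.0


@dataclass
class CountMatrix:
    """Integer transcript counts with a two-condition design.

    Parameters
    ----------
    counts
        DataFrame of shape (features, samples); non-negative integers.
    conditions
        Mapping sample id -> condition label; exactly two levels.
    treatment
        The condition label treated as the numerator of fold changes
        (e.g. ``"flight"``); the other level is the reference.
    library_size
        Optional per-sample totals; defaults to column sums.
    """

    counts: pd.DataFrame
    conditions: pd.Series
    treatment: str
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions).reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = list(self.counts.columns[self.conditions.isna()])
            raise ValueError(f"samples without a condition label: {missing}")
        levels = sorted(self.conditions.unique())
        if len(levels) != 2:
            raise ValueError(f"expected exactly two condition levels, got {levels}")
        if self.treatment not in levels:
            raise ValueError(f"treatment label {self.treatment!r} not in {levels}")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        for lev in levels:
            if (self.conditions == lev).sum() < 2:
                raise ValueError(f"condition {lev!r} has fewer than 2 replicates")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0).astype(float)
        else:
            self.library_size = pd.Series(self.library_size).reindex(self.counts.columns).astype(float)
            if self.library_size.isna().any() or (self.library_size <= 0).any():
                raise ValueError("library sizes must be positive for every sample")

    @property
    def reference(self) -> str:
        levels = sorted(self.conditions.unique())
        return levels[0] if levels[1] == self.treatment else levels[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    def group_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Counts and size factors split into (treatment, reference) blocks."""
        t_mask = (self.conditions == self.treatment).to_numpy()
        y = self.counts.to_numpy(dtype=float)
        s = self.library_size.to_numpy(dtype=float)
        return y[:, t_mask], y[:, ~t_mask], s[t_mask], s[~t_mask]

    def to_tsv(self, counts_path, conditions_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        pd.DataFrame({"sample_id": self.conditions.index, "condition": self.conditions.values}).to_csv(
            conditions_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, counts_path, conditions_path, treatment: str) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        cond = pd.read_csv(conditions_path, sep="\t")
        conditions = pd.Series(cond["condition"].values, index=cond["sample_id"].values)
        return cls(counts=counts, conditions=conditions, treatment=treatment)


@dataclass(frozen=True)
class DEThresholds:
    """Decision rules for the three layers.

    Defaults: transcripts |log2FC| >= 1 at FDR <= 0.05; proteins
    |log2FC| >= 0.2 at p <= 0.05; modified peptides p <= 0.1 (relaxed to
    allow PTM detection without phospho-enrichment).  All boundaries
    inclusive.
    """

    rna_lfc: float = 1.0
    rna_fdr: float = 0.05
    protein_lfc: float = 0.2
    protein_p: float = 0.05
    ptm_p: float = 0.1

    def __post_init__(self) -> None:
        for name in ("rna_lfc", "rna_fdr", "protein_lfc", "protein_p", "ptm_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series | None = None
    n_genes_used: int = 0

    def per_gene(self, index: pd.Index) -> np.ndarray:
        if self.tagwise is None:
            return np.full(len(index), self.common)
        return self.tagwise.reindex(index).fillna(self.common).to_numpy()


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise NB log-likelihood; y and mu are (genes, samples)."""
    mu = np.maximum(mu, 1e-12)
    r = 1.0 / alpha
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + y * np.log(alpha * mu / (1.0 + alpha * mu))
        - r * np.log1p(alpha * mu)
    )
    return ll.sum(axis=1)


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: float, max_iter: int = 60, tol: float = 1e-12) -> np.ndarray:
    """MLE of the relative abundance q for mu_ij = s_j * q_i, per gene row.

    Newton iterations on eta = log(q) using the NB score
    sum_j (y - mu)/(1 + alpha*mu) and Fisher information sum_j mu/(1 + alpha*mu).
    With equal size factors the solution is the plain group mean, which the
    first iteration already hits; unequal factors converge in a few steps.
    """
    tot = y.sum(axis=1)
    q = tot / s.sum()
    zero = tot == 0
    q = np.where(zero, 1e-12, q)
    eta = np.log(q)
    for _ in range(max_iter):
        mu = np.exp(eta)[:, None] * s[None, :]
        w = 1.0 + alpha * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < tol:
            break
    q = np.exp(eta)
    return np.where(zero, 0.0, q)


def _group_apl(y: np.ndarray, s: np.ndarray, alpha: float) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood contribution of one group.

    The naive profile likelihood (plug in the fitted group means) biases the
    dispersion downward because each gene spends one degree of freedom per
    group on its mean; subtracting half the log Fisher information of the
    mean parameter corrects this.
    """
    q = _fit_group_mean(y, s, alpha)
    mu = np.maximum(q[:, None] * s[None, :], 1e-12)
    ll = _nb_loglik(y, mu, alpha)
    info = (mu / (1.0 + alpha * mu)).sum(axis=1)
    return ll - 0.5 * np.log(np.maximum(info, 1e-12))


def _profile_loglik(alpha: float, y_t, y_r, s_t, s_r) -> float:
    """Summed Cox-Reid adjusted full-model log-likelihood at this dispersion."""
    return float((_group_apl(y_t, s_t, alpha) + _group_apl(y_r, s_r, alpha)).sum())


def _cpm_filter(cm: CountMatrix, min_cpm: float) -> np.ndarray:
    cpm = cm.counts.to_numpy(dtype=float) / cm.library_size.to_numpy()[None, :] * 1e6
    return (cpm >= min_cpm).any(axis=1)


def estimate_dispersion(
    cm: CountMatrix,
    *,
    tagwise: bool = False,
    prior_weight: float = 10.0,
    min_cpm: float = 1.0,
    grid_size: int = 25,
) -> DispersionEstimate:
    """Estimate the NB dispersion alpha shared across genes.

    Maximises the summed per-gene profile log-likelihood over a log-spaced
    grid in [1e-6, 10] followed by golden-section refinement between the
    neighbours of the grid optimum.  Genes below ``min_cpm`` counts per
    million in every sample are excluded from estimation (standard low-count
    guard; they remain testable downstream).

    With ``tagwise=True`` per-gene dispersions are additionally estimated by
    maximising each gene's profile likelihood augmented with ``prior_weight``
    pseudo-genes at the common value — a simple shrinkage that stabilises the
    estimates at three replicates per condition.
    """
    keep = _cpm_filter(cm, min_cpm)
    if not keep.any():
        raise ValueError("no genes pass the low-count filter; is the matrix all zero?")
    y = cm.counts.to_numpy(dtype=float)[keep]
    t_mask = (cm.conditions == cm.treatment).to_numpy()
    s = cm.library_size.to_numpy(dtype=float)
    y_t, y_r, s_t, s_r = y[:, t_mask], y[:, ~t_mask], s[t_mask], s[~t_mask]

    grid = np.logspace(np.log10(_ALPHA_FLOOR), np.log10(_ALPHA_CEIL), grid_size)
    lls = np.array([_profile_loglik(a, y_t, y_r, s_t, s_r) for a in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    common = _golden_max(lambda a: _profile_loglik(a, y_t, y_r, s_t, s_r), np.log(lo), np.log(hi))

    tw = None
    if tagwise:
        # weighted-likelihood shrinkage: each gene's profile likelihood is
        # augmented with `prior_weight` pseudo-genes behaving like the average
        # gene, pulling noisy per-gene estimates toward the common value
        per_gene_ll = _per_gene_profile(y_t, y_r, s_t, s_r)
        alphas = np.logspace(np.log10(_ALPHA_FLOOR), np.log10(_ALPHA_CEIL), grid_size)
        n_est = y.shape[0]
        mat = np.stack(
            [per_gene_ll(a) + prior_weight * _profile_loglik(a, y_t, y_r, s_t, s_r) / n_est for a in alphas]
        )
        tw = pd.Series(alphas[np.argmax(mat, axis=0)], index=cm.feature_ids[keep])
    return DispersionEstimate(common=common, tagwise=tw, n_genes_used=int(keep.sum()))


def _per_gene_profile(y_t, y_r, s_t, s_r):
    def f(alpha: float) -> np.ndarray:
        return _group_apl(y_t, s_t, alpha) + _group_apl(y_r, s_r, alpha)

    return f


def _golden_max(f, log_lo: float, log_hi: float, tol: float = 1e-4) -> float:
    """Golden-section maximisation of f(exp(x)) on [log_lo, log_hi]."""
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = log_lo, log_hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = f(np.exp(c)), f(np.exp(d))
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(np.exp(d))
    return float(np.exp((a + b) / 2.0))


def nb_lrt(cm: CountMatrix, dispersion: DispersionEstimate | float) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of condition effect.

    Returns a DataFrame indexed by feature id with columns ``layer``,
    ``log2fc`` (treatment minus reference, offset-normalised), ``lrt_stat``,
    ``p_value``, ``fdr`` and ``passes`` (the latter two filled by
    :func:`adjust_bh` / :func:`call_rna_degs`; here fdr is NaN).

    Genes with zero counts in both groups are reported with p = 1 and
    log2fc = 0.  When one group is all zero the fold change is computed with
    half a pseudo-count on each group total so it stays finite; the p-value
    is untouched.
    """
    if isinstance(dispersion, DispersionEstimate):
        alpha_vec = dispersion.per_gene(cm.feature_ids)
    else:
        alpha_vec = np.full(len(cm.feature_ids), float(dispersion))
    if np.any(alpha_vec <= 0):
        raise ValueError("dispersion must be positive")

    y_t, y_r, s_t, s_r = cm.group_arrays()
    n_genes = y_t.shape[0]
    lrt = np.zeros(n_genes)
    log2fc = np.zeros(n_genes)
    pvals = np.ones(n_genes)

    # group genes by identical alpha to keep the fits vectorised
    for alpha in np.unique(alpha_vec):
        rows = np.flatnonzero(alpha_vec == alpha)
        yt, yr = y_t[rows], y_r[rows]
        q_t = _fit_group_mean(yt, s_t, alpha)
        q_r = _fit_group_mean(yr, s_r, alpha)
        ll_full = _nb_loglik(yt, q_t[:, None] * s_t[None, :], alpha) + _nb_loglik(
            yr, q_r[:, None] * s_r[None, :], alpha
        )
        y_all = np.concatenate([yt, yr], axis=1)
        s_all = np.concatenate([s_t, s_r])
        q_0 = _fit_group_mean(y_all, s_all, alpha)
        ll_null = _nb_loglik(y_all, q_0[:, None] * s_all[None, :], alpha)
        stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)

        both_zero = (yt.sum(axis=1) == 0) & (yr.sum(axis=1) == 0)
        qt_fc, qr_fc = q_t.copy(), q_r.copy()
        one_zero = ((q_t == 0) | (q_r == 0)) & ~both_zero
        if one_zero.any():
            qt_fc[one_zero] = (yt.sum(axis=1)[one_zero] + 0.5) / s_t.sum()
            qr_fc[one_zero] = (yr.sum(axis=1)[one_zero] + 0.5) / s_r.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(qt_fc) - np.log2(qr_fc)
        fc[both_zero] = 0.0
        stat[both_zero] = 0.0

        lrt[rows] = stat
        log2fc[rows] = fc
        pvals[rows] = np.where(both_zero, 1.0, chi2.sf(stat, df=1))

    return pd.DataFrame(
        {
            "layer": "rna",
            "log2fc": log2fc,
            "lrt_stat": lrt,
            "p_value": pvals,
            "fdr": np.nan,
            "passes": False,
        },
        index=cm.feature_ids.rename("feature_id"),
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through as NaN."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_rna_degs(records: pd.DataFrame, thresholds: DEThresholds = DEThresholds()) -> pd.DataFrame:
    """Apply the transcript decision rule (inclusive boundaries).

    Adds/updates ``fdr`` (if absent), sets ``passes`` and returns the passing
    subset with a ``direction`` column in {"up", "down"}.
    """
    rec = records.copy()
    if rec["fdr"].isna().all():
        rec["fdr"] = adjust_bh(rec["p_value"].to_numpy())
    passes = (rec["log2fc"].abs() >= thresholds.rna_lfc) & (rec["fdr"] <= thresholds.rna_fdr)
    rec["passes"] = passes.fillna(False)
    out = rec[rec["passes"]].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out
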