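# Methods

## Count model and the likelihood-ratio test

Per gene *g* and sample *j* the count is negative binomial,
Y ~ NB(μ, α) with Var(Y) = μ + αμ² and μ = s_j · q_c(j), where s_j is the
sample's library-size factor (column sum by default, overridable) and q_c
the relative abundance of the sample's condition.  The full model fits one
q per condition, the null model a single q; the statistic
2(ℓ_full − ℓ_null) is referred to χ²(1).  Each q is found by Newton
iteration on η = log q using the NB score Σ(y − μ)/(1 + αμ) and Fisher
information Σ μ/(1 + αμ); with equal size factors the first iteration lands
exactly on the group mean.  The reported effect is
log₂FC = log₂(q_treatment / q_reference).

Normalisation is by library-size offsets only (no TMM-style factor): it
keeps the likelihood self-contained and checkable against a brute-force
grid maximisation of the same likelihood, which the tests do on all small
two-versus-two instances.

**Dispersion.**  A single α shared across genes is estimated by maximising
the summed Cox–Reid adjusted profile log-likelihood (subtracting
½·log of the Fisher information of each fitted group mean) over a 25-point
log-spaced grid on [1e-6, 10] with golden-section refinement between the
grid optimum's neighbours.  The adjustment matters: the naive profile
likelihood is biased low by roughly a third at three replicates per
condition because each gene spends one degree of freedom per group on its
mean.  Genes below 1 count per million in every sample are excluded from
estimation (they remain testable).  Optional tagwise estimates maximise the
per-gene adjusted likelihood augmented with 10 pseudo-genes at the common
behaviour, a weighted-likelihood shrinkage that is stable at n = 3; the
common value is the default because three replicates carry little per-gene
information.

**Degenerate inputs.**  Genes with zero counts in both groups are reported
with p = 1 and log₂FC = 0.  When exactly one group is all zero the p-value
is untouched but the fold change is computed with half a pseudo-count on
each group total so it stays finite.  Identical replicates everywhere drive
the profile likelihood to the α → 0 boundary; the grid floor (1e-6) is
returned.

## Protein and peptide tests

Protein log₂ abundance per channel is the unweighted mean of the protein's
*unmodified* peptide intensities (median available behind a flag); modified
peptides are excluded from the rollup so a stoichiometry shift in one
phosphopeptide does not masquerade as a total-abundance change.  The
two-condition comparison is the classic equal-variance Student's *t*
(df = n₁ + n₂ − 2); with three channels per condition Welch's correction
would cost more in degrees of freedom than it buys in robustness.
Zero-pooled-variance cases return p = 1 when the means agree and the
smallest positive float when they differ, flagged rather than hidden.

Peptide-level PTM tests reuse the same t machinery at p ≤ 0.1.  Oxidation
"prevalence" is operationalised as the oxidized peptide's own abundance
test; an oxidized/unmodified ratio mode would need the matched unmodified
peptide for every oxidized row, which real search output frequently lacks.
Among peptides significant at p ≤ 0.05 the summary reports the fraction
with a positive log₂FC (more oxidized in flight).

Protein inference applies the reportability rule literally: at least two
*distinct* peptides with ion score strictly greater than 20.  A score of
exactly 20 does not count; the rule is monotone in added peptides
(property-tested).

## Artifact-exclusion rule

For a candidate significant in a control study, with fold changes LFC_SF
(spaceflight) and LFC_control (that control):

retain ⇔ |LFC_SF − LFC_control| > |LFC_control| or |LFC_SF| > |LFC_control|.

The range of two scalars is max − min, so its magnitude is the absolute
difference.  Inequalities are strict: a candidate identical to its control
response is excluded.  A candidate significant in several control studies
must pass against each (conjunction); one absent from every control list
passes vacuously.  The rule is scale-invariant and satisfies
passes(x, 0) = true for x ≠ 0 and passes(x, x) = false — both are enforced
as property tests, and the implementation is checked exhaustively against a
literal transcription of the formula on an 81×81 grid.

## Overlap statistic

The overlap of k transcript candidates and n protein candidates (pooled
over fractions, duplicates collapsed) in a genome of N genes is evaluated
with the hypergeometric distribution computed in log-gamma space.  Two
modes share one kernel:

* **point** — P(X = x), the default, which reproduces the published
  convention for this analysis (at N = 27000, k = 968, n = 210 it yields
  0.036 at x = 12 and 9.7e-4 at x = 17);
* **tail** — P(X ≥ x), the statistically conventional over-representation
  p-value, recommended for new analyses and used by the GO module.

Numerics: point masses are exact to ~1e-15 relative at small N; at genome
scale the log-gamma route carries ~1e-9 absolute rounding (the support-wide
sum deviates from 1 by that much), far below any decision threshold in use.
Sign concordance of an overlapping locus uses the protein fraction with the
smaller p-value when the two fractions disagree in sign.

## GO enrichment and thinning

Annotations are propagated by the true-path rule (a gene annotated to a
term is annotated to all its is_a ancestors; idempotent).  Per term the
upper-tail hypergeometric is computed with population = background size;
Bonferroni multiplicity is the number of terms with at least one DE
annotation, because a term with zero hits cannot reject and is not a test.
Thinning applies, in order: corrected p ≤ 0.05; background term size in
[4, 750]; more than one DE gene; within each branch (the subtree under each
direct child of the biological_process root) the two surviving terms of
minimal depth (shortest is_a distance to the root; ties broken by smaller
p, then lexicographic id); and among terms annotating an identical DE-gene
set, only the deepest.  "Branch" and "distance" are interpretations —
neither has a canonical definition — and both are configurable; the
"similar naming" half of the redundancy criterion is not formalizable and
is deliberately not implemented (identical gene sets alone trigger the
collapse).  Each dropped term records the first rule that removed it, so a
report is auditable.  Up- and down-regulated lists run separately.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure of the emulated
design: a 27,000-gene genome, 3 + 3 samples, two protein fractions of
~1,300 quantified proteins each, peptide ion scores around the
reportability bar, and two control studies overlapping the treatment DE
set.  Defaults:

| parameter | default | rationale |
|---|---|---|
| baseline_log_mean / sd | 4.5 / 1.2 (ln scale) | detected genes in bulk RNA-seq: median ≈ 90 counts, ~3 orders of magnitude spread |
| dispersion α | 0.1 | biological CV ≈ 0.32, typical for replicated bulk tissue |
| library_size_sd | 0.2 | ±20% log-normal depth variation exercises the offsets |
| frac_de | 0.036 | ≈ 970 spiked genes in 27,000 |
| spiked \|log₂FC\| | 1 + Exp(1) | all spiked genes clear the DE threshold; mean 2, matching the magnitude range of published DE tables |
| rna_protein_coupling | 0.3 | protein-level confirmation of an RNA effect is the exception, not the rule |
| discordant_fraction | 5/17 | the observed share of opposite-sign protein effects |
| protein_noise_sd | 0.2 | free parameter (replicate-level iTRAQ channel variance is not published); chosen so protein effects of 0.3–1.0 are detectable but not trivial at n = 3 |
| oxidation_up_fraction | 0.79 membrane / 0.12 soluble | the reported asymmetry of significant oxidation shifts |
| control_frac / overlap | 0.02 / 0.27 | ≈ 540 control-affected genes, ≈ 27% drawn from the treatment DE set (matching the reported ~260/968 overlap), with identical/attenuated/inflated effects (×1, ×0.5, ×1.5) |

Spiked condition means split the fold change symmetrically
(±log₂FC/2) so the group means differ by exactly the true effect.  Each
generator draws from its own RNG stream spawned from the master seed at a
fixed key, so adding a generator never perturbs the others and identical
configurations give byte-identical outputs.

What the simulator does **not** model: raw reads or spectra, isobaric
interference and ratio compression, peptide-level missingness, correlated
genes or shared pathways, multi-factor designs, batch effects.  Passing
tests therefore demonstrate the *statistical* correctness and calibration
of the pipeline under its own model, not performance on any particular
real dataset; in particular the published candidate counts (968 transcripts,
107 + 103 proteins) depend on the deposited raw data and are not
reproduced here — the fixtures carry the published *tables*, and the
simulations carry calibration checks instead.

## Problem sizes and tolerances

Simulation-based checks use 3,000–10,000 genes and 600–2,000 proteins,
sizes at which binomial standard errors make the bands meaningful (e.g.
null type-I error 0.05 ± 3√(0.05·0.95/5000)) while the whole suite runs in
well under a minute.  Calibration assertions use 3–4 standard-error bands;
exact oracles (grid-search likelihood, combinatorial enumeration, literal
formula transcription) are matched to 1e-4 or better.  The documented
regression bound for the DE stage is ≥ 70% spiked-gene recall at FDR ≤ 0.05
under the default simulation; at dispersion 0.2 the three-replicate design
caps recall near 55% regardless of depth, which is a property of the
design, not of the implementation.

## Known limitations

* The NB-LRT is a self-contained stand-in for an edgeR-style GLM pipeline:
  no TMM normalisation, no trended dispersion, no quasi-likelihood.
* Whether the published peptide tests used channel intensities or ratios to
  a pooled reference is not stated; intensities are used here.
* The per-control conjunction in the artifact filter is an interpretation
  ("more or differently perturbed than either control"); a disjunction mode
  would retain strictly more candidates.
* The enrichment "branch" and "most informative" notions are proxies
  (root-child subtrees; deepest term), configurable but not canonical.
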