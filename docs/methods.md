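# Methods

This note documents the models, conventions and numerical choices behind
`coldnet`, in the order the pipeline runs them, together with what the
synthetic-data generators do and do not emulate.

## Study design emulated by the simulators

The toolkit targets data with the structure of a multi-genotype stress
experiment: 10 *Arabidopsis thaliana* ecotypes (Cvi, Kas-1, Kyo-2, Sha,
Col-0, Kond, C24, Ler, An-1, Eri — used as default condition names),
each measured under control and cold treatment with 3 biological
replicates, on the log2 intensity scale. Expression values stay on the
log2 scale everywhere; no reader, writer or simulator exponentiates.

`simulate_ecotype_experiment` draws per-gene baselines from
Normal(8, 1.5) log2 units and adds ±`effect_size` (default 2.0 log2
units) to the treated samples of responding genes, plus
Normal(0, `noise_sd`) replicate noise (default 0.3). A `de_fraction` of
genes responds in at least one ecotype; 75% of responders (the
`unique_fraction` default) respond in exactly one ecotype, the rest in
2–4. Defaults were chosen so that desk-scale runs have non-degenerate
power at n = 3 replicates: a 2.0 log2-unit shift against sd 0.3 is
detected essentially always, while null genes reject at the nominal
rate.

What the generator deliberately does **not** model: probe-level effects,
background intensity, array normalization artifacts, gene–gene
correlation, and heteroskedastic noise. Passing tests therefore
demonstrate correctness of the statistical machinery under its
assumptions (independent Gaussian log-scale noise, balanced design),
not robustness to microarray-specific artifacts.

## Differential expression

Per ecotype, cold-responsive genes are called by a two-sided two-sample
t-test on log2 values, treated vs control, at raw p < alpha (default
0.01). The pooled-variance (Student) form is the default — the
conventional choice at n = 3 per group — with Welch available via
`equal_var=False`. No multiple-testing correction is applied to DE
calls (the emulated workflow thresholds raw p-values); the
over-representation stage corrects by Bonferroni (default) or
Benjamini–Hochberg. Degenerate convention: if both groups have zero
variance, p = 1 when the means agree and 0 otherwise.

Genotype-dependent responses use the genotype × treatment interaction of
a two-way fixed-effects ANOVA. Balance (every cell present with equal
replicate count ≥ 2) is required rather than approximated; on a balanced
design the type-I/II/III sums of squares coincide, so the closed-form
cell-mean decomposition is used, vectorized across genes. The test suite
cross-checks it per gene against `statsmodels.anova_lm`.

The core transcript set for network inference keeps genes significant in
at least `min_ecotypes` (default 2) ecotypes, ranked by the minimum
p-value across ecotypes (the ranking is a package decision; ranking by
maximum |log2fc| is available via `rank_by="max_fc"`), truncated to
`max_core`, and partitioned into TFs and targets by an external TF list.

Ecotype clustering uses 1 − Pearson correlation between fold-change
columns with average linkage (UPGMA); bootstrap support resamples genes
with replacement and counts, per internal node, the fraction of
replicate trees reproducing the same leaf set (branch lengths ignored).
Degenerate resamples with a constant column are skipped, as they carry
no topology information.

## Network component analysis

The log-linear activity model gives the bilinear form `E = C T` with the
support of `C` constrained to the candidate connectivity `Z0`. The
solver is two-step (alternating) least squares:

1. given `T`, each gene row of `C` is an ordinary least-squares problem
   restricted to that row's allowed TFs (rows sharing a support mask are
   solved in one batched call; a singular within-row Gram matrix falls
   back to the minimum-norm `lstsq` solution and flags the gene);
2. given `C`, `T = argmin ‖E − C T‖` in one least-squares solve.

Both half-steps are exact minimizations, so the Frobenius residual is
non-increasing — recorded per full iteration and asserted by tests.
Iteration stops when the relative residual change drops below `tol`
(default 1e-6) or after `max_iter` (500). `n_restarts` (default 10)
independent standard-normal initializations of `T` are run and the
smallest final residual kept. Note `tol` bounds the residual *change*;
benchmarks that assert the residual itself (noiseless recovery to 1e-8
relative) tighten `tol` to 1e-12.

Identifiability: criterion (a) full generic column rank of `C`,
criterion (b) rank preserved after removing any single TF together with
every gene it regulates, criterion (c) `M ≥ L`. Generic rank is
evaluated by instantiating the support with random values (5 trials;
the generic rank equals the maximum over trials with probability 1).
In strict mode (default) a non-compliant pattern is refused; relaxed
mode proceeds and stamps the result non-identifiable.
`reduce_to_compliant` greedily removes TFs — the lowest-support TF under
a (c) violation, the lowest-support failing TF under (a)/(b), ties
lexicographic — dropping genes left without regulators, until the
criteria pass.

The diagonal scaling ambiguity `C S, S⁻¹ T` is resolved by scaling each
column of `C` to unit Euclidean norm with its largest-magnitude entry
positive (the convention is arbitrary; every downstream correlation-
based step is invariant to it up to sign). Normalization is idempotent
and leaves `C T` unchanged to machine precision. A configuration with
many more TFs than conditions (e.g. 178 TFs against 10 ecotype
conditions) necessarily fails criterion (c); the checker reports this
rather than guessing a workaround, and the pipeline reduces to a
compliant sub-network before fitting.

The estimator `NetworkComponentAnalysis` follows scikit-learn
decomposition conventions (NMF-like): `fit_transform(X)` returns `C`,
`activities_`/`components_` hold `T`, and `get_params`/`set_params`/
`clone` work for pipeline and model-selection composition.

## Network reconstruction and activity calls

Candidate edges are Pearson correlations between each inferred TF
activity row and each gene's expression (fold-change) row across
conditions; p-values come from the t transform with M − 2 degrees of
freedom and are reported but not used for filtering. Self pairs (TF
correlated with its own transcript) are excluded from edge candidates by
default (`exclude_self=False` to keep them); the TF's activity–
expression relationship is instead reported by the classification step.
Edges keep |r| ≥ 0.8 **inclusive**; activation iff r > 0. TF
activity-vs-own-expression classification uses |r| > 0.5 **strict**
(r = 0.5 exactly is "low"). Per-ecotype activity calls standardize each
TF row to mean 0, sd 1 (sample sd) and call z ≥ 1; a TF active in
exactly one ecotype is flagged ecotype-specific. Because Pearson r is
scale-invariant, the network is invariant to the NCA scaling ambiguity;
a sign flip of an activity row flips its edge signs together with the
activity — the normalization convention pins this down.

## Graph topology

All summary metrics use the undirected simple-graph convention
(parallel/antiparallel edges merged, self-loops dropped, both counted
and reported alongside the raw edge count so either convention is
inspectable). Clustering is the mean over all nodes of
2·triangles/(deg·(deg−1)), zero for degree < 2. Path length is the mean
shortest-path distance pooled over connected ordered pairs (infinite
distances excluded, not imputed); the diameter is the maximum finite
eccentricity across components. The power-law fit is descriptive least
squares of log10 P(k) on log10 k over observed degrees — the display
convention — not a maximum-likelihood exponent.

## Polymorphism statistics

Columns containing a gap, an N, or any symbol outside A/C/G/T are
eliminated before analysis (conservative reading of the usual
complete-deletion rule). π is reported per alignment by default
(`per_site=True` divides by the analyzed length; D is scale-free and
unaffected). Tajima's D uses the standard coefficients a1, a2, b1, b2,
c1, c2, e1, e2 determined by n alone. With S = 0 the statistic is
undefined and returned as NaN with status
`undefined_no_segregating_sites` — never silently 0. For n < 4 the
variance coefficients vanish identically (c1 = c2 = 0), so D is likewise
undefined (`undefined_zero_variance`) and a warning recommends n ≥ 4.

The alignment generator places single-hit mutations: each of S chosen
columns flips to one alternative base in a uniform random nonempty
proper subset of sequences, guaranteeing exactly S segregating sites.
This subset-size-uniform spectrum is *flatter* than the coalescent's
1/i frequency spectrum, so D under this generator is centred slightly
above zero (measured mean ≈ +0.73 at n = 10, L = 500, S = 25; the test
suite freezes 0.60–0.90 as a regression band). The generator validates
the D machinery, not coalescent theory; genuinely neutral expectations
would require a coalescent simulator, which is out of scope here.

## Pipeline, determinism and problem sizes

`run_pipeline` executes simulate → DE → core selection → connectivity
reduction → NCA → correlation network → topology, materializing every
intermediate with sha256 checksums and persisting the resolved
configuration; identical config + seed gives byte-identical outputs.
Every generator derives independent sub-streams as
`default_rng([seed, stream])`, so adding one draw never perturbs
another stage.

Default problem sizes (192 target genes, 8 TFs, 10 ecotypes × 2
treatments × 3 replicates, out-degree 25, noise sd 0.3, activity
blocks of 1–3 ecotypes at +2.0) were chosen as the smallest
configuration in which every stage is non-degenerate: the activity
matrix can have full row rank (L ≤ M), the DE stage has realistic power,
and the reconstructed network has enough edges for meaningful topology.
Benchmark sizes used by the validation suite are 50 × 5 × 12 (noiseless
recovery) and 100 × 8 × 20 at noise sd 0.2 over 10 seeds (noisy
recovery, median per-TF |r| ≥ 0.9 frozen as a regression bound).

## Known limitations

* The ANOVA stage requires exact balance; missing cells abort rather
  than fall back to an approximate decomposition.
* The NCA solver is a local optimizer; restarts make the noiseless
  benchmarks reliably hit the global optimum at these sizes, but no
  global guarantee exists for arbitrary patterns.
* Bootstrap clade support is a topology-frequency measure on leaf sets;
  it is not a posterior probability.
* The hypergeometric enrichment treats terms independently (no ontology
  DAG propagation).
* The popgen stage consumes pre-aligned sequences; alignment itself and
  sliding-window scans are out of scope.
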