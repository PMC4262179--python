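# Methods

Statistical models, algorithms, parameter defaults and numerical choices
used by `contactzone`.

## 1. Geometric morphometrics

### Generalized Procrustes analysis (`shape.gpa`)

Each landmark configuration X (k landmarks × 2) is centred and scaled to
unit **centroid size** CS(X) = sqrt(Σᵢ ‖xᵢ − x̄‖²). Configurations are then
rotated onto an iteratively re-estimated consensus using the optimal
*proper* rotation (SVD of the cross-product matrix with the determinant
sign corrected, so reflections are never introduced). The consensus is the
normalised mean of the aligned configurations.

Numerical choices:

- **Orientation anchoring.** After each update the new consensus is rotated
  onto the previous one before measuring the change. Without this the whole
  configuration set can rotate jointly by a tiny angle per iteration, and a
  plain difference norm never reaches tolerance even though the shapes have
  converged.
- Convergence tolerance `tol = 1e-10` on the consensus change,
  `max_iter = 500`. Real morphometric data converge in < 10 iterations;
  isotropic-noise "shapes" with near-degenerate consensus can legitimately
  be slow, in which case a `RuntimeWarning` is raised and the current state
  returned with `converged=False`.
- After convergence, aligned shapes are projected orthogonally onto the
  tangent plane at the consensus μ: x ↦ x − (x·μ)μ.

Property guaranteed (and asserted in the tests): pairwise Procrustes
distances are invariant to arbitrary rotation/translation/scaling of the
inputs to better than 1e-8.

### Relative warps (`shape.relative_warps`)

Principal components of the Procrustes tangent coordinates (α = 0, uniform
and non-uniform components together), computed by SVD of the centred
tangent matrix. All axes with singular value above `s₁·1e-12` are kept, so
variance fractions sum to 1 and full-rank reconstruction is exact to
machine precision. Axis sign is fixed by making each axis's
largest-magnitude loading positive.

### Allometry correction (`shape.allometry_residuals`)

Per-axis ordinary least-squares regression of relative-warp scores on
centroid size; residuals (re-centred) are the size-corrected scores.
Pooled regression is the default; a per-group option exists. The per-axis
R² and slopes are reported so users can verify the size effect is small
(with the study-default generator it stays below 10% of score variance on
every axis).

## 2. Transgression analysis (`transgression`)

For hybrid sample H and pooled parental sample P on one axis:

```
ext%(H, P) = 100 · [max(0, max H − max P) + max(0, min P − min H)] / (max P − min P)
```

`bootstrap_transgression` reports the **median of B = 500 bootstrap
replicates**, each resampling n = 50 hybrids with replacement against the
fixed parental sample (a `resample="parent"` variant resamples parents
instead).

### Significance: permutation, not bootstrap support

The naive significance measure — the fraction of hybrid bootstrap
replicates with a positive extension ("bootstrap support") — is **not a
calibrated test**: when hybrids and parents are drawn from the same
distribution, roughly a quarter of axis-cells reach support ≥ 0.95,
because sample extrema of an i.i.d. resample frequently poke past the
extrema of a different finite sample, and there is no null reference that
could correct for it (parental resamples can never extend the parental
range by construction).

The default significance is therefore a **group-label permutation test**:
the observed full-sample extension is compared with its distribution under
B random reassignments of the hybrid/parent labels, and
p = (1 + #{null ≥ observed}) / (B + 1), with support = 1 − p. Measured on
200 null datasets this gives a false-positive (support ≥ 0.95) rate of
about 0.03, and power of roughly 0.7–1.0 for hybrids with 1.5–2× the
parental spread. The literal bootstrap-support reading remains available
via `significance="bootstrap_support"` for comparison.

Stars: `*` support ≥ 0.95, `**` ≥ 0.99, `***` ≥ 0.999.

Note on estimands: the bootstrap median systematically *attenuates* the
full-sample extension (a size-n resample usually misses the most extreme
hybrids), so recovery of an injected extension is assessed on the
full-sample statistic; the bootstrap median is reported alongside it.

### Reproducibility

Each (axis, hybrid-group) cell derives its RNG stream from
`SeedSequence([seed, axis_index, crc32(group)])`, so tables are
reproducible and independent of the order in which cells are computed.

## 3. Population genetics (`popgen`)

- **Site filtering** removes every alignment column containing anything
  other than A/C/G/T (gaps, N, IUPAC ambiguity codes), keeping the
  remaining columns' order. Idempotent.
- **Haplotype collapsing** groups identical (case-insensitive) filtered
  sequences; haplotypes are labelled H1, H2, … in order of first
  appearance.
- **Minimum-spanning network**: Kruskal's algorithm on the pairwise
  Hamming-distance matrix with deterministic (weight, id-pair)
  tie-breaking; non-tree pairs whose distance equals the bottleneck
  (maximum edge weight) on their tree path are reported as *alternative
  edges*, which together with the tree are invariant to input order even
  when tied weights make the tree itself non-unique.
- **RFLP typing**: a sequence is `cut` if it contains the recognition
  motif (default HpaI, `GTTAAC`). If an N/gap falls in any window that
  could complete the motif, the call is indeterminate and an
  `AmbiguousSequenceError` is raised rather than guessing.
- **FST**: Weir & Cockerham's (1984) multiallelic θ, summing the a/b/c
  variance components over alleles and loci; per-locus complete-case
  handling of missing (0-coded) alleles; loci monomorphic across the pair
  are rejected. Significance by permutation of individuals between the two
  populations with the add-one rule p = (1 + hits)/(n_perm + 1).
  Hand-worked oracle: pops {(1,1),(1,2)} vs {(2,2),(2,2)} give θ = 2/3
  exactly; a fixed difference gives θ = 1.

## 4. Mate choice (`matechoice`)

- **Exclusion paternity**: a fry is compatible with a (mother, candidate)
  pair at a locus iff one fry allele occurs in the mother and the other in
  the candidate; a missing allele (0) makes the locus uninformative. A
  candidate survives if it fails at ≤ `mismatch_tolerance` loci (default
  0). Exactly one survivor → assigned; several → ambiguous; none → a
  greedy two-sire split (largest per-fry-explicable block to the best
  candidate, remainder must be uniquely explicable) models multiple
  paternity, otherwise the brood is excluded.
- **Assortment**: exact binomial tail on the count k of heterotypic
  matings among n assigned matings, computed in rational arithmetic
  (`fractions.Fraction`) and converted to float only at the end. The
  default alternative is the lower tail P(X ≤ k | n, p₀ = 1/2). Reference
  values: P(X≤1|11) = 12/2048 ≈ 0.0059, P(X≤1|9) = 10/512 ≈ 0.0195,
  P(X≤1|8) = 9/256 = 0.03515625 (a printed value of 0.0351 corresponds to
  truncation of this tail at four decimals).

## 5. Synthetic-data generators (`simulate`)

The generators emulate the *structure* of a secondary-contact study — a
common-garden cross design, a two-haplogroup mitochondrial alignment, a
structured microsatellite panel, and replicated mate-choice trials — with
known ground truth. They do not emulate the biology of any particular
lake: no linkage, no selection, no spatial structure, no genotyping-error
model beyond missingness/ambiguity injection.

### Landmarks (`MorphoSimConfig`, `gen_landmarks`)

Shape variation lives in a fixed orthonormal basis of `n_axes = 6` tangent
directions orthogonal to the similarity transforms of a deterministic
fish-like base outline (`k = 25` landmarks). Per-axis score standard
deviations decay geometrically (`score_sd = 0.02` Procrustes units,
`sd_decay = 0.8`) so the generating axes map onto the leading relative
warps. Parental lines differ by `parent_separation = 0.02` on axis 1; F1
sits at the midpoint, backcrosses and F2 draw from the corresponding
parental mixtures. A configured true range extension
(`hybrid_transgression = {"RW3": 30.0, "RW5": 40.0}` in the F2) is
injected by affinely rescaling the realized F2 scores against the realized
pooled parental range, so the sample-level truth equals the target
exactly. Allometry (`allometry_slope = 0.15` score-sd per size-sd),
per-specimen rotation (±0.15 rad), size scaling (mean 250 px, sd 25),
translation and digitisation noise (sd 0.5 px) are applied afterwards.

### Sequences (`gen_sequences`, `gen_screen_sequences`)

Two haplogroup ancestors differ at `divergence_sites = 10` fixed positions,
one of which disrupts the `GTTAAC` motif carried by group A. Individuals
(105 + 105) add Poisson(1.0) private mutations away from diagnostic
positions; each individual's restriction phenotype is verified against its
haplogroup, with bounded regeneration on collision. Gap/N cells are
injected column-wise (`ambiguous_column_rate = 0.115` of the 403 columns)
away from diagnostic positions, so site filtering removes exactly those
columns. The screening panel is the same model with ambiguity disabled.

### Microsatellites (`gen_genotypes`)

Balding–Nichols model: per-locus population allele frequencies are
Dirichlet(p·(1−F)/F) draws around an ancestral Dirichlet(1) vector, with
`target_fst = 0.15` across four populations of 50; genotypes are two
independent draws per locus.

### Mate choice (`gen_matechoice`)

Per replicate (4 total): 3 males per lineage, 6 females per lineage; each
female mates within her lineage with probability `assortment = 0.8`,
choosing uniformly among that lineage's males; 8 fry per brood inherit one
maternal and one paternal allele per locus at 5 loci with 8 alleles drawn
from lineage-specific Balding–Nichols frequencies (F = 0.15).

All generators derive independent substreams via `numpy.random.SeedSequence`
spawn keys, so every output is bit-reproducible from a single seed, and
`simulate_run` writes a manifest of SHA-256 file hashes.

## 6. Limitations

- The transgression permutation test assumes exchangeability of hybrid and
  parental scores under the null; strong variance differences that do not
  extend the range can still register.
- The MSN reports one minimum spanning tree plus equal-bottleneck
  alternative edges; it is not a full median-joining network and infers no
  unsampled intermediate haplotypes.
- Weir–Cockerham θ is computed from complete cases per locus; heavy,
  non-random missingness will bias it.
- The greedy two-sire split can under-count sires if more than two males
  fathered a brood, and cannot distinguish two compatible second sires.
- Generators draw alleles independently across loci and individuals; no
  linkage disequilibrium, mutation during the experiment, or null alleles.
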