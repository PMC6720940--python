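# Methods

## Model

Somatic single-nucleotide variants are classified into K = 96 channels: six
pyrimidine-centered substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each
in 16 flanking-base contexts. Variants whose reference base is a purine are
mapped by reverse complement, so the classification is strand-symmetric.
Canonical order is substitution class first, then 5′ flank, then 3′ flank
(A, C, G, T), giving index 0 = `A[C>A]A` through index 95 = `T[T>G]T`.

The additive model assumes each mutational process n contributes mutations
independently with channel distribution P·ₙ (column n of the signature
matrix), so the expected catalogue is a mixture P e. The exposure estimate is
the constrained least-squares solution

    e = argmin ‖m − P e‖₂,  e ≥ 0,

with m the catalogue as frequencies. Two constraint modes are offered:

- `simplex` (default): additionally Σ e = 1, so exposures are proportions of
  the mutational load directly. This matches how exposures are reported in
  practice (percentages of a sample's mutations).
- `nonneg`: only e ≥ 0 (the literal model above); proportions are obtained
  by renormalizing the minimizer. Its optimum can only be at least as good
  as the simplex optimum (larger feasible set), a relation the tests check.

`residual_norm` is always the objective value at the constrained minimizer
(in simplex mode the minimizer already sums to 1, so the two readings of the
field coincide).

## Solvers and numerical choices

- `nonneg` uses the exact active-set NNLS of scipy.
- `simplex` is a quadratic program over the probability simplex, solved with
  SLSQP (analytic gradient, ftol 1e-14) followed by an exact KKT refinement:
  the apparent active set of the SLSQP solution is frozen and the
  equality-constrained least-squares problem on the free coordinates is
  solved linearly; the refined point is kept when feasible and better. On
  random 2- and 3-signature instances the result is verified against
  exhaustive simplex grids (step 1e-3) to within 1e-6 in the objective.
- Solver negatives below 1e-10 are clipped to zero (and the simplex solution
  renormalized). Near-degenerate optima — a Gram-submatrix eigenvalue below
  1e-12 on the support of the solution — are flagged (`degenerate=True`)
  rather than perturbed: redundancy among published signatures is a studied
  feature, not an error.
- Fitting an empty catalogue is an error; a catalogue with fewer than 125
  mutations triggers `LowCountWarning` (also from the bootstrap), the
  threshold below which per-channel counts are too sparse for stable
  refits.

## Catalogue construction from VCF

Each biallelic SNV record contributes one count to one channel, derived from
the reference trinucleotide around the site (pyfaidx lookup, soft-masked
bases uppercased — masking is annotation, not sequence). Records are skipped,
with per-reason counts kept in the catalogue's provenance, when they are not
single-base SNVs, are multiallelic, fail FILTER (only with `--pass-only`;
by default FILTER is ignored because its semantics vary across callers), or
lack a clean A/C/G/T trinucleotide context (sequence edges, gap-adjacent
sites) — the latter with a warning rather than an error, since such sites
are expected in real references. A VCF REF base that disagrees with the
FASTA is a hard error: it signals a coordinate or reference-version mismatch
that would silently corrupt every channel assignment. Genotype columns are
ignored; sites are taken as listed, one catalogue per file.

## Trinucleotide baselines and normalization

A signature matrix is calibrated to the trinucleotide availability of the
region it was learned on (for COSMIC: the GRCh37 whole genome). A catalogue
observed on different regions (an exome capture) sees each context c in
proportion to its local availability f(c). Since expected channel counts
scale with context availability, data observed on baseline A are re-expressed
on baseline B by multiplying channel k by f_B(c(k)) / f_A(c(k)) and
renormalizing; the identical per-channel scaling, applied column-wise with
per-column renormalization, moves a signature matrix between baselines. The
three substitution classes of a context share one ratio. This direction
follows from the availability argument; because the opposite convention also
circulates in informal descriptions, an `invert_ratios` flag applies the
reciprocal ratios for comparison, and the round-trip/transitivity identities
(A→B→A = id, (A→B)∘(B→C) = (A→C)) pin the semantics down in the tests.
A context with zero source frequency is an error only where the data are
nonzero; zero-count channels pass through as zero, so restriction to
sub-genomes cannot poison unrelated channels.

Counting: a 3-mer is attributed to its **central** base; when regions are
given, the central base must lie inside the (merged) regions while flanks
may extend one base beyond the boundary — edge mutations still have real
genomic contexts. Overlapping BED intervals are merged first so overlapping
capture targets are not double counted. Purine-centered 3-mers count toward
their reverse complement, yielding 32 collapsed contexts; 3-mers containing
non-ACGT letters are ignored.

## Bootstrap

Resampling the n observed mutations with replacement is, at the channel
level, exactly a multinomial draw of size n with probabilities m/n; the
implementation draws multinomials rather than resampling VCF records, which
is equivalent under the channel model and far cheaper. Totals are preserved
by construction. One seed governs a whole summary (the R resamples are drawn
in a single generator stream), so summaries are bit-reproducible.
Quartiles use linear interpolation between order statistics (numpy default,
"type 7"); conventions differ between tools, so the choice is recorded here.
The summary reports, per signature: the point estimate of the original
catalogue and min / Q1 / median / Q3 / max of the R resampled estimates; the
plot marks the original estimate with a star over per-signature boxes.

## Simulator

`create_mut_catalogues` draws each catalogue as an independent multinomial
of size n from q = P w, for user-given mixture weights w over a subset of
signatures. Defaults follow the standard benchmark design: n = 1000
mutations per catalogue and equal weights of 0.2 over five signatures (the
named SET1/SET2 subsets of COSMIC v2 select five mutually distant and five
mutually similar signatures respectively; the simulator takes explicit
lists, as one historical description of the distant set swaps signature 27
for 28). `null_catalogues` draws mutations with probability proportional to
context availability and splits each context's mass equally over its three
substitution classes — the availability argument constrains only the context
marginals, and the equal split is the maximum-entropy completion consistent
with "no process-specific signal". `prediction_error_curve` reports, per
catalogue size, the mean over replicates of the sum of squared differences
between true and estimated proportions, taken over the **full** signature
set (absent signatures contribute their squared estimated exposure).

`synthetic_signature_matrix` builds test signatures: disjoint uniform blocks
(orthogonal, the easiest possible refit) optionally blended with a shared
random background (`overlap`), which reproduces qualitatively the
instability of redundant signature sets. It emulates the *geometry* of
signature matrices, not their biology: real signatures have heavy-tailed,
correlated profiles, so green tests on synthetic matrices establish solver
and pipeline correctness, not biological fidelity of any particular
signature call.

## What the tests establish

The unit and property suite runs entirely on synthetic and hand-tallied
inputs: channel bijections, strand-collapse involutions, conservation laws,
brute-force grid optimality of the QP, multinomial moment checks, and
determinism contracts. Checks of published numbers (COSMIC v2 redundancy
diagnostics, published patient catalogue totals, genome/exome baseline
correlation, the normalization-direction calibration, and the null-catalogue
experiment on GRCh37 frequencies) require the third-party reference files
described in `data/README.md`, which cannot be redistributed with the
package; without them those acceptance tests fail by design rather than
silently skip.

## Limitations

- Single-base substitutions only: no doublet-base or indel channels, no
  transcription-strand or pentanucleotide contexts.
- Refitting against a fixed matrix only — no de novo signature discovery,
  no sparsity-inducing model selection.
- Percentile bootstrap ranges only (no BCa or studentized intervals).
- Below ~125 mutations the estimates are unstable; the package warns but
  does not refuse.
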