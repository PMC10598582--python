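# Methods

## Detection model

A column of an amino-acid alignment is a convergent amino acid
substitution (CAAS) between a foreground group FG and a background group
BG when the observed residue sets `U_FG` and `U_BG` (gaps `-` and
unknowns `X` excluded) satisfy `U_FG ∩ U_BG = ∅` with both non-empty, and
at least one of the sets is a singleton. The two conditions close over
exactly three patterns — P1 (both singletons), P2 (FG singleton only),
P3 (BG singleton only); the disjoint-but-both-polymorphic case is not a
CAAS. The classifier (`classify_chars`) is total over valid columns and
is the single code path used by discovery, by p-value randomization and
(in a bitmask-vectorized form, cross-checked against the scalar form by
randomized tests) by the bootstrap counter.

Missing data is controlled per group by four caps: `max_*_gaps` bounds
`-` symbols and `max_*_missing` bounds `X` symbols. The two are counted
separately because they reflect different alignment-quality problems
(indels vs unresolved residues). A column exceeding a cap is skipped; a
group left with no residue at all can never satisfy the monomorphism
condition, so an all-missing group is never a CAAS even when the caps
would admit it. Raising caps can only grow the detection set (tested as
a monotonicity property).

## Convergent-noise p-values

The per-position empirical p-value is the probability that a *random*
FG/BG assignment of the observed sizes, drawn without replacement from a
resampling pool, yields any CAAS pattern at the column under the same
tolerance caps. The pool defaults to FG ∪ BG — the conservative
label-permutation null — and can be widened to all alignment species.
When the number of distinct assignments is at most 10,000 the fraction
is enumerated exactly; otherwise it is estimated from `cycles` uniform
draws and reported as `(hits + 1)/(cycles + 1)`. The pseudocount keeps
Monte-Carlo p-values strictly positive and matches the bootstrap
convention below, so the two outputs are comparable; exact enumeration
reports the true fraction (which is 0 only for columns that are not CAAS
under any assignment, a case reachable only through the oracle API).

## Resampling modalities

*Naive*: each virtual group is a uniform draw without replacement from
the pool (default: all tree tips). This is the correct null for
quantifying convergent noise when species are treated as exchangeable.

*Phylogeny-restricted*: the virtual groups preserve the observed
per-clade composition — for each clade the virtual FG receives exactly
as many pool species of that clade as the observed FG holds, drawn
uniformly within the clade. Clade labels come from an explicit TSV
rather than a tree cut: which ranks count as "clades" is user knowledge
not derivable from branch lengths.

*Brownian motion (permulation)*: per iteration a trait is simulated
under BM on the tree restricted to the pool (child value = parent value
+ N(0, σ²·branch length), root at `root_value`), the observed trait
values are reassigned to species by matching simulated rank to observed
rank (largest simulated value receives the largest observed trait — an
exact bijection of the trait multiset), and the virtual FG is the
`|FG|` species at the extreme of the permuted trait on the side where
the observed FG lies, the virtual BG at the opposite extreme. The FG
side is inferred from the data: top if the observed FG trait mean is at
least the BG mean, else bottom. σ² defaults to 1 and is effectively
scale-free here because only ranks are consumed downstream. Ties in
simulated or observed values are broken by a seeded shuffle before
ranking, since rank-matching needs a total order.

Trees are used as written: the first node of the newick string is the
root (deterministic for any input). Midpoint rooting is available on
request (`read_tree(..., rooting="midpoint")`) rather than applied
automatically to basal trifurcations, because a trifurcating first node
is indistinguishable from a genuine root polytomy — e.g. a star tree —
and midpoint-rooting a star would corrupt the BM covariance structure.

A consequence of BM covariance worth knowing: on trees where an FG
member has a close sister, the sister is strongly over-represented in
virtual FGs *conditionally* (P(sister ∈ FG | member ∈ FG) far above the
exchangeable rate), while its marginal inclusion rate can even drop
slightly below the exchangeable rate, because a tight cherry behaves
like a single draw occupying at most one "slot" when it is not at the
very top. The test suite asserts the conditional effect.

## Bootstrap

For each column, `hits` counts the retained iterations whose virtual
groups yield any requested CAAS pattern; the reported p-value is
`(hits + 1)/(cycles + 1)`. Iterations naming species absent from the
alignment are dropped with a logged count (error if more than half);
iterations failing a tolerance cap at a column count as non-hits, since
"no CAAS observable" is exactly the event being counted. Rows are
emitted for every column by default, or only for `hits ≥ 1` with
`sparse`. Merging across alignments is pure concatenation keyed by
(alignment id, position); duplicates are an error.

### Calibration

Because the per-iteration statistic is a binary indicator, the bootstrap
p-value of a column concentrates around that column's intrinsic
convergence probability q (the fraction of assignments yielding a CAAS,
which depends only on its residue composition). Across random columns q
takes a discrete, bounded set of values, so the *distribution* of
bootstrap p-values over exchangeable columns is far from uniform and a
Kolmogorov–Smirnov test against the uniform rejects essentially always —
uniformity of a permutation p-value requires a continuous test
statistic, which a binary CAAS indicator is not. The guarantee that does
hold, and that the suite asserts, is the standard permutation-test
validity: when the observed groups are exchangeable with the resamples,
P(a column is detected as CAAS *and* its bootstrap p ≤ α) ≤ α for every
α. In other words the p-value is honest exactly where it is used — for
columns that were detected.

## Synthetic data

The fixture generator emulates the inputs the pipeline consumes: a
seeded Yule (pure-birth) topology with Exp(1) branch lengths and tips
`sp1..spN`; alignments with *planted* CAAS columns (FG/BG residues set
to classify as exactly the requested pattern; species outside the
groups receive distinct left-over residues so they add no spurious
monomorphism) over an iid-uniform or a uniform-exchange tree-evolved
background; missing symbols injected at a configurable rate outside
planted columns; and a BM trait with a ±`gap` shift for FG/BG, so
`gap = 0` gives exchangeable groups and a large `gap` puts FG exactly at
the top ranks.

In *strict* mode, background columns draw from residues {A..H} and
planted FG/BG states from {I..Y}, and — because alphabet separation
alone cannot prevent a background column from forming its own CAAS
within {A..H} — any background column that classifies as a CAAS for the
observed groups is redrawn (rejection sampling, typically a few percent
of draws). Under that construction plant-recovery is an exact set
equality, not a probabilistic statement. The planted-power condition
fixed in the tests uses 20 species with groups of 2+2, a 30-column
strict alignment and 500 naive cycles: the strict background alphabet
(7 letters over 20 species) makes every background column duplicate-rich
and hence noisy (q ≈ 0.1–0.2) while the planted column's q is ≈ 0.02, so
the planted column attains the minimum bootstrap p-value essentially
always. Uniform-exchange background evolution (resample uniformly with
probability 1 − e^(−t) along each edge) is deliberately not an empirical
substitution matrix: fixtures need a controllable null, not realism, and
none of these generators model indel evolution or site-rate variation —
passing tests show correctness of the machinery on exchangeable or
planted columns, not performance on real proteomes.

## Numerical and interface choices

Columns are 0-based in the library and 1-based in every output file
(stated in each file's comment header). All randomness flows through
`numpy.random.default_rng(seed)`; every seeded entry point is
bit-reproducible (asserted). Test and acceptance problem sizes —
200 oracle alignments, 10⁴ simulations for BM moments, 10⁴ resamplings
for uniformity, 10³ permulation checks, 100 power replicates at 500
cycles, 10⁴ columns for calibration — are chosen so each statistical
band is at least ~3–4 standard errors wide at that size. Sequential
PHYLIP support uses strict 10-character names; interleaved PHYLIP,
NEXUS and nucleotide alignments are out of scope, as are ΔSSLS-style
likelihood tests, ancestral-state reconstruction and dN/dS analysis.
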