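# caaskit

Detection and permutation-based validation of **Convergent Amino Acid
Substitutions (CAAS)** in orthologous protein alignments.

When distantly related species converge on a phenotype — long lifespans,
marine lifestyles, high-altitude tolerance — the genes involved sometimes
converge at the sequence level too. Given two user-defined species sets, a
**foreground group (FG)** and a **background group (BG)** (jointly the
*discovery groups*, typically the extremes of a continuous trait or two
binary conditions), `caaskit` scans each column of an amino-acid multiple
sequence alignment and reports the positions where

1. the FG and BG species share **no** amino acid, and
2. at least one of the two groups is **monomorphic** (all members share the
   same amino acid).

The closure of these two conditions yields three mutation patterns:

| pattern | FG | BG |
|---------|----|----|
| P1 | monomorphic | monomorphic |
| P2 | monomorphic | polymorphic |
| P3 | polymorphic | monomorphic |

Molecular convergence is noisy: CAAS-like columns arise by chance with no
phenotypic association. `caaskit` quantifies this *convergent noise* per
position with an empirical p-value — the fraction of randomized FG/BG
assignments that reproduce a CAAS at that column — and validates detections
by bootstrap over *virtual discovery groups* generated in three modalities:

* **naive** — every species equally likely to enter either group
  (plain permutation null);
* **phylogeny-restricted** — randomization preserves the observed
  per-clade composition of the groups;
* **Brownian motion (BM)** — the *permulation* strategy: a trait is
  simulated under BM on the phylogeny, the observed trait values are
  reassigned to species by rank-matching the simulation, and the virtual
  groups are taken from the extremes of the permuted trait, so the null
  respects phylogenetic covariance.

The bootstrap tool counts, per column, the iterations whose virtual groups
yield a CAAS and reports the empirical p-value `(hits + 1) / (cycles + 1)`.
Discovery and bootstrap run on single alignments so proteome-scale sets can
be parallelized externally and merged afterwards.

## Worked example

Generate a seeded synthetic dataset (20 species, 30 columns, one planted P1
column at 0-based position 5), scan it, and validate by naive bootstrap:

```bash
caaskit fixtures --species 20 --columns 30 --plant 5:P1 --strict --seed 7 -o demo
caaskit discover -a demo/msa.fa -t demo/groups.tsv --pvalue exact -o demo/caas.tsv
cat demo/caas.tsv
```

```
# positions are 1-based
alignment_id    position    pattern  fg_aas  bg_aas  fg_missing  bg_missing  pvalue
msa             6           P1       L       V       0           0           0.3333333333333333
```

The planted column is found at 1-based position 6: the two FG species carry
L, the two BG species carry V, and the exact per-position noise p-value over
the FG ∪ BG pool is 2/6 ≈ 0.333 (of the six ways to split the four species
into virtual groups, two reproduce a CAAS).

```bash
caaskit resample -p demo/tree.nwk -m naive -n 1000 -t demo/groups.tsv --seed 3 -o demo/rs.tsv
caaskit bootstrap -a demo/msa.fa -t demo/rs.tsv -o demo/boot.tsv
sort -t$'\t' -k5 -g demo/boot.tsv | head -4
```

```
alignment_id    position    hits    cycles  pvalue
msa             6           18      1000    0.01898101898101898
msa             11          142     1000    0.14285714285714285
msa             5           160     1000    0.16083916083916083
```

Randomizing the groups over all 20 species, only 18 of 1000 virtual group
assignments reproduce a CAAS at the planted column (p ≈ 0.019), while every
background column is far noisier — the planted signal attains the minimum
bootstrap p-value by an order of magnitude. BM permulation replaces the
`-m naive` step with `-m bm --traits demo/traits.tsv`; clade-restricted
randomization uses `-m phylo --template demo/taxonomy.tsv`.

## Limitations

CAAS detection is descriptive: depending on the chosen groups the output
may reflect convergent noise or identity-by-descent rather than adaptation.
Complementing it with ancestral-state reconstruction, selection scans or
dN/dS analysis is advisable. Multiple-testing correction across genes is
left to the user. See `docs/methods.md` for the model, parameter and
calibration details.
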