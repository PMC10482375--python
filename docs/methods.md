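# Methods

This note documents the statistical machinery implemented in
`phagearsenal`, the assumptions behind it, and the design choices made
where the design was genuinely open.  The package analyses detector-style
hit tables (defence systems and biosynthetic gene clusters with per-gene
coordinates and GC), replicon metadata, prophage intervals, and trees —
it does not detect systems, predict prophages, or build trees.

## Arsenal profiling

Two per-type summaries are kept distinct throughout: **frequency** (the
fraction of genomes with at least one copy) and **abundance** (the mean
number of copies per genome).  Abundance ≥ frequency always, and the mean
number of systems per genome is the sum of per-type abundances.

The **defence genome fraction** is the summed length of defence genes
divided by the summed replicon length of the genome.  Overlapping defence
genes are merged (interval union) before summing, so nested or tandem
annotations are never double counted; the source annotations are silent
on this point and the union is the conservative reading.

**Defence islands** chain systems on one replicon whenever the number of
CDS strictly between two systems — between the highest gene ordinal of
the upstream system and the lowest of the downstream one — is below a
threshold (default 20, read strictly: "fewer than 20").  Counting uses
CDS ordinals, not base pairs, which is why the hit schema carries an
optional `gene_index`.  Islands are maximal chains; because the pairwise
criterion is monotone in the ordinal gap, chaining consecutive systems in
ordinal order yields exactly the transitive closure of the pairwise
relation (property-tested against a union–find oracle).  Singleton
systems are not islands.

## Differential abundance

For each system type with focal-group abundance $A_{in}$, background
abundance $A_{out}$ and pooled (genome-weighted) abundance $A_{all}$, the
effect size is

$$E = \frac{A_{in} - A_{out}}{A_{all}}.$$

The estimator is antisymmetric under group swap, and when the background
carries no copies it equals $(n_{in}+n_{out})/n_{in}$ exactly.  It is
undefined when the type is absent from the whole cohort; such types are
excluded rather than reported as zero.

Significance is a one-way two-group ANOVA on the raw per-genome copy
counts (not presence/absence), giving F with $(1, n-2)$ degrees of
freedom — equivalent to the squared pooled-variance t statistic.
Degenerate inputs are resolved explicitly: zero within-group variance
with equal means gives $F=0, p=1$; with unequal means $p=0$ plus a
`degenerate` flag.  Copy counts are Poisson-like rather than normal, so
the F test is an approximation; at the cohort sizes used here
(≥ 40 genomes per group) the simulated familywise false-positive rate of
the corrected screen stays below the nominal 5 % (it is in fact
conservative).

P-values are Bonferroni-corrected across the types tested in the run;
the family size is configurable upward (e.g. to a full detector model
set) for fidelity runs.  A type with zero focal copies but a non-zero
background is classified **absent** without testing — absence is treated
as its own category, not as an extreme depletion.  Otherwise the class is
**enriched** ($p_{adj} \le \alpha$, $E>0$), **depleted**
($p_{adj} \le \alpha$, $E<0$), or **not significant** (including the
rounding-only case $E=0$ with small $p$).

Genomes, not replicons, are the abundance denominator: a genome with a
plasmid is still one genome.

## MGE attribution and GC score

Each hit receives exactly one location among `chromosome`, `plasmid`,
`prophage`:

* a **defence** hit is prophage-borne if any of its genes overlaps the
  merged prophage union by ≥ 1 bp (tolerant of imperfect prophage
  boundary calls);
* a **BGC** is prophage-borne if at least 50 % of its span
  `[min gene start, max gene end)` lies in the union, with ties at
  exactly 50 % counting as prophage ("at least half");
* otherwise the replicon annotation decides plasmid vs chromosome.

Prophage takes precedence over plasmid, so a prophage integrated on a
plasmid is reported as prophage and the three per-type fractions are
mutually exclusive and sum to 1 exactly.  All overlap arithmetic is
half-open; touching intervals share zero bases.  Attribution is
property-tested against a per-base boolean-mask oracle on random layouts.

The **GC score** of a gene is its GC fraction divided by its replicon's
GC fraction; a hit's score is the arithmetic mean over its genes (the
alternative — concatenated-sequence GC — is not computable from
coordinate tables and would weight long genes more; the mean is the
declared choice).  Scores below a configurable threshold (default 0.8)
flag candidate horizontal transfers.  Report percentages round half-up
to one decimal.

## Spatial distribution on linear replicons

Each hit on a linear replicon gets a normalized position: min gene start
divided by replicon length, in $[0,1)$.  For a multi-gene system the
first gene's start stands for the system.  The extremities at threshold
$t$ are $x < t$ or $x \ge 1-t$ (half-open on both sides; the boundary
$x = 1-t$ counts as extremity — ties are measure-zero on real
coordinates).  Defaults $t = 0.10$ (chromosomal arms) and $t = 0.01$
(chromosome ends) against a uniform baseline of $2t$.

Circularly annotated replicons are rejected, not re-linearized — there
is no defensible origin choice for them in this context.  Per-type
profiles require more than 45 occurrences by default to keep fractions
out of small-sample noise.  An optional exact binomial test (doubled
smaller tail, capped at 1) compares the observed extremity count with
$\mathrm{Binom}(n, 2t)$; this convention reproduces, e.g., $p = 2(0.8)^{20}$
for 0 extremity hits out of 20 at $t=0.1$.

## Pagel's lambda

Presence/absence of a system type over the leaves of an ultrametric tree
is modelled as a continuous trait under lambda-transformed Brownian
motion: covariance $\sigma^2 C(\lambda)$ where $C_{ij}$ is the shared
root-to-MRCA path length and $C(\lambda)$ scales the off-diagonal by
$\lambda \in [0,1]$.  The root state and rate are profiled analytically
(GLS mean; mean residual quadratic form), leaving a one-dimensional
profile likelihood maximized on a 0.01 grid plus a bounded refinement to
tolerance 1e-8.  This is maximum likelihood, not REML, matching the
common default of comparative-methods tools.

*Numerical choices.*  Near $\lambda = 1$ the covariance of trees with
very short terminal or internal edges can be singular to machine
precision; a graded ridge (up to $10^{-8}$ of the mean diagonal) keeps
the Cholesky factorization alive without measurably moving the
likelihood.  When the likelihood is flat in $\lambda$ (a star tree), the
tie breaks to $\lambda = 0$.  The search is bounded to $[0,1]$ by
default; an upper bound above 1 is accepted where $C(\lambda)$ stays
positive definite.

The p-value is the upper $\chi^2_1$ tail of the likelihood-ratio
statistic against $\lambda = 0$.  Because $\lambda = 0$ sits on the
boundary of the parameter space, the plain $\chi^2_1$ tail is
conservative (the 50:50 mixture would be sharper); simulated null
rejection rates confirm this.  The screen reports raw p-values and takes
the patchiness cutoff as a parameter rather than hard-coding any
particular threshold, and an optional frequency filter restricts it to
rare types.

*Caveat.*  Treating a 0/1 trait as Gaussian is the same approximation
made whenever a continuous-trait signal statistic is applied to binary
data.  It biases $\hat\lambda$ downward for binarized traits and makes
the p-value approximate; conclusions about individual types should rest
on the reported p-values, not on point estimates of $\lambda$.  A
threshold/liability model is explicitly out of scope.

## Synthetic cohorts

The generator emulates the statistical structure of detector outputs for
a two-group comparison, not their biology: no nucleotide is ever
generated.  Per genome it draws a chromosome (linear by default, length
uniform on 2–10 Mb; GC uniform on 0.60–0.74 for the GC-rich focal group,
0.45–0.60 for the background), an optional plasmid (probability 0.39,
50–300 kb), and Poisson-distributed prophage intervals (mean 1.3 per
genome, 10–60 kb, placed uniformly — only the overlap topology matters
downstream).  The default 200 genomes per group keeps every planted
effect detectable at desk scale.

Per system type, copy numbers are Poisson or Bernoulli with separate
focal/background means; copies designated mobile (probability
`mge_prob`) are placed entirely inside a prophage interval or on the
plasmid; gene GC is the replicon GC times `gc_shift`, clamped to
[0.05, 0.95].  Positions along the replicon come from four placement
families chosen as the minimal shapes for the two archetypes seen in
real linear chromosomes (centre-peaked vs extremity-peaked):
uniform, Beta(5,5) (core), ½Beta(1,9)+½Beta(9,1) (arms),
½Beta(0.2,20)+½Beta(20,0.2) (ends).

One `SeedSequence` per cohort spawns a child stream per genome, so runs
are reproducible and genome *i* does not depend on how many genomes
precede it.  The `truth` table records, per hit, the designated mobility
and drawn position fraction — ground truth for recovery tests, never
read by the analysis modules.

Trees are pure-birth (Yule) with extant tips scaled to unit depth;
traits with controlled signal come from the lambda-Brownian sampler
above (optionally binarized at an empirical quantile).  What the
generator does **not** emulate: linkage between system carriage and
phylogeny inside `simulate_cohort` (presence there is i.i.d. across
genomes, so its presence matrices are genuinely patchy), detector
false-positive structure, shared defence-island architecture across
related genomes, and within-gene GC heterogeneity.  Passing recovery
tests therefore show the estimators are correct and calibrated under the
stated generative model — not that real detector output satisfies that
model.

## Problem sizes

Monte-Carlo checks use sizes at which every planted effect is decidable
with margin: 200 null cohorts of 2×40 genomes for familywise
calibration, 50 cohorts of 2×200 genomes at a 10× abundance ratio for
power, 200 replicates on 128-leaf trees for lambda recovery, 200 on
64 leaves for null p-value calibration, 1000 random layouts for the
overlap oracle and 500 for island chaining.

## Known limitations

* The ANOVA is a large-sample approximation on counts; very small groups
  (< ~10 genomes) deserve an exact test the package does not provide.
* The lambda screen assumes an ultrametric, correctly rooted tree with
  branch lengths; no rate heterogeneity or gain/loss model is fitted.
* Native detector output formats are not parsed; inputs must be
  converted to the schemas in `docs/schemas.md` (the coordinate
  convention there is 0-based half-open — converters from 1-based
  inclusive dialects must shift starts by −1).
* Circular replicons are excluded from, not adapted to, the spatial
  analysis.
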