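# phagearsenal

Comparative genomics of prokaryotic **anti-phage defence arsenals**, built
for the question: how does the defence-system repertoire of one bacterial
group (e.g. a GC-rich phylum with linear chromosomes, such as
Actinobacteria) differ from the rest of bacteria, and what do mobility,
GC composition, chromosomal position, and phylogenetic distribution say
about how that repertoire evolves?

The package consumes detector-style tables (defence systems and
biosynthetic gene clusters with per-gene coordinates and GC), replicon
metadata, prophage intervals (BED), and trees (Newick), and provides:

* **Arsenal profiling** — systems per genome, per-type frequency and
  abundance by taxon, genome fraction in defence genes, and defence
  islands (systems separated by fewer than *k* intervening CDS).
* **Differential abundance** — per type, the normalized effect size

  $$E = \frac{A_{in} - A_{out}}{A_{all}}$$

  (abundance = mean copies/genome; $A_{all}$ the pooled mean), with a
  two-group ANOVA on per-genome copy counts, Bonferroni correction, and
  classification into absent / enriched / depleted / not significant.
* **MGE attribution** — each hit assigned to chromosome, plasmid, or
  prophage (defence: ≥ 1 bp gene overlap with a prophage; BGC: ≥ 50 % of
  the span), plus per-gene **GC scores** (gene GC / replicon GC) flagging
  candidate horizontal transfers below 0.8.
* **Spatial distribution** — normalized start positions on linear
  replicons and extremity fractions at the 10 % / 1 % thresholds, with
  an exact binomial uniformity test against the 20 % baseline.
* **Pagel's λ** — from-scratch maximum-likelihood phylogenetic signal
  for per-type presence/absence traits, with a likelihood-ratio p-value,
  to separate tree-tracking from patchy distributions.
* **Synthetic cohorts** — a seeded generator that plants known group
  differences, MGE carriage, GC shifts, placement biases and trait
  signal, so every stage has a ground-truth recovery test without any
  genome download.

All coordinates are 0-based half-open (BED convention); file schemas are
in `docs/schemas.md`, and the statistical details in `docs/methods.md`.

## Worked example

Generate a synthetic cohort (200 focal + 200 background genomes with a
planted arsenal) and run the stages:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_profile_arsenal.py
python analysis/03_differential_abundance.py
python analysis/04_mge_attribution.py
python analysis/05_spatial_distribution.py
python analysis/06_phylogenetic_signal.py --seed 1
```

Output (seed 1, abridged):

```
Actinobacteria: 200 genomes, 5.00 systems/genome
mean defence genome fraction: 0.334 %
defence islands (>=2 systems, <20 intervening CDS): 71

 AbsentFocal: absent from focal group
      ShosTA: estimator -1.54 p_adj 2.09e-14 -> depleted
      Wadjet: estimator +1.16 p_adj 6.15e-10 -> enriched
          RM: estimator +0.03 p_adj 1.00e+00 -> not_significant

2445 hits: 2.6 % plasmid-borne (64), 6.4 % prophage-borne (156)

      Wadjet: n= 138  extremity10= 98.6 %  extremity1= 73.9 %
     Uniform: n= 371  extremity10= 18.1 %  extremity1=  2.2 %
          RM: n=1002  extremity10=  1.0 %  extremity1=  0.2 %
```

Reading it: the screen recovers the planted structure — `Wadjet`
(planted 0.6 vs 0.08 copies/genome) is enriched with a positive
estimator, `ShosTA` depleted, the equal-abundance types not significant,
and `AbsentFocal` reported as absent rather than tested.  The spatial
profile separates the end-biased `Wadjet` (99 % of occurrences in the
outer 10 % of the chromosome) from the core-biased `RM` (1 %), with the
uniform type near the 20 % baseline.  The phylogenetic-signal screen on
this cohort reports every type patchy (λ ≈ 0) — correctly, since the
generator draws presence independently of the tree; traits with planted
signal are exercised by `simulate_trait` in the test suite.

`analysis/07_full_report.py` runs the same stages through the file-based
orchestrator and writes a markdown report whose numbers are recomputable
from the stage TSVs.

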