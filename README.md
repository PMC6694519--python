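# actampl

Analysis of **total vs. transcriptionally active diazotroph communities**
from paired *nifH* DNA/RNA amplicon libraries, with qPCR-anchored gene
expression ratios.

Marine nitrogen-fixing microbes (diazotrophs) are routinely surveyed with
the *nifH* marker gene. Sequencing *nifH* from DNA profiles the *total*
community (who is there); sequencing it from mRNA (cDNA) profiles the
*active* community (who is transcribing nitrogenase). Comparing the two —
per station, across a transect — reveals rare-but-active taxa and
abundant-but-silent ones that a DNA-only survey misclassifies. `actampl` is
for microbial ecologists who have paired DNA/cDNA OTU tables and *nifH*
qPCR measurements and want the complete comparison pipeline: depth
normalization, diversity contrasts, ordination and dispersion, abundance
ranking, and expression ratios.

## The model

**Normalization.** Libraries are repeatedly rarefied (without replacement)
to a common depth *n* (default: smallest library), with the entrywise mean
over 100 iterations carried forward as the normalized table.

**Diversity.** Per sample: Shannon *H* = −Σ *p*ᵢ ln *p*ᵢ, Gini–Simpson
*D* = 1 − Σ *p*ᵢ², Pielou *J* = *H*/ln *S*, and Chao1
*S*ₒᵦₛ + *F*₁²/(2*F*₂) (bias-corrected when *F*₂ = 0), contrasted between
DNA and RNA libraries by Welch/Student *t* and one-way ANOVA. Between
samples: Bray–Curtis dissimilarity on proportions, non-metric MDS
(Kruskal stress-1), and a homogeneity-of-multivariate-dispersions test
(distance to group centroid in principal-coordinate space, ANOVA *F* with
a label-permutation null).

**Expression.** The bulk mRNA/DNA ratio per station comes from qPCR cycle
thresholds with amplification efficiency *E* (from a standard-curve slope,
*E* = 10^(−1/slope)):

    R_bulk = E^ΔCt,    ΔCt = mean Ct(DNA) − mean Ct(cDNA)

and is partitioned to taxonomic groups by their library frequencies:

    R_group = R_bulk · f_RNA / f_DNA

undefined when a group is absent from the DNA library (f_DNA = 0). A
group with R_group above 1 makes more transcript per gene copy than an
average community member — the signature of a rare-but-active taxon.

A synthetic-data module generates paired libraries and qPCR records from a
known community (per-taxon DNA abundance *d*ᵢ and activity multiplier
*r*ᵢ), so every stage of the pipeline is testable against ground truth;
the identity R_bulk · f_RNA,ᵢ/f_DNA,ᵢ = *r*ᵢ holds exactly at the
proportion level.

## Worked example

Generate a study-like synthetic dataset (9 stations × {DNA, RNA}, 731
OTUs, 4746 reads per library) and run the full pipeline:

```sh
actampl simulate --out demo/in --seed 7
cat > demo/run.yaml <<EOF
counts: demo/in/counts.tsv
metadata: demo/in/metadata.tsv
taxonomy: demo/in/taxonomy.tsv
qpcr: demo/in/qpcr.csv
seed: 7
iterations: 25
n_permutations: 199
EOF
actampl run --config demo/run.yaml --out demo/out
actampl report demo/out
```

The report (excerpts from this exact run) shows the hallmark total-vs-active
signatures:

```
Alpha-diversity contrast (total DNA vs active RNA libraries)
------------------------------------------------------------
       H: mean DNA=2.7081 RNA=3.0809  Welch t=-2.305 (p=0.0389)  ANOVA F=5.315 (p=0.0349)  higher in RNA

Beta-dispersion (between-community variation)
------------------------------------------------------------
  mean distance to centroid [DNA]: 0.1134
  mean distance to centroid [RNA]: 0.2473
  ANOVA F=28.125  p_parametric=7.14e-05  p_perm=0.005 (199 permutations)
  NMDS stress (k=2): 7.544e-05

Group frequencies (across-station averages)
------------------------------------------------------------
  Trichodesmium                  f_DNA=0.9786  f_RNA=0.7249
  cluster III                    f_DNA=0.0099  f_RNA=0.0000
  heterocystous cyanobacteria    f_DNA=0.0023  f_RNA=0.1621
```

The active (RNA) community is more diverse (higher Shannon index,
p < 0.05) and more variable between stations (beta-dispersion p = 0.005)
than the total (DNA) community. The dominant filamentous cyanobacterium
contributes proportionally less to transcripts than to gene copies, while
heterocystous cyanobacteria are ~70-fold enriched on the RNA side —
rare but highly active. Cluster III is present in DNA but silent, so its
expression ratio is reported as n.d. where it is absent from a DNA
library. The per-station ratios and undefined flags are in
`demo/out/expression_ratios.tsv`; `truth.tsv` in the input directory holds
the generator's ground truth for comparison.

Library use without the CLI mirrors the same steps:

```python
from actampl import (paper_like_spec, simulate_dataset,
                     group_frequencies, bulk_expression_ratio,
                     group_expression_ratio)

ds = simulate_dataset(paper_like_spec(seed=7), seed=7)
freqs = group_frequencies(ds.merged_table(), ds.taxonomy)
r_bulk = bulk_expression_ratio(ds.qpcr, efficiency=2.0, station="A")
r_het = group_expression_ratio(
    r_bulk,
    freqs.frequency("heterocystous cyanobacteria", "A", "RNA"),
    freqs.frequency("heterocystous cyanobacteria", "A", "DNA"),
)
```

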