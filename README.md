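# ticklink

Comparative taxonomic/functional profiling and taxon–function linkage
analysis for tick gut metagenomes.

## The problem

Male and female ticks of the same species lead very different lives, and
their gut microbial communities differ both in *who is there* (taxonomic
profile) and in *what the community can do* (functional profile).
Annotated shotgun-metagenome tables — per-read hits carrying a
six-rank bacterial lineage and a four-level functional hierarchy ending
in an EC/KEGG enzyme identifier — let both questions be asked from the
same reads, and a third one that neither profile answers alone: **which
bacterial genera provide the functions that differ between sexes, and
how redundantly?**

`ticklink` implements that analysis as a tested, reusable pipeline for
anyone working with annotation tables of this kind (e.g. MG-RAST-style
exports for *Amblyomma variegatum* (AV), *Ixodes ovatus* (IO), and
*I. persulcatus* (IP) gut metagenomes, one pooled sample per
species × sex):

1. **read_qc** — optional FASTQ preprocessing: dynamic trimming (longest
   window with ≤ 5 bases below Phred 15, minimum length 50 bp),
   artificial-replicate removal, per-sample length/GC summaries.
2. **profile_io** — the annotation-table dialect; quality filters
   (e-value ≤ 1e-5, alignment ≥ 15 bp, identity ≥ 60% taxonomic / 80%
   functional, Bacteria domain only); deterministic best-hit
   classification.
3. **abundance** — count matrices at any rank or functional level;
   median-of-ratios size factors; relative abundances.
4. **community_stats** — analytic rarefaction, Shannon diversity,
   Bray–Curtis distances, rank-based ANOSIM with permutation p-values,
   covariance PCA, Venn partitions of genus sets.
5. **differential** — per-feature two-sided Fisher exact tests
   (minimum-likelihood convention) with Benjamini–Hochberg q-values and
   Newcombe–Wilson 95% CIs on proportion differences; one-way ANOVA with
   η² effect sizes and Tukey–Kramer post-hoc tests.
6. **linkage** — the core analysis: join differentially abundant enzymes
   (q < 0.05) to the genera carrying them on the same read, then compute
   the functional-redundancy spectrum (enzymes per genus-count bin
   {1, 2–4, 5–10, ≥11}), per-genus contribution shares, and the
   dual-role partition of genera (taxonomically differential vs.
   function-providing vs. both).
7. **synthetic_data** — a generator with planted ground truth
   (abundances, sex effects, enzyme repertoires, annotation noise,
   QC-removable reads) standing in for the raw sequencing data.

## The statistics at the core

For a feature with counts $a$ of $n_1$ total hits in one sample and $c$
of $n_2$ in the other, significance comes from the two-sided Fisher
exact test on $\begin{pmatrix} a & n_1-a \\ c & n_2-c\end{pmatrix}$
(summing hypergeometric probabilities $\le$ the observed one), with BH
step-up control of the FDR across features. Functional redundancy of an
enzyme $e$ is $r(e) = |\{g : \text{genus } g \text{ carries } e\}|$,
summarized as the fraction of differential enzymes per redundancy bin;
genus contributions are hit shares $100 \cdot h_g / \sum_{g'} h_{g'}$
over the linkage edges.

## Worked example

The linkage summaries for the AV and pooled-*Ixodes* analyses can be
reproduced from the bundled synthetic worked-example edge lists:

```python
from ticklink.linkage import genus_contributions, redundancy_spectrum
from ticklink.synthetic_summaries import synthetic_av_linkage_edges

av = genus_contributions(synthetic_av_linkage_edges(), top_k=5)
print(round(av.top_k_share_pct, 1))            # 89.9
print(round(av.single_enzyme_fraction_pct, 1)) # 56.5
print(av.per_genus["share_pct"].head(5).round(1).to_dict())
# {'Haemophilus': 29.3, 'Aggregatibacter': 22.8, 'Proteus': 16.7,
#  'Pasteurella': 11.7, 'Coxiella': 9.4}
```

i.e. five genera hold 89.9% of the linkage hits in AV while 13 of the 23
provider genera (56.5%) contribute a single enzyme each — a community in
which a few genera dominate the differential functions but most genera
are narrow specialists.

A full synthetic run from the command line:

```bash
ticklink simulate --out sim --seed 3
ticklink profile --annotations sim/annotations.tsv --mode taxonomic \
    --level genus --out genus.tsv
ticklink diff --matrix genus.tsv --a AVf --b AVm --out diff_av.tsv
ticklink profile --annotations sim/annotations.tsv --mode functional \
    --level func_l4 --out enzymes.tsv
ticklink diff --matrix enzymes.tsv --a AVf --b AVm --out diff_enzymes.tsv
ticklink linkage --annotations sim/annotations.tsv --diff diff_enzymes.tsv \
    --out linkage_out
```

`linkage_out/summary.json` then contains the redundancy-spectrum
fractions, the top-5 cumulative share, and the single-enzyme genus
fraction for the simulated community; `sim/ground_truth.json` holds the
planted values they should recover.

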