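# arisakit

Community analysis for ARISA fingerprints (Automated Ribosomal Intergenic
Spacer Analysis) anchored to an IGS–23S clone library.

ARISA characterises a bacterial assemblage as a set of electrophoretic
peaks whose sizes track the length of the 16S–23S intergenic spacer (IGS).
Peaks alone do not identify organisms: unrelated taxa can share a fragment
length, and one organism with several rRNA operons produces several peaks.
`arisakit` implements the companion analysis for surveys that resolve this
with a clone library — here, a study of cloacal bacteria in adult and chick
black-legged kittiwakes, where amplicons span the IGS plus a 131-bp
fragment of the 23S rRNA gene:

1. **Clone library → OTUs** — deduplicate cloned sequences; clones sharing
   an identical 23S fragment belong to one OTU (one organism, operons of
   different IGS length).
2. **Peak ↔ clone matching** — bin fractional peak sizes to integer bp,
   then assign each clone to at most one peak per age class using a
   size window on (clone − peak) ∈ [−6, +15] bp and a cross-sample
   co-occurrence score. Unclaimed peaks are artefacts and are dropped;
   OTUs seen in saline-control samples (by clone or peak) are flagged as
   contaminants.
3. **Taxonomy** — consensus of the best similarity hit and the placement
   of the clone in a reference phylogeny, assigned at the deepest agreeing
   rank.
4. **Diversity and comparison** — analytical (hypergeometric) rarefaction
   `E[S_n] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n))` with exact variance and 95%
   limits; unweighted UniFrac (fraction of branch length unique to one of
   two assemblages), its permutation significance test, the parsimony
   P test, lineage-specific (per-clade Fisher exact) analysis, PCoA by
   Gower double-centering, and UPGMA clustering of individuals with
   sequence-jackknife node support.
5. **Synthetic studies** — a generator that emulates the study design
   (22 adults at 9.2 ± 2.3 OTUs/individual, 21 chicks at 5.8 ± 3.0 with
   richness rising with age, 24 + 33 + 7 class-split OTU pools, 12
   contaminants, 1–9 operons per OTU, systematic ±bp size offsets,
   artefact peaks) with full ground truth, so every stage is testable
   end to end.

The packaged reference table (`arisakit.reference_table`) transcribes the study's
printed OTU table and reproduces its headline counts: 64 cloacal OTUs, 31
in adults, 40 in chicks, 7 shared, Proteobacteria 12.5%.

## Worked example

```python
from arisakit import (SimConfig, simulate_dataset, analyze, AnalysisParams,
                      truth_report)

ds = simulate_dataset(SimConfig().zero_noise(), seed=42)
result = analyze(ds.clones, ds.profiles, ds.metadata, ds.hits, ds.tree,
                 ds.reference_lineages, params=AnalysisParams(seed=42))
```

which prints (via the fields shown in `result`):

```
clones: 1576  unique: 110  OTUs: 76  contaminants flagged: 12
adults: 31 OTUs, chicks: 40, shared: 7, total: 64
richness adult 9.0 +/- 2.8, chick 5.7 +/- 3.4 (permutation p = 0.0007)
P test p = 0.0099, UniFrac significance p = 0.0099
PCoA axis 1 explains 31.6% of variation
presence-matrix F1 vs truth: 1.000
```

Reading this: 1576 simulated clones collapse to 110 unique sequences and
76 OTUs; the 12 OTUs recovered from control samples are flagged and
removed, leaving the 31/40/7 adult/chick/shared split. Adults host more
OTUs per individual than chicks, the age classes cluster on the 23S
phylogeny (both permutation tests at the 1/101 floor with 100
permutations), and in the noise-free configuration the recovered
presence/absence matrix equals the generator's truth exactly.

The same pipeline runs from the shell on files (clone FASTA, peak CSV,
metadata/hit TSVs, newick tree):

```sh
arisakit simulate --seed 42 --zero-noise --outdir study/
arisakit run --clones study/clones.fasta --peaks study/peaks.csv \
    --metadata study/metadata.tsv --hits study/hits.tsv \
    --tree study/tree.nwk --ref-lineages study/reference_lineages.tsv \
    --outdir study/out
arisakit table-check
```

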