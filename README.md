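# panmod

Histone **pan-modification** gene classification and Pol II run-off signal
analysis for CUT&Tag / PRO-seq style data.

Active transcription couples with widespread ("pan") acetylation (H3K9ac,
H4K12ac) and phosphorylation (H3S10ph, H4S1ph) of nucleosomes along gene
bodies. `panmod` provides the downstream analysis for studying this
coupling, for epigenomics researchers who already have peak calls and
coverage tracks in hand:

1. **Gene classification.** Peak calls of the four marks are merged within
   the two mark families (ac = H3K9ac ∪ H4K12ac, ph = H3S10ph ∪ H4S1ph).
   Each gene is split into a promoter window (TSS ± 200 bp) and the
   remaining gene body, and four flags record family presence per zone
   (≥ 1 bp overlap). The flags map to one of seven mutually exclusive
   classes: acetylation-dominated, phosphorylation-dominated, both,
   promoter-acetylation-only, promoter-phosphorylation-only,
   promoter-both, and unmodified. Body modification takes precedence over
   promoter flags.
2. **Isoform selection.** An isoform-level annotation is reduced to one
   gene model per gene — the isoform with the highest mean RPKM across
   samples (`count / (L/10³ · N/10⁶)`, floor 0.1) — and genes with another
   same-strand TSS within 100 kb are removed, so TSS-anchored windows stay
   uncontaminated.
3. **Signal matrices.** log2((treatment + 1)/(control + 1)) tracks from
   RPKM-scaled bedGraphs, binned into a strand-aware genes × bins matrix
   anchored at the TSS (−5 kb … +100 kb, 100 bp bins) and sorted by gene
   length — the standard reference-point heatmap computation.
4. **Run-off kinetics.** When initiation is blocked (e.g. by DRB), engaged
   Pol II "runs off" each gene, clearing signal from the TSS outward at
   the elongation rate v. `wavefront_estimate` locates the cleared
   region's far edge per gene by threshold crossing with linear
   interpolation, and `estimate_elongation_rate` regresses front position
   on time to recover v.
5. **Synthetic data.** A generator produces annotations, peak sets with
   known per-gene class labels, expression tables and time-course tracks
   with a clearing/refilling wave — ground truth for every stage.

## Worked example

```sh
panmod simulate --seed 17 --n-genes 40 --outdir run/sim
panmod classify \
    --annotation run/sim/genes.bed \
    --h3k9ac run/sim/H3K9ac.bed --h4k12ac run/sim/H4K12ac.bed \
    --h3s10ph run/sim/H3S10ph.bed --h4s1ph run/sim/H4S1ph.bed \
    --outdir run/cls
```

The classify step logs per-stage counts to stderr, e.g.:

```
panmod: read 40 gene models from run/sim/genes.bed
panmod: read 16 H3K9ac peaks
panmod: merged peaks: 38 acetylation, 36 phosphorylation
panmod: AC_DOMINATED: 10 genes
panmod: BOTH: 17 genes
panmod: PROM_BOTH: 7 genes
...
```

and writes `classification.tsv` (gene_id, four flags, label) and
`summary.tsv` (one row per class plus the modified total). On this
synthetic cohort the labels match the generator's manifest exactly —
with intergenic noise peaks present — because noise peaks never enter a
gene ± 200 bp.

For the time course:

```sh
panmod matrix --annotation run/sim/genes.bed \
    --treatment run/sim/drb_5min.bedgraph \
    --control run/sim/control.bedgraph \
    --outdir run/mat --heatmap
```

writes `matrix.tsv.gz` (gzip TSV with a JSON header; 1,050 bins/gene) and
a heatmap in which short genes (top rows, ascending length sort) are fully
cleared while long genes show the run-off front ~10 kb downstream of the
TSS after 5 min at 2,000 nt/min.

In Python:

```python
>>> from panmod import rpkm, classify_gene, Flags
>>> rpkm(250, 500, 5e7)
10.0
>>> classify_gene(Flags(body_ac=True, body_ph=False, prom_ac=True, prom_ph=False)).value
'AC_DOMINATED'
```

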