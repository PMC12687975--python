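# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`, matching
BED/bedtools semantics; GTF input (1-based closed) is shifted on read and
restored on write. The TSS of a plus-strand gene is `interval.start`; for
a minus-strand gene it is `interval.end − 1`, the last covered base. Peaks
are strandless (peak callers do not emit strand). The default chromosome
whitelist for annotations is the primary assembly (chr1–22, chrX, chrY);
records elsewhere are dropped.

## Gene classification model

The unit of classification is one representative gene interval. The
promoter is the TSS ± `promoter_halfwidth` window — ± 200 bp by default,
i.e. the half-open window `[tss − 200, tss + 201)` — clipped to the
chromosome; the gene body is the gene interval minus that window (empty
for genes shorter than the window). Peaks are merged **within** each mark
family (acetylation = H3K9ac ∪ H4K12ac, phosphorylation = H3S10ph ∪
H4S1ph) with bedtools-style bookend coalescing; a single union across all
four marks would make the acetylation/phosphorylation distinction
undefinable, so the cross-family union exists only as an explicit CLI
variant (`--merge-all-marks`) for sensitivity analysis.

Presence is ≥ 1 bp overlap (`min_overlap_bp`, configurable; no minimum
overlap fraction is imposed). A peak straddling the promoter boundary sets
both the promoter and the body flag; the promoter-only classes are
reserved for genes whose modifications are *confined* to the TSS window.
`strict_containment=True` switches to the alternative reading in which
the promoter flag requires full containment. The label is a pure function
of the four flags, with body flags taking precedence: body-ac-only →
acetylation-dominated, body-ph-only → phosphorylation-dominated, both
body flags → both; with no body flags the promoter flags choose among the
three promoter-only classes; all-false → unmodified. This yields a
partition (exactly one label per gene), which the summary layer
aggregates: the acetylation analysis set is AC-dominated + both, the
phosphorylation analysis set is PH-dominated + both, and the unmodified
remainder is total protein-coding genes minus the six modified classes.
The gene body ends at the annotated gene end; no 3′ extension is applied.

## Isoform selection

RPKM is `count / ((L/10³)·(N/10⁶))` with L the isoform length and N the
per-sample total mapped reads. Per gene, the isoform with the highest
*unweighted arithmetic mean* RPKM across samples is kept, requiring a
minimum mean of 0.1; ties go to the longer isoform, then to the
lexicographically smaller id (the choice must be deterministic; the
criterion itself does not disambiguate ties). The clustered-TSS filter
removes every gene with another same-strand TSS at distance
≤ `window_bp` (default 100 kb) on the same chromosome; the boundary
counts as clustered, matching the bookend behaviour of window-merge-based
clustering. The pairwise-distance definition and the
transitive-window-cluster definition agree on which genes survive as
singletons (a gene isolated by > window from its nearest same-strand
neighbour is exactly a size-1 cluster); the test suite asserts this
agreement on random instances rather than assuming it.

## Signal matrices

`log2_compare` re-segments two tracks at the union of their breakpoints
and emits `log2((t + p)/(c + p))` with pseudocount p = 1.0 on RPKM-scaled
values (configurable; uncovered positions on both tracks give 0 and stay
implicit). `compute_matrix` anchors a −5 kb … +100 kb window at each TSS
(the spans and reference point of the standard reference-point heatmap),
with 100 bp bins — 1,050 bins per gene; the bin size keeps the 105 kb
window near a thousand columns and is not dictated by the upstream tools'
defaults. Bin values are length-weighted means computed from a cumulative
integral per chromosome, with uncovered bases counting as 0. For
minus-strand genes the window is reflected through the TSS so that bin 0
is always the most upstream position in the direction of transcription;
the mapping takes transcription offset d to genomic base `tss − d`, which
makes the matrix exactly invariant under genome reflection plus strand
swap (a property test). Bins extending past position 0 — or past the
chromosome end when lengths are supplied — are NaN and are excluded from
summaries, never zero-filled. Rows are sorted by gene (region) length,
ascending, stable on ties.

For the time-course comparisons, both inhibition and recovery time points
are compared against the untreated control; comparing recovery against
the fully inhibited state is available as a CLI choice of inputs rather
than a separate mode.

## Run-off wave and elongation-rate recovery

Under initiation block, the engaged-polymerase profile of a gene is
cleared on `[TSS, TSS + v·t]` (transcription direction, clipped at the
TES). The wavefront estimator takes a gene's treated/control ratio in
downstream bins, requires the ratio at the TSS to be below
`threshold_fraction` (default 0.5 — the midpoint between cleared and
intact, maximally distant from both noise floors), and returns the first
crossing back above it, linearly interpolated between bin centres; genes
never cleared (ratio at TSS above threshold) or never recovering within
the window (fully cleared, front beyond the gene) return NaN and drop out
of downstream statistics — this self-selects genes long enough to resolve
each time point. The rate estimate is the OLS slope of mean front
position on time; with fronts at 5/15/30 min the fit uses three points
and recovers the simulated 2,000 nt/min to well within 10% at noise sd
0.05 × plateau.

## Synthetic data generator

The generator encodes the study conditions; its defaults are fixed, not
tuning knobs:

| parameter | default | rationale |
|---|---|---|
| n_genes | 200 | enough genes per class at the observed proportions |
| gene lengths | log-uniform 5–100 kb | spans short genes through genes long enough to resolve a 30-min front (60 kb) |
| class quotas | observed proportions of the 19,989 protein-coding genes (incl. 135/19,989 unmodified) | cohort mirrors the real class structure |
| peak widths | uniform 200–1,000 bp | typical histone-mark peak scale |
| noise peaks | 50, strictly intergenic (> gene ± 201 bp) | background that cannot perturb ground-truth labels |
| elongation rate v | 2,000 nt/min | in-vivo Pol II rate anchor |
| inhibition / recovery times | 5, 15, 30 / 10, 30, 60 min | the experimental time grids |
| plateau height h | 10, noise sd 0.05·h | moderate-depth coverage with mild count noise |

Genes are placed on one 60 Mb chromosome without body overlap;
non-clustered genes are spaced so consecutive TSSs are > 100 kb apart,
which makes the clustered-TSS ground truth exact, and a configurable
fraction of genes is laid out as same-strand pairs with TSSs within the
window. Isoforms share the gene's TSS and differ at the 3′ end, so
isoform choice never moves the reference point. Peaks realise the target
label by construction (body peaks strictly inside body zones,
promoter-only peaks inside the TSS window; family peaks split at random
between the two constituent marks); a separate `confuser_fraction` mode
plants wrong-family body peaks to *measure* classifier robustness —
reported, never asserted. Track noise is additive Gaussian floored at 0,
the simplest model consistent with count-derived coverage at moderate
depth; the run-off model ignores re-initiation during inhibition
(initiation is treated as fully blocked) and refills only `[TSS, TSS+v·t′]`
after washout.

What the generator does **not** emulate: mappability and GC artefacts,
per-mark decay lags and replicate-to-replicate kinetic differences,
nucleosome-resolution footprints (±200 bp cannot separate +1 from −1
nucleosomes, and neither can the assays), overlapping/nested real gene
architectures, or read-level sampling noise. Passing tests therefore
demonstrate correctness of the interval logic, the matrix arithmetic and
the estimators under the stated model — not robustness to every artefact
of real chromatin data.

## Numerical and design choices

- Merging uses gap ≤ 0 (bookended intervals coalesce), matching the
  default of the standard interval toolkit.
- Signal queries run through per-chromosome cumulative integrals
  (`O(log n)` per window via binary search), so matrices over thousands
  of bins stay cheap; per-base brute-force oracles validate them on small
  instances.
- Overlap queries against merged peaks use sorted-array bisection; the
  merged-set invariant (sorted, disjoint) makes peak ends sorted too.
- Degenerate inputs: empty peak files are valid (no peaks); genes shorter
  than the promoter window have an empty body and can only be
  promoter-classified or unmodified; an empty gene-body yields a missing
  body-signal summary, and a profile with no finite bins yields a missing
  front.
- Problem sizes in the acceptance script (2,000-gene round trip, 200
  brute-force instances, 150-gene run-off cohort) were chosen to give
  stable statistics at interactive runtimes on a single CPU.

## Known limitations

- The classifier is peak-based: signal present below the peak caller's
  threshold is invisible, and the class counts inherit the caller's
  operating point.
- `select_max_isoform` requires expression entries for every isoform and
  does not impute missing samples.
- The wavefront estimator assumes a monotone cleared→intact transition;
  profiles with interior dropouts (e.g. unmappable stretches) can cross
  the threshold early. Front estimates from very short genes are
  systematically censored, so per-time gene sets differ — the regression
  uses per-time means, which tolerates this but assumes no length-
  dependent rate.
- bigWig is not read or written; convert to bedGraph externally.
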