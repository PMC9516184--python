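# Methods

## Scope and data model

The package operates strictly downstream of read processing: MACS2-style
peak calls (narrowPeak/BED), a GFF3 gene annotation, a genome FASTA and
a DE table (gene, contrast, log2 fold change WT/mutant, adjusted p,
mean expression) are inputs. All internal coordinates are 0-based
half-open; GFF3 is converted on read (1-based closed → subtract one
from the start). Chromosome names match by exact string equality; a
rename map can be supplied where inputs disagree. The TSS of a
minus-strand gene is `end − 1`, its TTS `start`.

## Consensus merging

Two replicate peaks belong together when the overlap covers at least
`min_frac` (default 0.8) of the shorter segment. The relation is
evaluated pairwise on the **original** replicate peaks and closed
transitively (single linkage); the merged union segment is not
re-tested against members. This choice is deliberate: the pairwise rule
plus transitive closure is deterministic and independent of input
order, whereas iterative re-merging of union segments depends on the
merge schedule. The union span is therefore at least as long as the
broadest member — asserted on every emitted consensus peak. Support
counts distinct replicate identifiers (not member peaks; two calls from
one replicate in one component contribute support 1), and the filter
`support ≥ min_support` (default 2 of 4) is applied after component
formation. The implementation sweeps start-sorted peaks with an active
list and a union–find; tests compare it against an O(n²) all-pairs BFS
oracle.

## Condition comparison

A consensus peak of length L and mid-point c defines the center window
`[c − 0.3L, c + 0.3L)`. Mid-points of odd-length peaks are
half-integers and are kept exact — window bounds are reals, never
rounded. Two peaks from different conditions are "shared" when their
windows intersect under half-open comparison; classification is per
peak, so with one-to-many matches the shared counts of the two sides
may differ. Negative-control handling is distinct and simpler: a
consensus peak is flagged when it intersects any mock peak by ≥ 1 bp on
the raw intervals. Flagged peaks are reported, not removed, because a
cross-reacting antibody signal is evidence against specificity but not
proof; `exclude_control_flagged` switches on removal for users who want
it.

## Peak–gene association

A peak links to a gene when it overlaps the gene body or the promoter
window (`upstream_bp`, default 2,000 bp 5′ of the TSS in gene
orientation). The default window matches the span of the positional
analyses; association is intentionally one-to-many in both directions.
Localization codes: S when the peak interval contains the TSS
coordinate; otherwise P when the peak lies entirely 5′ of the TSS and G
when entirely 3′ of it. A peak overlapping the TTS and running past the
3′ end is still G — only three codes exist and S is reserved for the
start. The signed distance is TSS → peak center in gene orientation
(negative = upstream); per-gene code strings concatenate replicate
support and code ("4G"; several peaks join as "4P, 2P", descending
support).

## Expression integration

Regulation classes derive only from the DE table: activated when
`log2fc > min_abs_log2fc` (default 0) and `padj ≤ padj_max` (default
0.05); repressed symmetrically; otherwise unchanged. A missing padj is
missing — never treated as 1 — and always yields "unchanged". A target
call requires both a peak link and a non-unchanged class under the same
condition; by default any peak present under the condition qualifies
(`peak_presence_filter="any"`), with a stricter condition-specific mode
available. Because the thresholds behind published candidate counts are
rarely printed, both are configuration, echoed into the output
metadata. Overlap testing uses the upper-tail hypergeometric
distribution via `scipy.stats.hypergeom.sf`; tests check it against
exact rational enumeration for all universes up to N = 12 at 1e−12
relative tolerance. The universe defaults to the genes in the supplied
annotation. A Benjamini–Hochberg helper is included for batches of
overlap tests only; the pipeline never re-adjusts the DE table's padj.

## Motif scanning and positional statistics

The scanner matches IUPAC degenerate patterns exactly (no PWM scores):
a sequence position matches when every base lies in the pattern
position's allowed set; an N in the sequence matches only an N in the
pattern. Minus-strand sites are plus-strand matches of the
reverse-complement pattern, reported in plus coordinates. Overlapping
matches are all counted — tandem arrangements of the extended core
variants (AGTACA/TGTACT) overlap by construction. The implementation is
vectorized (per-position membership masks ANDed across the pattern);
tests hold it to a naive lookahead-regex oracle on random sequences.

All distances use the site midpoint, which is symmetric for even and
odd motif lengths. Copies-per-peak counts sites whose midpoint lies in
the peak; the scan window is widened by one motif length so
boundary-straddling sites are found. Peak-center distances are binned
in 75-bp half-open bins placed symmetrically with the central bin
straddling zero (edges at ±(k+½)·75); signed distances are the default,
absolute available by flag. The metagene profile maps a site d bp past
the TSS of a gene of length L to `d/L · 2000` (upstream and
beyond-TTS offsets stay in real bp, the latter shifted by 2,000) and
bins at 200 bp over [−2000, 4000).

## Synthetic data generator

The generator emulates the downstream products of a 4-replicate,
2-condition tagged-line ChIP experiment with untagged-control mocks and
a 3-replicate WT-vs-mutant RNA-seq contrast per condition. Reference
defaults: two 700-kb chromosomes; 260 non-overlapping genes (1–2.5 kb,
1.5–2.5-kb gaps); 200 true sites of width 240–360 bp centered 150 bp
upstream of the TSS of 200 distinct genes, each planted with one
concrete instance of the degenerate motif; 15% of sites present only
under low Cu (the observed condition asymmetry of low-Cu-responsive
binding); per replicate each present site is emitted with
Normal(0, 20 bp) center and width jitter and dropped with probability
0.2; 100 background peaks per replicate placed uniformly ≥ 600 bp away
from true sites; 30 mock peaks per condition placed uniformly. The DE
table draws negative-binomial counts (dispersion 0.05, gene means
lognormal around 200) with a 2³-fold WT/mutant effect for 50
bound-activated and 50 bound-repressed genes plus 40 unbound DE genes
under the low-Cu contrast; the control contrast is null. Significance
is a Wald-style two-group normal approximation on log2 counts with
Benjamini–Hochberg adjustment — deliberately not a shrinkage DE model,
since the pipeline consumes only (log2fc, padj).

One `numpy` Generator seeded once drives everything, consumed in a
fixed documented order, so a seed reproduces the file set byte for
byte. What the generator does **not** emulate: read-level noise, peak
shape and summit structure, chromatin-driven background clustering,
copy-number or mappability artifacts, alternative TSSs, and correlated
replicate failure. Passing tests therefore demonstrate correctness of
the downstream arithmetic and robust recovery under idealized noise,
not performance on real sequencing data.

Expected behavior under the reference settings is analytically
anchored: with dropout p and support threshold 2 of 4, per-site
recovery is `P(Binomial(4, 1−p) ≥ 2)` (e.g. 11/16 at p = 0.5), which
the test suite checks within three binomial standard errors at 200
sites.

## Numerical and degenerate-input choices

- Exactly representable arithmetic where possible: window bounds and
  centers are floats of integers (k or k + 0.5), so comparisons are
  exact; the f·2000 metagene mapping is a single multiply/divide.
- Empty inputs return empty-but-valid outputs (empty BED, zero
  histograms, p = 1 at k = 0); an empty peak file or gene list warns.
- Duplicate peaks from one replicate are deduplicated with a warning;
  duplicate (gene, contrast) DE rows are an error.
- Ties in the merge sweep are broken by (chrom, start, end, replicate),
  making output order and names deterministic.
- `min_frac` must lie in (0, 1]; window fraction must be positive;
  padj thresholds in (0, 1]. All parameters are validated before any
  stage runs.

## Known limitations

- Single-linkage consensus can chain peaks into long components in
  pathological tilings (each neighbor pair satisfies 80% but the ends
  do not overlap); the merged-length invariant still holds.
- Whether the original analytic choice re-applied the merge rule to
  already-merged segments is an open question; single linkage on
  originals is this package's documented choice and `min_frac` is
  configurable.
- The promoter window (2 kb) and the DE thresholds are conventions, not
  derived quantities; published candidate counts are sensitive to both.
- The scanner is exact-match only; weak/partial motif instances that a
  PWM would score are invisible to it.
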