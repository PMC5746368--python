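# Methods

## Coordinate model and breakpoint→protein mapping

External files use 1-based inclusive genomic coordinates; internally all
intervals are 0-based half-open. A breakpoint is the junction base: the
last retained base of the 5' partner's transcript, or the first retained
base of the 3' partner's, both in transcript orientation. On the minus
strand the retained 5' prefix is the genomically-last part of the locus;
all codon arithmetic is done after reordering CDS bases into transcript
orientation.

For a 5' partner with `r` retained CDS nucleotides, the retained protein
prefix is `⌊r/3⌋` complete codons (capped at the protein length; the stop
codon never counts) with `r mod 3` residual junction nucleotides. For a
3' partner whose first retained nucleotide is CDS position `j`, the first
fully retained codon is `⌈(j−1)/3⌉ + 1`; the value `protein_length + 1`
encodes "no coding residue retained". A fusion is in frame when the
residual nucleotides on the two sides of the junction complete a codon:
`(r₅ mod 3 + r₃ mod 3) mod 3 = 0`.

Degenerate inputs are total, not errors: a breakpoint upstream of the CDS
maps to position 0 (5' role) or codon 1 (3' role); downstream of the CDS
to the protein length (everything retained) or `length + 1` (nothing).
Intronic breakpoints contribute no coding sequence and therefore behave
like the nearest exon junction; a `strict` switch turns them into errors
instead. Breakpoints are *not* restricted to exon junctions in the
retention module, only in the synthetic generator.

## Retention rules

* 5' role: feature `[s, e]` retained iff retained codon count `≥ e`.
* 3' role: retained iff first retained codon `≤ s`.
* A junction strictly inside the feature yields "not retained" for both
  roles — a partial domain is functionally suspect, so the conservative
  call is made.
* The boundary case (junction exactly at a feature edge) counts as
  retained by default; `include_boundary=False` excludes it. Only
  features abutting a junction are affected.
* Isoforms: a feature is retained for the fusion if **any** annotated
  isoform retains it (evidence union). Adding an isoform can only turn a
  verdict from lost to retained, never the reverse.
* A TF partner with no annotated features classifies as a TFFG with
  `binding_domain_retained = False` and is reported separately.

The fast arithmetic path is validated against an exhaustive oracle that
enumerates the three genomic bases of every codon and tests side-of-
junction membership directly; the property suite and an acceptance check
require 100 % agreement, including intronic and boundary breakpoints on
both strands.

## Enrichment

Per feature category, a one-sided hypergeometric upper tail on the 2×2
(TFFG events vs all other fusion events) × (category retained vs not).
The counting unit is one fusion *event* (sample × fusion); a category
counts once per event however many of its features are retained
(presence/absence, avoiding domain-count inflation). A `unit="pair"`
switch collapses to unique gene pairs. Significance is a raw p < 0.001
cutoff; no multiple-testing correction is applied at this stage, which is
deliberate and documented — the categories form a small fixed vocabulary
of 34 and the cutoff is already stringent.

## Recurrence scores

DoF is the product of the three diversity counts (distinct cancer types,
distinct partners, distinct breakpoint coordinates within the TF gene)
over the TF's binding-retained events; breakpoint identity is the exact
genomic coordinate, so coordinate-level duplicates collapse. MAII =
obs/DoF; the sub-unity branch of the transform is tMAII = −DoF/obs, the
negative reciprocal, which spreads scores below 1 onto a symmetric scale
with |tMAII| ≥ 1 always. Reported tables round half-up to two decimals;
classification always uses unrounded values. Class boundaries: eTFinFG
iff tMAII > 1 (the fixed point tMAII = 1 is *neither*); peTFinFG iff
tMAII < −1 and DoF > 8.

## DETG testing

For each recurrent binding-retained fusion (same gene pair, same cancer
type, ≥ 2 positive samples — below that the test is refused, not
degraded), the union of the TF partners' target genes is tested,
fusion-positive vs all other samples of that cancer type (carriers of
other fusions stay in the negative group; carriers of the same fusion are
excluded regardless of frame). Wilcoxon rank-sum, two-sided: exact
distribution when both groups have ≤ 25 samples and the pooled data are
tie-free, normal approximation with continuity and tie correction
otherwise. Benjamini–Hochberg is applied within one fusion's target
family only; no cross-fusion correction. log2FC is the difference of
group means on the already-log2(count+1) scale, so the default threshold
0.585 = log2(1.5); significance requires |log2FC| ≥ 0.585 and q < 0.1
(strict inequality). The in-frame vs out-of-frame contrast of the same
fusion uses the identical machinery with q < 0.2 and the in-frame group
on the reported `mean_fg` side.

## Network

Directed multigraph: 5'→3' edges keyed by cancer type, so the same
fusion in two cancer types is two edges; edge attribute `n_samples`, node
attributes `tmaii`/`tf_class` for TFs only (partner nodes carry no
sentinel). TFs with tMAII exactly 1 are dropped by default together with
fusions whose only TF partners are such — a single observation per
possible isofusion carries no prioritization signal. GraphML export is
lossless (round-trip tested); SIF export writes sibling node/edge
attribute tables since the format itself carries none.

## Synthetic cohorts

The generator emulates the pipeline's five inputs with known truth. Gene
models: 1–3 isoforms per gene, 2–7 exons, CDS always a codon multiple,
both strands, disjoint loci. The first isoform of every gene uses a
regular 7-exon layout with 90 nt coding chunks, so junction-to-junction
fusions between first isoforms are in-frame by construction; other
isoforms have arbitrary chunk lengths, giving background fusions a
mixture of frames that is always labelled from the CDS arithmetic, never
sampled. Every TF's first isoform carries a DNA-binding feature at
residues 5–25, upstream of all junctions, so a 5'-TF junction fusion is
always binding-retained.

Planted recurrence: each planted TF receives an exact (cancer types,
partners, breakpoints, samples) structure by cycling events through the
cross product; partner genes and samples are reserved so background
events cannot perturb the planted counts. Default plantings are one
single-isofusion TF with 15 positive samples and one diverse TF with
3×3×5 structure and 10 samples — the two extremes of the recurrence
spectrum. Defaults (60 genes, 15 TFs, 3 cancer types × 40 samples, 60
background events, noise sd 0.5 on the log2 scale, planted shift ±2.0 on
half of a TF's targets) keep a full run in well under a second while
leaving every stage non-trivial; statistical calibration checks use 20 vs
150 samples and 40 targets per replicate, sized so the Monte-Carlo error
of a 100-replicate null run is a few percent.

Expression is baseline-per-gene Uniform(4, 10) plus Gaussian noise on the
log2(count+1) scale, truncated at zero; planted shifts (alternating sign)
are applied only in fusion-positive samples of the fusion's cancer type,
and each gene is shifted on behalf of at most one planted TF so effects
never leak into another TF's negative group. Ground truth (oracle
retention verdicts, per-TF counts, per-gene shifts) is written to
separate `truth_*.tsv` files that the pipeline never reads.

What the generator does **not** emulate: read-level evidence, sequence
content, splicing or copy-number effects, correlated expression between
genes, library-size artefacts, and intra-exon breakpoints (accepted by
the retention module but not generated). Passing tests therefore
demonstrate correctness of the coordinate arithmetic, the scoring
algebra and the statistical machinery under idealized noise — not
robustness to the pathologies of real fusion callers or RNA-seq
normalization.

## Numerical choices

* Rounding of reported scores: decimal half-up to 2 places (not banker's
  rounding), matching conventional table formatting; internal values stay
  exact.
* Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, …)`; validated
  against an exact combinatorial sum for all N ≤ 60.
* BH via `statsmodels.stats.multitest.multipletests(method="fdr_bh")`;
  validated against a direct sort/cummin step-up implementation.
* Determinism: every stochastic component draws from
  `numpy.random.default_rng(seed)`; reruns are byte-identical.

## Known limitations

* Frame inference for unknown-status fusions requires both partners'
  gene models; otherwise the record is excluded and reported.
* Feature annotations longer than an isoform's protein are skipped for
  that isoform (accession reused across isoforms of different lengths).
* The DoF > 8 recurrence bar and the α/FC/q defaults are inherited
  conventions, exposed in `RunConfig` but not re-derived here.
* The published cohort-scale funnel (thousands of fusions across 13
  cancer types) is not reproducible from synthetic data; cohort-level
  claims are covered by property tests and planted-truth checks instead.
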