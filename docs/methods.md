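# Methods

## Scope and model

`polygenespace` estimates gene-family copy numbers in a polyploid genome
from low-coverage shotgun reads without a whole-genome assembly, and
orders unanchored gene-bearing sequences along a genetic map via
conserved synteny. The core quantity is the **position-specific
hit-count profile**: for one orthologous-group representative protein
(OGR) of length L amino acids, `counts[i]` is the number of *distinct*
sub-assemblies whose spliced alignment covers position i. Under ideal
conditions each resolvable gene copy contributes exactly one
sub-assembly tiling the template, so the profile plateaus at the copy
number. The call is made robust to partial coverage by the cumulative
coverage distribution over *covered* positions only:

    fraction(h) = |{i : counts[i] >= h}| / |{i : counts[i] >= 1}|
    copy_number = max{ h : fraction(h) >= C }

`fraction(1) = 1` by construction, so a covered template never reports
0; an uncovered one reports 0. C (default **0.9**) is the minimum
fraction of the covered template that must reach the count; the estimate
is non-increasing in C.

## Alignment conventions

* Percent identity is matches / aligned columns, gap columns counting as
  mismatches, ×100. All thresholds are inclusive (≥).
* Internal coordinates are 0-based half-open; serialized files are
  1-based inclusive (12-column tabular hit format).
* Translated alignment: all six frames, frames split at stop codons (no
  read-through), each segment locally aligned with BLOSUM62. Gap
  opening/extension is deliberately expensive (−12/−6) so a local hit
  cannot bridge a translated intron with one cheap affine gap — spliced
  coverage is the chainer's job. Within a frame segment, repeated
  Smith–Waterman (best hit, then recurse into unaligned flanks, ≥15 aa)
  yields multiple HSPs when a segment spans several exons.
* Spliced chaining: maximum-score subset of HSPs co-linear on template
  and query (same strand), allowing unlimited unaligned gaps (introns)
  and up to 10 aa of template overlap between consecutive HSPs (local
  extensions overshoot exon boundaries by up to ~8 aa).
* Read binning filters: ≥30 aligned aa and a per-reference-species
  identity threshold (default 70%); each read goes to its first-best hit
  (max score, then longer alignment, then lexicographic OGR id), so bins
  partition the assigned reads.

## Sub-assembly and the mi dial

Reads of one bin are assembled by overlap-layout-consensus. An overlap
(suffix–prefix or containment, either strand) is accepted iff its length
is ≥ `min_overlap_bp` (40) and its alignment identity ≥ **mi**. mi is
the central trade-off: relaxed mi merges diverged homeologous copies
(undercount), mi=100 splits a single copy on sequencing errors
(overcount); mi=99 balances the two for ~1–3% homeolog divergence and
0.5% read error. Implementation choices that matter:

* **Candidate overlaps** come from shared exact 16-mers (diagonal
  voting); each candidate diagonal is verified with an edit-distance
  alignment of the implied overlapping substrings. Diagonals are ranked
  by identity before length: an off-by-one diagonal yields a near-equal
  overlap with strictly lower identity, and committing a wrong offset
  corrupts the layout consensus.
* **Merge consistency.** Greedy merging processes overlaps longest
  first (ties: identity, then read-id pair). A merge is committed only
  if every implied read-vs-read overlap of ≥100 bp in the merged layout
  also meets mi. Without this, a single chance 40–80 bp exact overlap
  between two otherwise ~2%-diverged copies bridges and collapses them.
* **Error correction.** Within a bin, k-mers (k=21) supported ≥3 times
  on either strand are solid; an isolated substitution error produces a
  short weak-k-mer run flanked by solid ones and is corrected to the
  substitution that re-solidifies the run. Copy-specific variants are
  supported at their own copy's depth and remain untouched; weak runs
  longer than k (diverged or thin regions) are left alone. This supplies
  the error tolerance a flow-space/quality-aware 454 assembler has
  natively; without it, read-vs-read identity at 0.5% error per read is
  centred exactly on 99.0%, putting mi=99 on a knife edge and leaving
  ~13% of reads as redundant singletons that inflate profiles.
* **Consensus** is per-column majority vote, quality-weighted when
  qualities are present, ties broken lexicographically. A second merge
  pass (iterated ≤3×) re-overlaps the consensus pieces: majority voting
  has averaged away read errors, so borderline same-copy overlaps heal
  while diverged copies stay apart.
* **Excluded reads** fall into three operational classes: ultra-short
  (<50 bp), over-represented (mean k-mer depth >10× the bin median;
  repeat-derived), and containment outliers (aligned to their layout
  consensus below mi−5 points).
* Output sub-assemblies = contigs (≥100 bp, ≥2 reads) + singletons.
  Contigs shorter than 100 bp are dropped from output but their reads
  still count as assembled.

## Simulators

`simdata` generates every input the pipeline consumes, seeded and
byte-deterministic:

* **Gene space** — genes (1–4 exons of 40–120 codons, introns 80–400 bp,
  UTRs 80–300 bp; rice-like architecture) separated by intergenic
  spacers, a configurable fraction of which is filled from an emitted
  repeat library (exact copies, so k-mer masking can find them).
  Multi-copy families diverge by a configurable per-coding-base
  substitution rate (non-coding at twice that rate); stop codons in the
  shared CDS are avoided by construction for family copies.
* **Reads** — 454-like: lengths Normal(400, 100) truncated to
  [50, template], both strands, per-base substitution probability 0.005,
  total bases within 2% of `coverage` × template bases. Read ids encode
  (template, start, strand) for truth tracking; nothing downstream may
  parse them outside tests. Homopolymer indels are not modelled.
* **Polyploid catalogue** — each annotated transcript is replicated
  `ploidy_factor` (3) times; every coding base substituted with
  p=0.01 and every non-coding base with p=0.04, uniform over the three
  alternatives. Substitutions are blind to codon structure, so premature
  stops can arise in copies (~a few % of copies) and legitimately
  fragment their translated HSPs.
* **Truth counting** — copies indistinguishable at the assembler's
  identity level cannot be resolved by any assembly, so calibration
  truth is taken after greedy longest-first redundancy collapse at the
  mi level (`collapse_redundancy`, global edit-distance identity).

What the simulators do *not* emulate: real maize/rice base composition,
flow-space 454 noise, indel errors (optional flag absent by default),
paralog interference between families, and chimeric reads. Passing
calibrations therefore demonstrate the internal consistency of the
method under its stated statistical model, not performance on real
wheat data.

## Calibration experiments

* **Diploid WGS** (`diploid_calibration`): 200 gene families (30%
  multi-copy up to 3 copies, 3% coding divergence) on a repeat-bearing
  chromosome; 5× reads; full pipeline at mi=99, C=0.9. Expected modal
  estimated:true ratio 1. Measured (seed 1): 1.0.
* **Polyploid catalogue** (`polyploid_calibration`): 200 transcripts
  triplicated with the stated SNV rates; expected modal ratio 3 at
  mi=99; mi=97 lowers the median estimate (homeolog collapse) and
  mi=100 raises it (error-driven splitting). Measured (seed 1): modal
  3.0; medians 2.0 / 3.0 at 97 / 99 and ≥3 at 100.

Problem sizes (200 families, ~0.5–4 Mbp of reads) are the package's
desk-scale defaults; each run takes one to a few minutes on one CPU.

## Sub-genome classification

Six features per sub-assembly: best-hit nucleotide identity and
length-normalized match score against each progenitor pool (edlib infix
alignment; hits below 70% identity are noise, and sub-assemblies lacking
a qualifying hit to *all three* pools are excluded). The default
classifier is an RBF SVM with libSVM-style pairwise-coupled probability
estimates (scaled inputs); logistic regression, Gaussian naive Bayes and
a decision tree are selectable for comparison. Pairwise coupling matters
at the rejection boundary: a point equally similar to all three pools
receives near-uniform probabilities and falls below the rejection
threshold (default 0.6), whereas sigmoid-calibrated one-vs-rest margins
over-commit there. Training labels are re-derived as the argmax
similarity; ties are dropped rather than guessed. Validation is
stratified k-fold (default 10) with per-class precision/recall/F1.

## GenomeZipper

Reference genes must be supplied in genomic order. Synteny blocks:
first-best translated hits (defaults 75% identity for the top-ranked
reference, 70% for the rest; ≥30 aa) are counted in a sliding window of
5 reference genes; windows with ≥3 hit genes qualify and overlapping
windows merge, trimmed to their outermost hit genes. Markers anchor to
genes by bidirectional best hits. Between two consecutive anchored
markers, genes of the highest-ranked reference carrying both anchors are
inserted in reference order, restricted to synteny blocks and
deduplicated per reference column; anchor indices contradicting marker
order emit the interval reversed with an inversion flag. References
lacking an anchor fall through to the next rank; leftover genes and NGS
ids are reported unplaced. Marker (cM) order is preserved exactly.

## Known limitations

* The assembler assumes substitution-dominated errors; indel-rich reads
  would need gapped layouts (offsets are integral).
* Copy-number calls for very short templates (<~60 aa) rest on few
  positions and are noisy.
* MCL is dense (O(n²) memory) — fine for desk-scale protein sets, not
  for hundreds of thousands of proteins.
* The sub-genome classifier presumes three progenitor pools; other
  ploidies require relabelling.
* Absolute genome-wide gene-count extrapolation is out of scope.
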