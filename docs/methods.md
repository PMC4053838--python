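# Methods

`wseq` models the transcriptome of early avian (ZW) embryos: sexually
dimorphic expression in blastoderm and embryonic gonad, discovery and
reassembly of W-chromosome transcripts from a broken genome annotation, and
divergence of W/Z gametologue pairs. All analyses run end-to-end on a
synthetic "mini-genome" whose generative parameters are the package's study
conditions; real count matrices and FASTA inputs drop in through the same
interfaces.

## The synthetic study

`wseq.synthetic.SimConfig` fixes the study conditions:

- **Design**: 2 tissues (blastoderm, E4.5-style gonad) × 2 sexes × 2
  replicates. Other replicate numbers are accepted for power exploration.
- **Mini-genome**: 8,000 autosomal, 500 Z, 20 W, 6 W_random and 80
  Un_random genes. The Z fraction (~5.8%) matches the chicken karyotype;
  keeping it realistic matters because TMM normalisation trims composition
  outliers and a grossly Z-heavy genome would leak the sex effect into the
  scaling factors.
- **Counts**: negative binomial, mean `fpkm × length_kb × libsize/1e6`,
  variance `μ + φμ²`. Library sizes are 20 million fragments jittered ±20%
  (a typical bulk RNA-seq depth; at 1M fragments the weakest W genes fall
  to single-digit counts and no test could see them). Gene-wise φ is
  log-normal around 0.04 (BCV 0.2, the standard figure for genetically
  identical laboratory animals) with sdlog 0.5 — wide enough that the
  empirical-Bayes moderation step has real work to do.
- **Dosage compensation**: non-compensated Z genes (all of them by default)
  have male mean = 1.6 × female mean in both tissues. Two MHM-like Z genes
  are female-only.
- **W genes**: female FPKM log-uniform on [5, 500]; male counts are hard
  zeros, reflecting the qPCR-level non-detection of W transcripts in males.
  A `w_male_leak_fpkm` switch exists for robustness experiments only.
- **Autosomal dimorphism**: 30 genes per tissue, 4-fold, dimorphic in
  exactly that tissue (half female-, half male-biased); 50 genes carry a
  5-fold tissue effect shared by the sexes.
- **Sequences**: gametologue pairs are evolved from a random Z CDS by
  uniform single-nucleotide proposals accepted with probability 1
  (synonymous) or ω (nonsynonymous); proposals creating stop codons are
  rejected; the process runs to a target substitution count, so repeat hits
  model multiple substitutions. No transition/transversion bias is modelled
  (the divergence estimator does not use κ either). 0.3 substitutions per
  codon at ω≈0.2 yields the ~90% W/Z cDNA identity regime the scaffolder is
  designed for.
- **Fragmentation**: transcripts are cut into n pieces with inter-fragment
  overlaps of at least `min_overlap` (default 60 bp); each junction
  independently becomes a gap with probability `orphan_prob`; fragments are
  randomly reverse-complemented and assigned fake evidence sources and
  pseudo-chromosomes.
- **Retroviral decoys**: back-translations of a packaged *synthetic*
  gag/pol-like toy protein panel (≤10% codon noise) embedded in adenine-free
  UTRs, so the back-translated ORF is exactly the transcript's maximal ORF.

What the generator does **not** emulate: read-level noise (no FASTQ, no
positional bias, no multimapping), isoforms and splicing, genuine W
repetitive elements, correlated library composition, and batch effects.
Passing tests therefore demonstrate correctness of the statistics and
assembly logic under the declared model, not robustness to every artefact
of real libraries.

## Dimorphism statistics

Normalisation is trimmed-mean-of-M-values on raw counts (trim 30% of
M-values, 5% of A-values, reference = sample with the most typical
upper-quartile count fraction), factors scaled to geometric mean 1.
Effective library size = factor × geometric mean of the raw sizes, used as
the GLM offset and for FPKM.

The NB GLMs use a log link and are fitted by IRLS vectorised across genes
(batched 4×4 normal equations), convergence |Δlog-likelihood| < 1e-8,
at most 100 iterations, φ fixed per gene during mean fitting. The full
model is parameterised as [intercept, gonad, female-in-blastoderm,
female-in-gonad], which spans the usual tissue×sex interaction space while
exposing each tissue's sex contrast as one coefficient.

Dispersion estimation maximises the Cox–Reid adjusted profile likelihood
(`ll − ½ log det XᵀWX`): with 8 samples and 4 mean parameters the
unadjusted profile likelihood underestimates φ by roughly half. The common
value maximises the genome-wide sum; gene-wise values maximise
`ll_g(φ) + w·mean_g' ll_g'(φ)` on a log2 grid around the common value with
parabolic refinement, where the prior weight w (default 10) plays the role
of effective prior observations. No abundance trend is fitted — with so few
residual degrees of freedom a trend would be noise. Values are floored at
1e-6.

Three likelihood-ratio tests (χ², 1 df each), each BH-adjusted within the
test: sex within tissue (drop that tissue's female coefficient), ratio
difference between tissues (interaction: full model vs additive
tissue+sex), and tissue average (tissue vs intercept-only, sexes pooled —
the "(male+female)/2" comparison). Reported log2 fold changes add an
offset-scaled pseudo-count of 0.125 to avoid infinities; positive means
female-biased (sex tests) or gonad-higher (tissue test).

The Z-dosage estimator takes, per tissue, each expressed Z gene's
male:female ratio of mean FPKM (expressed = mean FPKM ≥ 1 in at least one
sex; the floor is exposed because ratios of near-zero means are garbage)
and summarises them with a 5% trimmed mean computed on the log scale. The
log scale makes the estimate invert exactly under a sex-label swap and
removes the upward Jensen bias of averaging raw ratios; female-only MHM
genes land in the trimmed tail. On default simulations the estimate runs
≈3% below the generative 1.6 — residual Z-gene leakage into the TMM
trimming window; we report it as is.

## W discovery

A candidate is female-specific when mean female FPKM ≥ 1 in at least one
tissue and mean male FPKM ≤ 0.1 in all tissues. ORFs are maximal ATG→stop
spans, all six frames (de-novo fragments have unknown orientation), default
minimum 30 aa, trailing ORFs reaching the sequence end included. The
retroviral filter aligns every ORF against every panel protein (local,
BLOSUM62, affine gaps 11/1) and converts scores with the ungapped
Karlin–Altschul constants λ=0.267, K=0.041: `S' = (λS − ln K)/ln 2`,
`E = mn·2^(−S')`; a candidate is removed iff any ORF reaches E < 1e-3.
Panel hits in practice sit many orders of magnitude below that boundary, so
the fixed ungapped constants are adequate. The pseudogene filter removes a
candidate whose best frame-translation match to a known gametologue protein
covers < 50% of it or contains an in-frame stop within the aligned span;
both thresholds are our construction (the filter concept is standard, its
rule is not published) and every removal is logged with its reason.

## Scaffolded assembly

Because W/Z gametologue pairs are collinear and ~88–95% identical at the
cDNA level, the Z cDNA serves as an ordering/orienting scaffold. Placement
uses full-query infix edit-distance alignment (edlib HW mode) in both
orientations — full-query semantics avoid the end-trimming that local
alignment would inflict on fragments whose last bases mismatch the scaffold
— accepted at ≥ 80% identity over ≥ 50 bp, ties resolved toward '+' and the
leftmost location. Adjacent placements are spliced when their sequences
overlap ≥ 40 bp at ≥ 95% identity (common overlap-assembler defaults; both
exposed); the splice point is searched ±15 bp around the scaffold-predicted
offset. Consensus columns use an incremental majority vote with ties broken
by source priority (curated annotation > genome-guided > de-novo).
Non-overlapping contigs are joined with N-runs sized by the Z-scaffold
distance; a negative inferred gap is a conflict and the contigs stay
unjoined. Completeness is the fraction of the longest forward-frame Z ORF
covered by non-N consensus. Coordinates are 0-based half-open internally,
1-based inclusive in human-readable reports.

The model's known blind spots: insertions in W relative to Z longer than
the splice search radius would shift placements; rearranged (non-collinear)
gametologues violate the scaffold assumption and surface as conflicts.

## Gametologue divergence

Identity is computed from end-gap-free global alignments (DNA +2/−3,
gaps −5/−2; protein BLOSUM62, gaps −11/−1) over aligned columns, terminal
overhangs excluded. Codon alignment aligns the translations, back-maps to
nucleotides and drops gapped codons. dN/dS is the Nei–Gojobori counting
estimator: per-codon synonymous site fractions (changes to stops count as
nonsynonymous), observed differences averaged over all equally weighted
minimal mutational pathways with stop-passing pathways excluded, and a
Jukes–Cantor correction `d = −¾ ln(1 − 4p/3)`. Maximum-likelihood codon
models, κ and codon-frequency corrections are deliberately out of scope.
Sentinels: dN = 0 reports ω = 0.000 whatever dS; dS = 0 with dN > 0 is
"undefined" (never ∞); p ≥ ¾ is "saturated". Sliding windows (default 50
codons, step 10 — the profile figure convention; both configurable) emit
sentinel windows as missing values without dropping their axis position.

Combined expression compares female W+Z against male ZZ by summing counts
per female sample and applying the NB sex test to the summed "gene",
flagged at raw P < 0.01; no fold-change heuristic is involved. The
statistical test behind this comparison is our choice of instrument —
re-using the pipeline's sex test keeps the error model consistent.

## Problem sizes and numerical choices

Default test/acceptance workloads: 8.6k-gene default simulation (dispersion
estimation ≈ 10 s), 2000-gene null calibration, 20-gene scaffolding
benchmarks, 50 pairs × 300 codons per ω recovery setting. IRLS clips η to
±50 and μ below 1e-10; a 1e-10 ridge keeps the batched solves stable for
all-zero genes. The dispersion optimiser works on log φ in [1e-6, 5] with
xatol 1e-3. All randomness descends from one integer seed; pipeline stages
derive their own seeds by hashing the stage name (crc32, mod 2³¹) so stages
re-run standalone reproduce their in-pipeline output.

## Known limitations

- FDR-level guarantees are checked at the nominal 5% level on null
  simulations; with 4 residual df the χ² reference is approximate and
  slightly conservative dispersions can tip either way at more extreme
  thresholds.
- The female-specificity screen is threshold-based; lowly expressed W genes
  below FPKM 1 are invisible to it by design.
- The scaffolder reconstructs one W gene against one Z cDNA per call; no
  multi-gene joint scaffolding, no splice-graph awareness.
- dN/dS on assembled consensus requires a frame-clean (N-free) sequence;
  the pipeline falls back to skipping the pair (with a logged warning)
  rather than guessing a frame through an N-bridge.
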