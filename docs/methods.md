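# Methods

This note documents the models, conventions, parameter defaults and design
choices behind `fsneo`, and what the synthetic-data tests do and do not
establish about real data.

## Coordinates and variant application

All internal coordinates are 1-based on the CDS, position 1 being the first
base of the start codon, matching HGVS "c." positions as annotated in MAF
files. GFF3 intervals (1-based inclusive) are converted on ingestion;
minus-strand CDS features are reverse-complemented and concatenated in
transcript 5'→3' order.

Insertions are anchored *after* `cds_pos` (HGVS `c.N_N+1ins`, MAF
Start = End = N); deletions, SNVs and delins start *at* `cds_pos`. Beyond
stripping the shared leading base of anchored VCF alleles, indels are not
re-normalized (no left-alignment): annotated positions define "the mutation
site", and silently shifting them would move the peptide anchor. A
reference-allele mismatch during application is a hard error naming the
transcript, position and both alleles, because it almost always indicates a
coordinate-convention bug upstream rather than a data problem.

Multiple variants on one transcript in one patient are applied
independently — one functional peptide per variant. Phasing is unknown in
this setting, and per-mutation accounting is what the cohort statistic
needs.

## Translation and the functional peptide

Translation uses the standard genetic code (61 sense codons; stops TAA,
TAG, TGA) taken from biopython's table. Codons containing `N` translate to
`X` and never terminate: ambiguity must not fabricate a premature stop,
which would silently shorten peptides.

The functional peptide starts at the first codon containing altered
nucleotides, with the frame anchored at the native start codon of the
*mutated* sequence — this is exactly what a ribosome initiating at the
native AUG reads. That first codon may still encode the wild-type residue
(e.g. a deletion late in a codon); the default keeps it, since the anchor
is the mutation site, not the first changed residue. The
`start_at_first_changed_aa` option trims to the first residue differing
from the native protein for users who want the strictly non-self suffix.

Stop-lost read-through: when the shifted frame exhausts the CDS, translation
continues into the transcript's 3' flank; if no stop is found at all the
peptide is reported with `stop_found=False` and its observed length, rather
than being dropped. Length statistics must not silently lose the longest
candidates; downstream summaries expose an exclusion switch
(`include_stop_lost=False`) so both conventions are one flag apart.

## Geometric length law, and why "clean" ORFs are not neutral

Under i.i.d. uniform nucleotides, each shifted-frame codon is an
independent uniform triplet, so the FP length is geometric with per-codon
stop probability 3/64 and P(L ≥ n) = (61/64)^n; P(L ≥ 60) ≈ 0.0561.

A subtlety worth recording: conditioning frame 0 to contain *no* internal
stop codon (i.e. drawing codons uniformly from the 61 sense codons) is not
neutral for the shifted frames. Counting patterns shows the +1- and
−1-frame per-codon stop probability becomes 192/61² ≈ 0.0516 — above the
unconditioned 192/4096 = 3/64 ≈ 0.0469 — because excluding stop codons
shrinks the sample space without removing any of the shifted-frame stop
patterns. Over 60 codons the difference compounds to a ~25% deficit in
P(L ≥ 60). Consequently:

* `generate_transcriptome(clean_orf=True)` (the default) produces curated
  ORFs — ATG start, terminal stop, no internal in-frame stop — appropriate
  for fixtures that mimic annotated transcripts;
* the `uniform_sequence` cohort model and `simulate_fp_lengths` draw CDS
  interiors as unconstrained i.i.d. uniform bases (internal frame-0 stops
  possible), which is the distribution the analytic law actually describes
  and the model used when the law is checked empirically.

Real coding sequences are closer to the curated case (and additionally
non-uniform in codon usage), so the analytic law is a model statement, not
a claim about observed tumor cohorts.

## Epitope scan and CTA classification

Windows are all contiguous k-mers, 1-based starts, defaults 8–11 for MHC
class I and 15 for class II (both configurable). "Strong binder" is
rank-based: predicted rank ≤ 1% for the allele, threshold inclusive. An
absolute-IC50 mode is deliberately not the default because thresholds are
predictor-specific, while percentile ranks are comparable across tools.
Binder counts are distinct (start, length, allele) windows — overlapping
windows each count, as scan-level counts do. A chain is a complete T cell
antigen iff both classes contribute at least one strong window; the call is
monotone in evidence (more calls can only confirm it).

Prediction is pluggable. `TablePredictor` ingests an external tool's
results TSV (peptide, allele, ic50_nM, rank_percent; affinity derived as
1/IC50 × 100); the package never shells out to licensed binaries.
`MockPredictor` is a deterministic test double, not a trained model: the
score is the count of anchor-motif matches (motifs loosely shaped after
H2-Kb / H2-Db / I-Ab preferences) plus a hash jitter in [0, 1), so a
full-anchor peptide always outranks any peptide missing an anchor, and the
rank is the score's percentile within a seeded random background
(rank = 100·(k+1)/(N+1) with k background scores strictly above). It exists
so binder-dependent logic is exactly reproducible with no model files.

A prediction failure on a window is recorded as a call with NaN scores and
a warning — never silently dropped — so scan coverage is auditable.

## Missense filter cascade

Stage 1 keeps candidates whose best mutant window ranks ≤ 1% on any scanned
allele (defaults H2-Kb + H2-Db); stage 2 requires the mutant/wild-type
affinity ratio at the best window's own coordinates and allele to be
≥ 1.0 (mutant binds at least as well); stage 3 requires transcript
FPKM ≥ 1.0, with missing expression failing explicitly as
`no_expression`. The ratio and FPKM cutoffs are honest defaults chosen to
be conservative and auditable — the cascade's structure is fixed but both
numbers are prominent parameters, and every candidate carries per-stage
pass flags so any reanalysis can re-cut without re-scoring. The survivor
set is anti-monotone in every threshold, which the tests assert.

## Cohort statistics and survival

TMB is the raw somatic mutation count, divided by the capture size in Mb
when given (default 38 Mb in the simulator, a typical exome). "Long FP"
uses strict inequality (> 120 AA), so a 120-AA peptide is short. The
TMB/frameshift-count "high" groups default to the top 20% with boundary
ties included (`numpy` quantile, `method="higher"`); a median split is one
option away (`top_quantile=None`, CLI `--split median`), since both
conventions are common and they answer slightly different questions.

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`. The test suite pins the statistic to an independent hand
computation (six subjects, times 1–6, alternating groups:
chi-square = 529/1091) and checks operating characteristics on simulated
cohorts: power ≥ 80% at hazard ratio 0.5 with n = 400 and 30% censoring,
size ≤ 8% at hazard ratio 1.0 (200 seeded replicates each).

## Knock-in designer

Every CDS position (optionally codon boundaries only) is evaluated by
building the +2-nt and +1-nt insertions — adenines by default, configurable
because stop creation depends on inserted content — extracting both
functional peptides and ranking sites by |len(FS1) − len(FS2)| descending,
site ascending. Target transcripts are filtered to the top 1% of the
supplied expression distribution before re-ranking. The inserted cassette
itself is not modelled; only the net frame consequence matters for the
downstream peptide. One non-obvious property, asserted in tests: within a
homopolymer run of the inserted base, all insertion sites give the *same*
mutated sequence, so a +3 site shift moves the peptide start by exactly one
codon — both lengths drop by 1 and their difference is invariant.

## Synthetic-data generator

The generator is deterministic given its config and seed, down to
byte-identical output files. Defaults describe a desk-scale version of an
exome-sequenced colorectal-cancer cohort: 100 patients; mutation counts
negative-binomial (mean 20, dispersion 5); InDels 12% of calls with sizes
1/2/3 nt at probabilities 0.55/0.30/0.15 (so some indels are in-frame);
transcript expression log-normal(µ=1, σ=1.5) FPKM; 300-nt 3' flanks;
survival exponential with baseline hazard 1/40 per month, long-FP hazard
ratio 0.5, and independent exponential censoring tuned to ≈ 30%.

Two FP-length models:

* `uniform_sequence` — lengths emerge from the sequence model (geometric
  law holds); long-FP patients are correspondingly rare (~0.3% per
  frameshift), so survival-contrast studies at realistic group sizes use
  either `simulate_survival` directly (explicit group fractions) or the
  implanted model;
* `implanted` — each patient receives one knock-in frameshift with an
  exact target length on a dedicated transcript (25% of patients drawn
  long, 130–240 AA; the rest 5–100 AA). Implantation edits the fewest
  bases needed: stops in the shifted frame within the target window have
  their middle base flipped to C (which turns any stop into a sense
  codon), and the terminal stop is written as TAA; the native frame is
  preserved wherever possible. Round-trip exactness through the standard
  extraction path is asserted at construction time.

Ground-truth per-patient maximal FP lengths are computed by a separate
direct string-splice-and-scan routine inside the generator, kept
independent of the pipeline's extraction code, so the round-trip test
compares two implementations rather than one with itself.

What the generator does **not** emulate: mutational signatures and
context-dependent indel rates, isoform structure, expression–mutation
correlation, copy number, tumor purity, and clinical covariates. Passing
round-trip and law tests therefore validates the pipeline's mechanics and
statistics, not biological claims about any real cohort.

A companion module, `synthetic_reference`, fabricates a transcript-scale
CDS in which a designated single-base deletion (by default at position 331)
yields an exact target peptide length (default 216 AA). It is clearly
labelled synthetic: it demonstrates the deletion/extraction geometry at
realistic scale when no real reference sequence is available, and shares
nothing with any real gene.

## Problem sizes and numerical choices

Simulation sizes used by the tests and the acceptance script — 10,000
frameshifts for the length law, 100 patients for the cohort round-trip,
200 replicates of n = 400 for power/size, 20 toy transcripts for the
designer oracle — were chosen so each check has clear statistical
resolution (e.g. the 99% binomial band at n = 10,000 is ±0.006 around
0.056) while the whole suite stays interactive. Thresholds are compared
inclusively (≤ for ranks, ≥ for quantile cuts) everywhere; tie-breaks are
deterministic (site ascending, transcript id lexicographic) so outputs are
stable across runs and platforms.

## Known limitations

* HGVS parsing covers the coding-DNA forms that occur in somatic MAFs
  (substitution, del, ins, dup, delins); intronic/UTR offsets are skipped
  with a reason, by design.
* VCF→CDS projection handles variants fully inside CDS features;
  splice-spanning and multi-allelic records (beyond the first ALT) are
  skipped with reason codes rather than guessed at.
* The log-rank comparison is two-group; no Cox adjustment or multivariate
  modelling (the simulator's hazard-ratio recovery test uses `lifelines`'
  Cox fit, but the analysis surface does not expose one).
* The mock predictor's ranks are calibrated against its own random
  background, not against any real binding data; CTA counts obtained with
  it characterize the scanning logic only.
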