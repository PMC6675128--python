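# Methods

## The system being modelled

Mature human tRNA-His-GUG is 76 nt in the packaged reference (stored in
the DNA alphabet), with the non-templated 5' G at position -1 (core index
0), the anticodon GTG at core 34-36, m1G at core 37, m1A at core 58 and
the non-templated 3' CCA. Display numbering follows the field convention:
sparse anchors (0 -> -1, 37 -> 37, 58 -> 57, the last reflecting the
skipped variable-loop position) with linear interpolation between them;
only the anchored positions are guaranteed, full Sprinzl numbering is out
of scope.

The miR-4454 decoy is derived, not transcribed from an annotation: the
last 21 bases of the tRNA core with the m1A-position base replaced by G
(the annotated miRNA sequence templates G where the tRNA carries modified
A). A window that excludes the m1A index leaves the decoy undefined and is
rejected. Three fixed arbitrary background entries (106, 68 and 22 nt)
give enrichment analysis a null set.

All internal coordinates are 0-based half-open on the unpadded core;
padded coordinates exist only inside the aligner and in SAM output
(1-based there, with the core offset in a `ZC` tag).

## Synthetic TGIRT-seq generator

The generator is the package's stand-in for raw sequencing data; its
defaults define the study conditions and are fixed, not tuned per run.

Per molecule, in order: (1) Dicer cleavage (full-length molecules only, at
most one cut); (2) reverse transcription 3'->5' with premature stops,
3'-end fall-off, misincorporation and a non-templated 5' T; (3) uniform
substitution sequencing error. One top-level seed; molecule i uses the
substream `default_rng([seed, 1, i])`, so libraries are byte-identical per
seed. Quality strings are constant "I" because no stage uses them.

Defaults (per-molecule probabilities unless stated):

| parameter | default | rationale |
| --- | --- | --- |
| cut after 54 / 57 / 60 | 0.22 / 0.25 / 0.07 | calibration: total 0.54 reproduces the ~54% full-length depletion of the 5'P substrate; the dominant product is the 18-mer starting at the m1A base; 54/57 sit on the double-stranded TPsiC stem, 60 in the loop |
| methyl sensitivity (multiplier on the cut probability for 5'Pme2) | 0.2 / 0.2 / 0.9 | stem cuts strongly inhibited by phospho-methylation, loop cut barely |
| m1A misincorporation at 58 | rate 0.30, spectrum T .6 / G .3 / C .1 | the T/G-dominated read-base spectrum characteristic of TGIRT at m1A |
| m1G misincorporation at 37 | rate 0.08, spectrum T .4 / C .3 / A .3 | partial methylation at G37: detectable but weaker than m1A |
| premature stop at 37 | 0.25 | the m1G roadblock that floods the short partition with reads starting at G37 (39 nt) |
| non-templated 5' T | 0.15 | non-templated addition at the cDNA 3' end, seen as a sense-strand 5' T |
| 3'-end fall-off | 0.05, 1-3 nt uniform | generic RT fall-off / incomplete 3'->5' chemical synthesis |
| sequencing error | 0.002 per base | typical short-read substitution rate |

The stop convention: a stop at core index i yields a sense read beginning
AT i (the roadblock base is the last one copied), so stop sites appear as
5'-end peaks of the short partition at the modified position itself.

Pre-made fragment species (3' products starting at core 50/55/58) model
cellular fragments with heterogeneous 5' ends; they carry a cleavage 5'P.
Composition presets: `mock`/`dicer_5p`/`dicer_5pme2` are single-substrate
in-vitro arms; `pulldown_b3df` vs `pulldown_control` emulate an IP where
only the tRNA and its fragments are specific; `shB3D` doubles the fragment
proportion of `shNC` (0.02 vs 0.01 of the pool); `provenance_mix` is a
50/50 fragment/decoy mixture. What the generator does NOT emulate: adapter
content, paired-end structure and merging, PCR duplicates, ligation
biases, a realistic transcriptome background, or indel sequencing errors.
Passing tests therefore demonstrate correctness of the analysis given the
artifact model, not performance on real libraries.

## Aligner

Local (Smith-Waterman) alignment with affine gaps over the padded
sequence: match +2, mismatch -3, a gap of length L costs -5 - 2L, N
columns score 0, minimum reported score 20 (about a 10-nt perfect match;
blocks spurious short hits), minimum read length 15. The DP engine is
Biopython's `PairwiseAligner`; CIGAR construction, pad accounting and
primary selection are native. Equal-score tracebacks within an entry are
resolved deterministically - smaller core start, then shorter, then
lexicographically smaller CIGAR - evaluated over the first four co-optimal
tracebacks the engine enumerates (the full co-optimal set can be
exponential; four suffices for every tie class the pipeline produces, and
determinism holds regardless). Across entries, every score-tying alignment
is primary with weight 1/k.

Read bases aligned to pad Ns fold into the soft-clip counts and never move
the core span. Consequence worth knowing: a terminal mismatch is clipped,
not aligned (clipping costs 0, a terminal mismatch -3). A fragment whose
first base is a misincorporated site base therefore starts one position
downstream; the provenance classifier compensates by reading a single
clipped base adjacent to an alignment starting at site+1, and the RT-stop
rate at position 37 is measured against the expectation
p_stop x (1 - p_misinc37).

Equivalence is defined against the in-repo full-matrix Gotoh oracle
(tests), not against any external mapper: scores must be equal and end
coordinates must lie in the oracle's optimal set, on random and
mutated-substring instances up to 40x60.

## End profiling and cut calling

End profiles are primary-weighted distributions of the first
(five_prime) or last (three_prime) core-aligned position. The packaged
workflow computes them on the >50 nt partition: short 3' products and
RT-stop reads would otherwise inflate the denominator of the full-length
fraction, which is what makes the treated/mock ratio estimate 1 - c
(every 5' cleavage product is longer than 50 nt for the modelled cut
sites, so the long-read denominator is conserved between arms).

">73 nt" is interpreted as aligned core span >= 74, not raw read length,
so a non-templated 5' T cannot rescue a truncated molecule. "Normalized"
full-length counts are per-entry fractions (the in-vitro assay has a
single substrate), not library RPM. The significance test on replicate
ratios is a two-tailed Welch t-test - the original analysis reports a
p-value for n=2 vs 2 without naming a test, so this is a documented
stand-in. Cut calls use min_delta 0.01 and min_frac 0.02 with
adjacent-index merging only (cut heterogeneity appears as discrete,
non-contiguous peaks); 3'-end calls report the 5' product's last base,
i.e. the position cut after.

## Modification calls and provenance

Thresholds (mismatch >= 0.05, T+G share >= 0.6, stop >= 0.1, depth >= 50)
were chosen once against the generator's defaults: they sit several
standard errors away from both the planted signals (0.30/0.9/0.23) and the
sequencing-error background (0.002) at the depths the pipeline produces.
tg_share excludes deletions from its denominator; mismatch_fraction
includes them.

The provenance verdict for G-at-site reads deliberately tolerates up to
two non-site mismatches against the decoy before calling annotated_mirna
(sequencing error makes literal perfect-match verdicts misroute several
percent of true decoy reads to ambiguous); `max_decoy_mismatches=0`
restores the strict rule. A G-at-site read with no 5' extension remains
the one intrinsically ambiguous class - m1A can be misread as G - and the
classifier accepts that error mode by design rather than guessing.

The knockdown fragment quantity (RPM of tRNA 3'-fragment reads) counts
primary alignments to the decoy plus alignments to the tRNA with core
start >= 50: fragment 5' ends live in the TPsiC window, while RT-stop
reads start at 37 and are excluded. Enrichment uses a +1 raw pseudocount
and a fold-change cutoff of 4 - the source analyses state no numeric rule,
so both are documented, configurable choices.

## Problem sizes

Full-scale checks run 20,000 molecules per Dicer-assay arm (two replicates
for the depletion estimate), 10,000 reads for the provenance mixture, and
1,000 random instances for the aligner oracle; these sizes put every
recovered parameter's 3-standard-error band well inside the tolerances
being checked while keeping a full run in tens of seconds on one core.
Unit tests use 300-6,000-molecule libraries for the same contracts.

## Known limitations

* The per-site cut probabilities and methyl sensitivities are
  calibrations; every check that uses them is parameter recovery, not
  external truth.
* Display numbering is anchor-interpolated and only exact at the anchors.
* The aligner is for references of a few thousand short entries; there is
  no indexing, spliced alignment or quality-aware scoring.
* Single-read provenance cannot resolve G-at-site, non-extending reads;
  population-level spectra can, but the classifier reports per-read
  verdicts only.
* Real-library phenomena outside the artifact model (see generator
  section) are untested by construction.
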