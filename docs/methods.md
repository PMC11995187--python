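# Methods

This note documents the models, statistics and numerical choices behind
`selexdimer`, and what the synthetic-data experiments do and do not show.

## Motif model and scanning

A motif is a position probability matrix (PPM) over A,C,G,T.  Information
content per column is `2 + Σ_b p_b log2 p_b` bits (`0·log 0 = 0`); total IC
is the column sum and mean IC the per-column average.  Scanning scores a
window by the log2-odds `Σ_i log2((p_i(b_i)+ε)/(bg(b_i)+ε))` with a
pseudocount `ε = 1e-3` (so consensus matrices built from IUPAC strings,
which contain exact zeros, still score finitely).  Ambiguous bases (N)
contribute 0 bits; windows more than half ambiguous are dropped.

Site significance uses the *exact* null distribution of window scores under
the i.i.d. background: scores are discretised to 0.01-bit bins and the null
pmf is built by convolving the per-column score distributions.  A p-value
threshold therefore maps deterministically to a score cutoff, and for motifs
up to ~10 columns the mapping is verified against exhaustive enumeration of
all 4^L windows in the tests.  Two consequences worth knowing:

* a short degenerate motif may be unable to reach a strict p-value at all
  (a 7-column motif with one two-fold-degenerate position has a best-score
  tail of 1.2e-4, so no site passes p = 1e-4) — analyses of short monomers
  therefore use longer composite motifs or laxer cutoffs;
* for long hard-consensus motifs the combinatorial tail makes nominal
  cutoffs admit surprisingly many mismatches (p = 1e-4 on a 14-informative-
  column 0/1 motif admits 3–4 mismatches).

Motif comparison is `1 − max` over relative offsets (≥ 4 aligned columns)
and orientations of the mean column-wise Pearson correlation, clipped to
[0, 1]; it is symmetric and invariant to reverse-complementing either
argument.  The motif specificity space is embedded by classical (Torgerson)
MDS — double-centred squared distances, top-2 eigenvectors — which is
deterministic up to sign (signs are fixed by convention).

## SELEX discovery

Reads are tiled into non-overlapping 40-bp segments from position 0;
remainders are discarded.  Seeds are 8–10-mers whose size-normalised
both-strand frequency ratio between an enriched cycle and the input library
(pseudocount 1 on counts) exceeds a threshold (default 2.0) *and* is a local
maximum over all Hamming-1 neighbours.  Near-duplicate seeds — some gapless
alignment covering at least `min(k)−2` positions with at most one mismatch —
are merged keeping the more enriched seed.  The mismatch-1 rule is
deliberately strict: simulated (and real) enriched libraries contain
"jackpot" clones whose random flanks otherwise generate families of
spuriously distinct seeds, while genuinely different half-sites share no
near-exact alignment.

PWMs are built by multinomial-1 counting: column *i* counts windows (both
strands folded onto seed orientation) that match the seed everywhere except
possibly at *i*.  Columns are normalised with a pseudocount (default 1).
Discovered motifs are trimmed to the maximal contiguous run of columns with
≥ 0.25 bits around the strongest column; the contiguity requirement also
removes detached islands that arise when a seed sits inside a *dimeric*
site and the partner half-site bleeds into the flank columns.  Motif sets
are filtered by total IC < 1 bit, single-nucleotide runs (≥ 80 % of columns
sharing one top base), and near-duplicates (motif distance < 0.05, keeping
the higher enrichment).

E-MI quantifies library-level binding signal as the mutual information (in
bits) between 3-mer identities at every ordered pair of non-overlapping
positions.  The plug-in MI estimator of a 64 × 64 joint distribution is
biased upward by roughly `(Kx−1)(Ky−1)/(2N ln 2)`; the Miller–Madow
correction (using observed support sizes) is applied per pair.  The summary
score is the mean of the top-10 pair MIs.  Residual small-sample bias
remains in sparse regimes, so "zero" for an unenriched library is assessed
against a simulated i.i.d. null at the same read count, which is how the
tests phrase it.

## Dimer analysis

With `h` the half-site in monomer orientation and `rc` reverse complement,
the package's orientation conventions are `DR(s) = h N^s h`,
`IR(s) = h N^s rc(h)` (head-to-head), `ER(s) = rc(h) N^s h` (tail-to-tail).
Negative spacing overlaps the two elements; overlapping symbols take the
IUPAC intersection and an empty intersection marks the configuration
infeasible (reported as missing, never as zero enrichment).  For a
homodimer, relabelling the half-site to its reverse complement swaps IR and
ER; pipelines therefore canonicalise the half orientation (lexicographically
smaller consensus) before naming configurations.  Configuration scans
measure per-read fold enrichment `(f_sig+ε)/(f_bg+ε)`, `ε = 1/(n_bg+1)`, of
each grid pattern on both strands; an optional second half-site supports
heterotypic pairs (needed once a half-site has diverged — a pattern built
from the monomer half alone cannot see it), scanning the second half in both
orientations to cover all arrangement classes.

Half-site divergence compares each half-site submatrix of a dimeric motif,
oriented into the monomer frame, to the monomeric motif by fixed-offset
column Pearson distance.  The divergence flag threshold of 0.4 was chosen
from the simulation null — distances between two PWMs re-estimated from
split halves of the same planted mode stay well below 0.1, while unrelated
half-sites score near 1 — and is exposed as a parameter.  Cooperativity is
operationalised as `fold(dimer)/(fold(left)·fold(right))`; it discriminates
joint from independent half-site preference when half-site enrichment is
moderate, and is reported, not tested against a null distribution.

DNA-shape profiles average a pentamer→value lookup (e.g. minor groove
width) per aligned motif position across matched reads, with gap columns
inserted between half-sites so modes of different spacing align
half-site-to-half-site.

## Genome evaluation

Fragment scoring tiles the genome into non-overlapping 200-bp windows from
coordinate 0 (a step flag allows overlap) and scores each fragment with the
best site's `−log10 p` (exact null), taking the max over the motif set so
motifs of different lengths are comparable.  Positives for PR analysis are
fragments overlapping (≥ 1 bp) any top-n peak by rank score.  AUPRC is the
step-wise average precision `Σ_k (R_k − R_{k−1}) P_k` with tied scores
sharing one threshold; motif-set comparisons use a paired Wilcoxon
signed-rank test on precision at a matched recall grid (49 levels,
0.02–0.98).  Note that max-combining motif sets adds each motif's own random
score tail, so an uninformative added motif slightly *dilutes* precision —
the test is two-sided about that reality.

Shuffled-sequence controls permute each sequence (mononucleotide, default)
or apply an Altschul–Erickson Eulerian shuffle preserving all dinucleotide
counts; both are seeded.  TSS density counts motif-hit midpoints at
strand-oriented offsets per TSS and subtracts the density of the *reversed*
motif (columns reversed without complementation — a composition control
that is not the reverse complement), then smooths with a centred boxcar
whose divisor is the covered width.  Conservation profiles average the
per-base track around promoter hits (0 to −1 kb of TSSs, strand-aware)
aligned on motif start in motif orientation.

## The SELEX simulator

Selection follows an occupancy model: per-ligand weight
`w(x) = Σ_modes ω_m Σ_windows,strands exp(λ_m · score_m)` with per-mode
activity λ (multiplying the log2-odds score in bits) and cooperativity
ω ≥ 1 on dimeric modes; the per-cycle selection probability is
`s(x) = min(1, ns + cs·w(x))` with a nonspecific floor `ns` (default 0.002,
the fraction of junk ligands carried through a cycle) and a capture scale
`cs`.  The sequenced reads of cycle *k* are drawn exactly from
`p_k(x) ∝ p0(x)·s(x)^k` — selection applied *k* times to the i.i.d.
background `p0` — by self-normalised importance resampling from a proposal
that mixes background reads with reads carrying one planted PWM-sampled
site per mode.  This emulates selection from an effectively infinite
initial pool: bench experiments start from ~10^12 molecules, so every
strong site exists in the pool, whereas a literal finite pool of 5 × 10^4
random 101-mers would contain, in expectation, ≈ 0.03 copies of a
14-informative-position dimer site and no enrichment mechanism could ever
surface one.  Cycle 0 is a literal i.i.d. background sample.  All outputs
are pure functions of (parameters, seed).

The planted specificity-change model (`make_er1a_like_model`) has three
modes: the monomer (`ACCTAAY` by default), a distant ER8 homodimer of two
base halves (unchanged control), and a close ER1 dimer whose right half is
`CACGTGG` — dissimilar to the base half at 6 of 7 positions.  Activities
are parametrised by per-cycle capture probabilities of one full consensus
site (defaults 0.01 monomer, 0.5 distant, 0.9 close with ω = 4): the
dimeric modes dominate enrichment, emulating a factor whose homodimeric
binding carries the library.  This is the regime in which a half-site
specificity change is observable at desk scale at all — a site of the
changed dimer is intrinsically ~4× rarer per degenerate base-half position
in random sequence, so equal activities would leave it below k-mer
detectability at 50,000 reads.

Default scales: 50,000 ligands × 3 cycles of 101-bp ligands for SELEX
recovery; 2-Mb genomes with 500 peaks of 200 bp and 600 TSSs; 10^5 virtual
ligands for the in-silico control.  These run in minutes on one CPU and
give comfortable statistical margins for every recovery test.

## The genome generator

`plant_genome` draws an i.i.d. background genome, places non-overlapping
ranked peaks, TSSs and promoter CREs (offsets uniform in (−1000, 0),
gene-strand oriented), and sets conservation to a base level plus a boost
exactly over planted footprints.  Planted sites are exact consensus
realisations by default — sharp for site-recovery tests — or PWM samples
when a Motif is supplied.  The evaluation pipelines plant from *graded*
motifs (consensus mixed with 12.5 %… default `soft = 0.1` uniform mass per
column): hard 0/1 planting makes every site identical, which collapses PR
curves onto a few massive score ties and gives every dimeric CRE a perfect
monomer half-site, hiding exactly the affinity gradation that makes dimeric
motifs informative in real data.  With graded sites a realistic fraction of
dimeric CREs carry weak monomer halves and are recoverable only through the
dimeric motif.

## What passing tests show — and what they do not

The generators emulate selection, amplification-free resampling, and clean
genomic planting.  They do not model PCR bias or duplicates, sequencing
error, adapter chimeras, chromatin context, heterodimers, or graded
genome-wide binding landscapes; conservation is piecewise constant rather
than phylogenetically simulated.  Passing recovery tests therefore
demonstrates that the *analysis* is correct and sensitive under its own
model assumptions — not that those assumptions capture every property of
bench data.  Quantities reported from real libraries (peak fractions,
AUPRC values) will differ from the synthetic ones, which are properties of
the documented simulation conditions.

## Known limitations

* Gapped seeds are not implemented; dimeric motifs longer than the 10-mer
  seed range are reconstructed by pattern-match alignment instead.
* The exact-null scanner assumes an i.i.d. (order-0) background.
* `motif_distance` uses column correlation, not information-weighted
  alignment; very low-IC columns can dilute distances between long motifs.
* The E-MI summary depends on the bias correction in sparse regimes; only
  comparisons at equal read counts are meaningful.
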