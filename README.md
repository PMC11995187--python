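# selexdimer

Tools for deriving monomeric and homodimeric DNA-binding specificities of
transcription factors from HT-SELEX sequencing libraries, and for evaluating
the resulting motifs against genomic peak sets, promoters and conservation
tracks.  The package targets the analysis situation of plant R2R3-MYB
factors, where a factor binding a short degenerate consensus (e.g. the
CCWAA-box, `RCCWAAY`) can homodimerise on composite sites whose two
half-sites sit in one of three relative orientations — direct (DR), inverted
(IR) or everted (ER) repeat — at varying spacing, and where close spacing can
*change* the specificity of one half-site relative to the monomer.

## What it does

* **SELEX motif discovery** — reads are tiled into 40-bp segments; enriched
  8–10-mers that are local maxima of their Hamming-1 neighbourhood are called
  as seeds against the input (cycle-0) library; position probability matrices
  are built by multinomial-1 counting (column *i* counts windows matching the
  seed everywhere except possibly at *i*); motif sets are filtered (total
  IC < 1 bit, single-nucleotide runs, near-duplicates).  Library-level signal
  is scored by E-MI, the mutual information between 3-mer identities at
  non-overlapping position pairs (Miller–Madow bias corrected).
* **Dimer configuration analysis** — fold enrichment of composite IUPAC
  patterns over an orientation × spacing grid (negative spacing = overlapping
  half-sites, merged by IUPAC intersection); inference of (orientation,
  spacing) from a dimeric matrix; per-half-site divergence from the monomer
  (column-wise Pearson distance) with a flag for specificity change; a
  cooperativity index `fold(dimer) / (fold(left)·fold(right))`; per-position
  DNA-shape profiles from a pentamer lookup table.
* **Genome evaluation** — motif scanning with exact p-values (the null score
  distribution is computed by discretised convolution, so `p = 1e-5` maps
  deterministically to a score cutoff); 200-bp fragment scoring
  (−log10 best-site p, max over a motif set); precision–recall / AUPRC of
  peak prediction with motif-set ablations and paired Wilcoxon comparison;
  peak site fractions with shuffled-sequence and mutated-motif controls;
  TSS-centred net motif density (reversed-motif subtracted, 200-bp smoothed);
  conservation profiles around promoter hits.
* **In-silico SELEX** — retain random ligands that a virtual factor scores
  above threshold; used to show that a library retained on a *degenerate*
  motif also "enriches" every stricter sub-pattern, i.e. pattern enrichment
  alone cannot prove an extra binding mode.
* **Synthetic data** — a SELEX simulator driven by a thermodynamic mixture
  of monomeric/dimeric PWM modes with activities and cooperativity, and a
  genome generator planting CREs, ranked peaks, TSSs and conservation with
  full ground truth.  Every analysis stage is tested against these
  generators.

## Worked example

Simulate a factor whose close-spacing everted-repeat dimer carries a changed
right half-site, then re-discover everything from the reads alone:

```python
from selexdimer import (make_er1a_like_model, simulate_selex, segment_reads,
                        discover_seeds, pwm_from_seed, trim_motif,
                        configuration_scan, iupac_to_ppm, motif_distance)

model = make_er1a_like_model(base_half="ACCTAAY", modified_half="CACGTGG")
lib, truth = simulate_selex(model, n_ligands=50_000, cycles=3, seed=1)

sig = segment_reads(lib.reads(3))
bg = segment_reads(lib.reads(0))
seeds = discover_seeds(sig, bg)
monomer = trim_motif(pwm_from_seed(seeds[0].seed, sig))
print(monomer.consensus)                                   # RTTAGGT
print(motif_distance(monomer, iupac_to_ppm("ACCTAAY")))    # 0.0002

scan = configuration_scan("ACCTAAY", lib.reads(3), lib.reads(0))
print(scan.argmax())                                       # ('ER', 8)
```

The recovered monomer is the planted `ACCTAAY` consensus (reported on the
opposite strand; the distance of 0.0002 is orientation-invariant), and the
homotypic configuration scan finds the planted distant everted repeat at
spacing 8.  Running the full recovery (`selexdimer demo --seed 0`) also
finds the second, dissimilar half-site `CACGTGG`, locates it at ER spacing 1
against the monomer half, and reports half-site divergences of ~0.0 (left)
and ~1.0 (right) for the close mode versus ~0.0/~0.0 for the ER8 control —
the planted specificity change, re-derived from sequence data alone.

A command-line layer mirrors the library (`selexdimer simulate | discover |
dimers | scan | pr | tss | conserve | insilico | demo`); each run writes a
JSON manifest with the resolved configuration, seed and input checksums.

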