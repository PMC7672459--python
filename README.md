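# quadprobe

Genome-wide analysis of G-quadruplex (G4) formation from probe-based
ChIP experiments: scanning genomes for putative G-quadruplex sequences
(PQS) — canonical and non-canonical — profiling ChIP signal around TSSs
and motifs, overlap and fold-change statistics for called peaks, and
quantitation of probe binding (EMSA isotherms, ΔΔCt qPCR).

G-quadruplexes are four-stranded structures formed by guanine-rich DNA;
they concentrate near transcription start sites and form in response to
transcription. A small G4-affinity probe expressed in living cells and
pulled down by ChIP-seq reports where G4s actually fold. Interpreting
such data needs, on the computational side: a motif scanner that knows
the non-canonical G4 classes, signal metaprofiles oriented by gene
strand, a shuffle null, peak–motif overlap statistics, and binding
quantitation. `quadprobe` packages these steps as a tested library,
with a deterministic synthetic-data generator so the whole pipeline can
be validated end-to-end with no external downloads.

## Motif classes

The canonical PQS consensus is G≥3(N1–7G≥3)≥3 — at least four G-tracts
of three or more guanines joined by loops of 1–7 nt. The scanner (`4G`
class) reproduces exactly the behaviour of the regular expression
`G{3,}(.{1,7}?G{3,}){3,}` under standard engine semantics (greedy
G-runs, lazy loops, leftmost non-overlapping matches). On top of it,
three non-canonical classes are found and filtered against the
canonical calls:

| class | structure |
|---|---|
| `4GL15` | four tracts, exactly one loop of 8–15 nt |
| `GVBQ` | G-vacancy-bearing: one terminal tract is a bare `GG` |
| `Bulge` | one tract of three Gs broken by a single non-G base |
| `Hybrid2`/`Hybrid3` | two/three tracts; can complete a G4 with RNA G-tracts |

All coordinates are 0-based half-open (BED convention); minus-strand
motifs are scanned on the reverse complement and reported in
plus-strand coordinates.

## Worked example

`examples/synthetic_study.py` runs the full pipeline on the default
synthetic study (two 500 kb chromosomes, 40 genes in four expression
tiers, 120 planted motifs of all six classes, probe and input coverage
tracks):

```
genome: 2 chromosomes x 500 kb, 40 genes, 120 planted motifs
scanner recovery: 120/120 motifs, 0 spurious calls

mean probe-minus-input signal at TSS +/- 2 kb, by expression tier:
  tier  1.0: 0.722
  tier  2.0: 1.413
  tier  4.0: 2.897
  tier  8.0: 6.040

downstream/upstream signal ratio at TSSs: 2.23
peaks overlapping >=1 PQS: 100.0% of 120
```

The scanner recovers every planted motif with exact coordinates and
subtype; probe enrichment scales with the host gene's expression tier
(transcription drives G4 formation) and is about twice as strong
downstream of the TSS, where the R-loop stabilizes the structure.
Other examples: `scan_motifs.py` (BED output for each motif class),
`fit_emsa.py` (two-population binding fit — recovers F1 = 0.598,
Kd1 = 1.87 nM, Kd2 = 146.5 nM from truth 0.60/2 nM/150 nM at noise
sd 0.05), and `qpcr_quantitation.py` (ΔΔCt and pull-down folds).

A thin CLI mirrors the main workflows:

```sh
quadprobe simulate --seed 1 --outdir fixtures/
quadprobe scan --fasta fixtures/genome.fa --out motifs.bed
quadprobe profile --track fixtures/g4p.bedgraph --control fixtures/input.bedgraph \
    --genes fixtures/genes.bed --chrom-sizes fixtures/chrom.sizes --out matrix.tsv
quadprobe fit-emsa --table titration.tsv
```

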