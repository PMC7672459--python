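# Methods

## Canonical motif matching

The `4G` scanner implements the consensus G≥3(N1–7G≥3)≥3 with the exact
operational semantics of a backtracking regex engine evaluating
`G{3,}(.{1,7}?G{3,}){3,}`: G-runs are matched greedily, loops lazily
(shortest first), matches are leftmost and non-overlapping, and
scanning resumes at the base after each match. Consequences worth
knowing: the minimal match is 15 nt; a run of 15 Gs is itself a match
(loops may contain G); a run of 12 Gs is not. The matcher is written
natively (run-table plus memoized backtracking) rather than delegating
to `re`, so the test suite can use the stock regex engine as an
independent oracle; the two agree exactly on tens of thousands of
random sequences.

One deliberate deviation from the bare `.` of the printed pattern: `N`
is an unknown base and may not occur anywhere inside a motif (tract,
loop, or bulge). Reporting a motif across an assembly gap would be
indefensible; an `N` therefore truncates candidates.

## Non-canonical classes

The non-canonical search follows the published two-phase scheme — a
candidate round per class, then filtering rounds — with the filter
operationalized as: discard any candidate whose span overlaps a
canonical 4G span on the same strand by ≥ 1 nt (configurable via
`overlap_filter_nt`). Because the original flow-chart figure for this
procedure is not available, the class predicates are this package's own
reconstruction, chosen to make the classes well-defined and mutually
interpretable:

* tracts are **maximal** G-runs (a tract cannot be extended by an
  adjacent G, inside or outside the motif);
* loops may contain isolated G or GG but never a full G≥3 run — such a
  run would itself be a tract, making the decomposition ambiguous;
* `4GL15`: exactly four tracts, exactly one loop of 8–15 nt, the
  remaining loops 1–7 nt;
* `GVBQ`: four tracts of which exactly one is a bare `GG`, restricted
  to the first or last position (a vacancy in a terminal quartet is the
  defining case); interior vacancies are available behind the
  `interior_vacancy` flag, default off;
* `Bulge`: four tracts with loops 1–7 nt; exactly one tract is three
  Gs interrupted by one non-G base (`G·B·GG` or `GG·B·G`, B ∈ {A,C,T}),
  the other three intact;
* hybrid motifs: maximal chains of G≥3 tracts with 1–7 nt gaps holding
  exactly two (`Hybrid2`) or three (`Hybrid3`) tracts; a three-tract
  chain is one `Hybrid3`, never two `Hybrid2`; chains overlapping any
  four-tract motif span are discarded.

Within a subtype, overlapping candidates resolve left-to-right (earlier
start wins; at equal starts the shorter candidate, mirroring the lazy
loops of the canonical matcher). Overlaps *across* subtypes are
preserved and can be merged with `merge_subtype_calls`, which unions
spans and subtype sets transitively — the basis for Venn-style subtype
combination counts.

These predicates admit genuine biological ambiguity in one corner: a
bulged tract at a motif's edge (`…G·B·GG`) leaves a `GG` fragment that
is simultaneously a legal terminal vacancy, so such loci can carry both
a `Bulge` and a `GVBQ` call. The scanner reports both (they merge into
one multi-subtype motif); the synthetic generator avoids planting such
instances so its truth tables stay single-subtype.

## Region partition and assignment

The genome is partitioned into promoter (TSS ± flank), TES flank
(TES ± flank), intragenic, and intergenic, with flank default 2000 bp.
Windows anchor on the gene's half-open boundary coordinates, so the
TES ± 2 kb window of a `+` gene `[4000,7000)` is `[5000,9000)`. Where
windows of different genes overlap, precedence is promoter > TES flank
> intragenic > intergenic (configurable); promoters are the biologically
privileged sites here, and four mutually exclusive percentages require
*some* precedence. Every base carries exactly one label; the partition
is independent of gene input order. Items are assigned to regions
either by their integer midpoint (exactly one label per item; fractions
sum to 1) or by any-overlap (reads-style accounting, one count per
touched label). Peak–motif and motif–window overlap is by ≥ 1 nt
against half-open intervals, strand-blind (a peak is double-stranded
DNA).

## Signal profiling

Coverage is held at base resolution per chromosome. Matrix computation
is deeptools-like: per-anchor windows averaged into fixed-width bins
(default 50 bp; window half-widths 3000–4000 bp depending on the
figure emulated), minus-strand rows column-reversed so downstream is
always rightward, and out-of-chromosome bases contributing 0 (masking
would distort profile tails; the choice is documented rather than
silent). Gene-body rescaling uses exact step-function integration of
the per-base cumulative sum, so genes shorter than the bin count still
contribute every base and preserve their mean. RPKM converts summed
base coverage to read-equivalents via the read length, then normalizes
by bin kilobases and million mapped reads. Track comparison supports
`subtract` (a − b) and `ratio` ((a+p)/(b+p), pseudocount default 1.0 —
no value is prescribed anywhere, so it is explicit and configurable).
Heatmap scaling maps the global matrix min/max linearly onto [0, 255]
(per heatmap, not per row); a constant matrix maps to 0. Row sorting
(by mean or max, stable, descending) returns the permutation so one
ordering can be applied across heatmaps of different tracks.

The shuffle null relocates each interval uniformly at random on its own
chromosome, avoiding an exclusion set and previously placed intervals,
deterministically per seed. Staying on the same chromosome preserves
chromosome-scale composition and keeps the feasibility search simple.
When the null is used to test enrichment collapse, the exclusion set is
the motif spans padded by 4 enrichment-bump standard deviations
(600 bp at defaults): a "PQS-free" location that still sits on the
shoulder of a neighbouring motif's enrichment would not be a null.

## Binding quantitation

EMSA titrations are fitted to the two-population 1:1 isotherm
Y = F1·X/(Kd1+X) + (1−F1)·X/(Kd2+X) by bounded nonlinear least squares
in (F1, log10 Kd1, log10 Kd2) space, from a start grid of
F1 ∈ {0.25, 0.5, 0.75} crossed with Kd pairs log-spaced over the
observed concentration range; the best-RSS solution is kept and
canonically ordered Kd1 ≤ Kd2. The fit collapses to a one-site model —
reported as a single Kd with `degenerate=True` — when
|log10 Kd1 − log10 Kd2| < 0.05 or Kd2 > 1 M.

Noiseless titrations recover parameters to machine precision. With
Gaussian noise of sd 0.05 on Y, a *single* 12–48-point titration does
not identify the constants to 10%: the fitted optimum always has RSS at
or below the truth's, yet median Kd errors are 30–55% — a sampling
variance floor, not an optimizer failure. The package's simulation
study therefore follows standard replicate practice: 20 noisy replicate
titrations are averaged point-wise and the mean curve fitted (24-point
log grid spanning Kd1/100 to Kd2·100), which brings the median
per-parameter error to ~5–7%.

ΔΔCt enrichment is E^−[(Ct_chip,t − Ct_chip,ref) − (Ct_in,t − Ct_in,ref)]
with efficiency E default 2.0 (classic assumption; configurable because
no standard-curve correction is modelled). Pull-down enrichment is the
target/internal-control ratio referenced to input and normalized to the
mutant-motif control.

## Synthetic data: what it emulates and what it does not

The generator builds the study the analysis assumes. Background
sequence is i.i.d. with every G/C run capped at two bases, so planted
motifs are provably the only PQS sources on either strand — planted
truth is exact, at the cost of a less realistic base composition (real
genomes have G-runs everywhere; the generator trades that realism for
closed-loop testability). Planted loops additionally cap C-runs at two
(a CCC loop would be a G-tract on the opposite strand), and bulged
tracts are planted in interior slots only (see above). Motifs keep
≥ 400 bp mutual separation plus 25 bp AT-only margins so no candidate
can straddle a planting boundary and neighbouring enrichment bumps stay
resolvable.

Genes (default 40 across 2 × 500 kb; 8 kb long) sit in equal segments
with alternating strands and an expression tier cycling through
(1, 2, 4, 8). 70% of motifs are promoter-proximal (200–1800 bp from a
TSS); tier and TSS side are assigned by cycling so every subtype
samples the same tier/side mix — the subtype amplitude ordering is then
a construction property, not a sampling accident. The rest are planted
intergenically, away from all gene ± 3.5 kb zones.

Tracks: input = background (1.0) + Gaussian noise (sd 0.2, floored at
0); the probe track carries its own independent noise realization plus
one Gaussian bump (sd 150 bp) per motif with amplitude
subtype × tier × asymmetry, where asymmetry (default 2.0) applies to
motifs downstream of their host TSS and subtype amplitudes default to
4G:4 > Bulge:3 > 4GL15:2 > GVBQ:1 > Hybrid3:0.75 > Hybrid2:0.5,
mirroring the in-cell formation hierarchy. (Giving the probe track the
input's literal noise would make probe-minus-input noise-free and the
noise parameter meaningless.) Peaks are emitted at motif centres
± 250 bp with fold enrichment = local probe/input mean ratio — peak
*calling* is out of scope, so peaks come from truth. Every output is a
pure function of the seed; a post-check rescans the genome and
regenerates on any collision.

What passing tests on this fixture do **not** show: robustness to
G-rich backgrounds with near-miss motifs, read-level artefacts
(mappability, duplicates, fragment-size effects), realistic peak-caller
behaviour, or chromatin-accessibility confounds in the input. Those
need real data.

## Problem sizes and numerical choices

Default analysis sizes — 1 Mb genome, 120 motifs, 40 genes, 1000×300 nt
oracle sequences, 10,000×200 nt regex-fidelity sequences, 50 binding
draws × 20 replicates — are chosen so the full suite and the
acceptance script each run in well under a minute per stage on one
core. Ties in integer midpoints go toward start; stable sorts
everywhere an order is user-visible, so reports are byte-identical
across reruns; all derived seeds stay below 2^31.
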