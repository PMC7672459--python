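"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a small genome whose only PQS motifs are planted at known coordinates,
genes with expression tiers, an input coverage track, and a probe
("G4P") track whose enrichment at planted motifs scales with the host
gene's expression tier and is stronger downstream of the TSS than
upstream. Background sequence is drawn with G/C runs capped at two
bases, so planted motifs are provably the only PQS sources and
scanner-recovery tests are exact.

Every output is deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding_quant import BindingFit, BindingSeries, CtQuad, predict_bound
from .io_formats import GeneModel, GenomicInterval, Peak, SequenceRecord
from .pqs_scan import ALL_SUBTYPES, reverse_complement, scan_genome
from .signal_profile import CoverageTrack

DEFAULT_MOTIF_COUNTS = {
    "4G": 40,
    "4GL15": 20,
    "GVBQ": 20,
    "Bulge": 20,
    "Hybrid2": 10,
    "Hybrid3": 10,
}

# relative enrichment amplitudes; ordering mirrors the in-cell hierarchy
# canonical > bulged > long-loop > vacancy, with hybrids weakest
DEFAULT_AMPLITUDES = {
    "4G": 4.0,
    "Bulge": 3.0,
    "4GL15": 2.0,
    "GVBQ": 1.0,
    "Hybrid3": 0.75,
    "Hybrid2": 0.5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``expression_tiers`` are relative transcription activities cycled
    over genes; ``asymmetry`` multiplies the enrichment of motifs lying
    downstream of their host TSS; ``enrichment_sd`` is the Gaussian
    half-width (bp) of each motif's enrichment bump.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 40
    gene_length: int = 8000
    expression_tiers: tuple = (1.0, 2.0, 4.0, 8.0)
    motif_counts: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_COUNTS))
    promoter_fraction: float = 0.7
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    asymmetry: float = 2.0
    background: float = 1.0
    noise_sd: float = 0.2
    enrichment_sd: float = 150.0
    margin: int = 25  # AT-only buffer flanking each planted motif
    min_separation: int = 400  # keeps neighbouring enrichment bumps resolvable
    peak_half_width: int = 250

    def __post_init__(self) -> None:
        if self.asymmetry < 1:
            raise ValueError("asymmetry factor must be >= 1")
        if any(c < 0 for c in self.motif_counts.values()):
            raise ValueError("motif counts must be non-negative")
        for st in self.motif_counts:
            if st not in ALL_SUBTYPES:
                raise ValueError(f"unknown subtype {st!r} in motif plan")

    def total_motifs(self) -> int:
        return sum(self.motif_counts.values())


@dataclass(frozen=True)
class PlantedMotif:
    """One ground-truth motif: where it is, what it is, how much signal."""

    chrom: str
    start: int
    end: int
    strand: str
    subtype: str
    sequence: str  # strand-oriented
    host_gene: str = ""
    tier: float = 1.0
    downstream: Optional[bool] = None
    amplitude: float = 0.0


def truth_to_dataframe(truth: Sequence[PlantedMotif]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truth])


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------


def _chrom_names(config: SimulationConfig) -> list:
    return [f"chr{i + 1}" for i in range(config.n_chroms)]


def make_genes(config: SimulationConfig, genome=None) -> tuple:
    """Lay out non-overlapping genes with alternating strands and tiers.

    Genes are centred in equal chromosome segments; strand alternates
    and the expression tier cycles with gene index, so tiers are balanced
    across the genome. Returns (genes, tiers) with tiers a name->activity
    dict. The layout is a pure function of the config.
    """
    if config.n_genes == 0:
        return [], {}
    names = _chrom_names(config)
    per = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per[i] += 1
    genes = []
    tiers = {}
    idx = 0
    for chrom, n in zip(names, per):
        if n == 0:
            continue
        segment = config.chrom_length // n
        if segment < config.gene_length + 8000:
            raise ValueError("gene plan infeasible: segments too small for gene + flanks")
        for k in range(n):
            start = k * segment + (segment - config.gene_length) // 2
            strand = "+" if idx % 2 == 0 else "-"
            name = f"gene{idx:03d}"
            genes.append(GeneModel(GenomicInterval(chrom, start, start + config.gene_length, strand), name))
            tiers[name] = config.expression_tiers[idx % len(config.expression_tiers)]
            idx += 1
    return genes, tiers


# ---------------------------------------------------------------------------
# motif sequence construction
# ---------------------------------------------------------------------------

_NON_G = "ACT"


def _rand_loop(rng, lo: int, hi: int) -> str:
    """G-free loop with C-runs capped at 2 (a CCC would be a G-tract on the
    opposite strand and could seed an unplanned motif there)."""
    length = int(rng.integers(lo, hi + 1))
    out = []
    for i in rng.integers(0, 3, size=length):
        ch = _NON_G[i]
        if ch == "C" and out[-2:] == ["C", "C"]:
            ch = "AT"[int(rng.integers(0, 2))]
        out.append(ch)
    return "".join(out)


def _rand_tract(rng) -> str:
    return "G" * int(rng.integers(3, 6))


def _motif_sequence(rng, subtype: str) -> str:
    """A random instance of the subtype; loops are G-free by construction."""
    if subtype == "4G":
        parts = [_rand_tract(rng)]
        for _ in range(3):
            parts += [_rand_loop(rng, 1, 7), _rand_tract(rng)]
        return "".join(parts)
    if subtype == "4GL15":
        long_at = int(rng.integers(0, 3))
        parts = [_rand_tract(rng)]
        for j in range(3):
            lo, hi = (8, 15) if j == long_at else (1, 7)
            parts += [_rand_loop(rng, lo, hi), _rand_tract(rng)]
        return "".join(parts)
    if subtype == "GVBQ":
        tracts = [_rand_tract(rng) for _ in range(3)]
        units = ["GG"] + tracts if rng.integers(0, 2) == 0 else tracts + ["GG"]
        parts = [units[0]]
        for u in units[1:]:
            parts += [_rand_loop(rng, 1, 7), u]
        return "".join(parts)
    if subtype == "Bulge":
        b = _NON_G[int(rng.integers(0, 3))]
        bulged = "G" + b + "GG" if rng.integers(0, 2) == 0 else "GG" + b + "G"
        units = [_rand_tract(rng) for _ in range(4)]
        # interior slot only: a terminal bulged tract leaves a GG fragment at
        # the motif edge that doubles as a GVBQ vacancy, making truth ambiguous
        units[int(rng.integers(1, 3))] = bulged
        parts = [units[0]]
        for u in units[1:]:
            parts += [_rand_loop(rng, 1, 7), u]
        return "".join(parts)
    if subtype in ("Hybrid2", "Hybrid3"):
        n = 2 if subtype == "Hybrid2" else 3
        parts = [_rand_tract(rng)]
        for _ in range(n - 1):
            parts += [_rand_loop(rng, 1, 7), _rand_tract(rng)]
        return "".join(parts)
    raise ValueError(f"unknown subtype {subtype!r}")


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


def _background(rng, length: int) -> np.ndarray:
    """Random sequence with every G/C run capped at 2 bases."""
    codes = rng.integers(0, 4, size=length)  # 0=A 1=C 2=G 3=T
    at = rng.integers(0, 2, size=length) * 3  # replacement draws: A or T
    for i in range(2, length):
        c = codes[i]
        if (c == 1 or c == 2) and codes[i - 1] == c and codes[i - 2] == c:
            codes[i] = at[i]
    return codes


_CODE2CHAR = np.array(list("ACGT"))


def make_genome(config: SimulationConfig) -> tuple:
    """Build the synthetic genome and its motif truth table.

    Motifs are planted per the config's plan, on both strands, with
    AT-only margins so no spurious PQS can straddle a planting boundary;
    a post-check rescans the genome against the truth table and
    regenerates on collision. Returns (records, truth).
    """
    last_err = None
    for attempt in range(3):
        try:
            records, truth = _build_genome_once(config, attempt)
        except RuntimeError as err:
            last_err = err
            continue
        return records, truth
    raise RuntimeError(f"could not build a collision-free genome: {last_err}")


def _build_genome_once(config: SimulationConfig, attempt: int) -> tuple:
    rng = np.random.default_rng([config.seed, 17 + attempt])
    genes, tiers = make_genes(config)
    genes_by_tier: dict = {}
    for g in genes:
        genes_by_tier.setdefault(tiers[g.name], []).append(g)
    tier_cycle_pos = {t: 0 for t in genes_by_tier}

    chrom_seqs = {c: _background(rng, config.chrom_length) for c in _chrom_names(config)}
    occupied: dict = {c: [] for c in chrom_seqs}
    gene_forbidden: dict = {c: [] for c in chrom_seqs}
    for g in genes:
        # keep intergenic plantings outside the promoter/TES windows (+/-2 kb)
        # plus the enrichment bump reach, so their signal stays intergenic
        gene_forbidden[g.interval.chrom].append((g.interval.start - 3500, g.interval.end + 3500))

    pad = config.margin + config.min_separation

    def free(chrom: str, start: int, end: int) -> bool:
        if start - pad < 0 or end + pad > config.chrom_length:
            return False
        return all(e <= start - pad or s >= end + pad for s, e in occupied[chrom])

    def in_gene_zone(chrom: str, start: int, end: int) -> bool:
        return any(start < e and end > s for s, e in gene_forbidden[chrom])

    truth: list = []
    chroms = _chrom_names(config)
    tier_list = list(config.expression_tiers)

    for s_idx, subtype in enumerate(ALL_SUBTYPES):
        count = config.motif_counts.get(subtype, 0)
        n_prom = round(count * config.promoter_fraction) if genes else 0
        for j in range(count):
            seq = _motif_sequence(rng, subtype)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            placed = False
            if j < n_prom:
                # tier cycles fastest, side cycles per tier block, and each
                # subtype starts at its own phase: tiers and sides stay
                # balanced within every subtype while the combined load
                # spreads over all (tier, side) slots instead of piling onto
                # one gene side
                phase = j + s_idx
                tier = tier_list[phase % len(tier_list)]
                downstream = (phase // len(tier_list)) % 2 == 0
                d_draws = [int(rng.integers(200, 1801)) for _ in range(200)]
                d_draws += list(range(200, 1801, 100))  # deterministic fallback grid
                for d in d_draws:
                    pool = genes_by_tier[tier]
                    g = pool[tier_cycle_pos[tier] % len(pool)]
                    tier_cycle_pos[tier] += 1
                    sign = 1 if (downstream == (g.strand == "+")) else -1
                    pos = g.tss + sign * d
                    start, end = pos, pos + len(seq)
                    if free(g.interval.chrom, start, end):
                        _plant(chrom_seqs[g.interval.chrom], rng, seq, strand, start, config.margin)
                        occupied[g.interval.chrom].append((start, end))
                        truth.append(
                            PlantedMotif(
                                g.interval.chrom, start, end, strand, subtype,
                                seq, g.name, tier, downstream,
                                config.amplitudes[subtype] * tier
                                * (config.asymmetry if downstream else 1.0),
                            )
                        )
                        placed = True
                        break
            else:
                for _ in range(500):
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    start = int(rng.integers(pad, config.chrom_length - len(seq) - pad))
                    end = start + len(seq)
                    if not in_gene_zone(chrom, start, end) and free(chrom, start, end):
                        _plant(chrom_seqs[chrom], rng, seq, strand, start, config.margin)
                        occupied[chrom].append((start, end))
                        truth.append(
                            PlantedMotif(
                                chrom, start, end, strand, subtype, seq,
                                "", 1.0, None, config.amplitudes[subtype],
                            )
                        )
                        placed = True
                        break
            if not placed:
                raise ValueError(
                    f"motif plan infeasible: no room for {subtype} motif {j}"
                )

    records = [
        SequenceRecord(c, "".join(_CODE2CHAR[chrom_seqs[c]])) for c in chroms
    ]
    _verify_truth(records, truth)
    return records, sorted(
        truth, key=lambda t: (t.chrom, t.start, t.end, t.strand)
    )


_CHAR2CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _plant(codes: np.ndarray, rng, seq: str, strand: str, start: int, margin: int) -> None:
    text = seq if strand == "+" else reverse_complement(seq)
    codes[start : start + len(text)] = [_CHAR2CODE[ch] for ch in text]
    left = rng.integers(0, 2, size=margin) * 3  # A/T only
    right = rng.integers(0, 2, size=margin) * 3
    codes[start - margin : start] = left
    codes[start + len(text) : start + len(text) + margin] = right


def _verify_truth(records, truth) -> None:
    """Closed-loop check: the scanner must recover exactly the truth table."""
    found = scan_genome(records, ALL_SUBTYPES)
    got = {(m.interval.chrom, m.interval.start, m.interval.end, m.strand, next(iter(m.subtypes)))
           for m in found}
    want = {(t.chrom, t.start, t.end, t.strand, t.subtype) for t in truth}
    if got != want:
        missing = want - got
        spurious = got - want
        raise RuntimeError(
            f"planting collision: {len(missing)} truth motifs not recovered, "
            f"{len(spurious)} spurious calls (e.g. {list(spurious)[:3]})"
        )


# ---------------------------------------------------------------------------
# coverage tracks and peaks
# ---------------------------------------------------------------------------


def simulate_tracks(
    config: SimulationConfig,
    genome: Sequence[SequenceRecord],
    genes: Sequence[GeneModel],
    truth: Sequence[PlantedMotif],
) -> tuple:
    """Simulate (g4p_track, input_track, peaks) from the truth table.

    Both tracks are background plus independent Gaussian noise (floored
    at 0); the probe track additionally carries one Gaussian-shaped
    enrichment bump per planted motif with the truth amplitude. Peaks are
    emitted at planted motifs (centre +/- ``peak_half_width``) with fold
    enrichment defined as the local probe/input mean ratio.
    """
    rng = np.random.default_rng([config.seed, 29])
    sizes = {r.name: len(r.sequence) for r in genome}
    input_vals = {}
    g4p_vals = {}
    for chrom, n in sizes.items():
        input_vals[chrom] = np.maximum(
            config.background + rng.normal(0.0, config.noise_sd, size=n), 0.0
        )
        g4p_vals[chrom] = np.maximum(
            config.background + rng.normal(0.0, config.noise_sd, size=n), 0.0
        )
    sd = config.enrichment_sd
    reach = int(4 * sd)
    for t in truth:
        center = (t.start + t.end) // 2
        n = sizes[t.chrom]
        lo, hi = max(0, center - reach), min(n, center + reach + 1)
        x = np.arange(lo, hi)
        g4p_vals[t.chrom][lo:hi] += t.amplitude * np.exp(-((x - center) ** 2) / (2 * sd * sd))

    g4p = CoverageTrack(g4p_vals, mode="raw")
    inp = CoverageTrack(input_vals, mode="raw")

    peaks = []
    hw = config.peak_half_width
    for i, t in enumerate(sorted(truth, key=lambda t: (t.chrom, t.start))):
        center = (t.start + t.end) // 2
        n = sizes[t.chrom]
        lo, hi = max(0, center - hw), min(n, center + hw)
        local_g4p = g4p_vals[t.chrom][lo:hi]
        fold = float(local_g4p.mean() / input_vals[t.chrom][lo:hi].mean())
        peaks.append(
            Peak(
                GenomicInterval(t.chrom, lo, hi, "."),
                fold_enrichment=fold,
                qvalue=4.0,
                summit_offset=int(np.argmax(local_g4p)),
                name=f"peak{i:04d}_{t.subtype}",
            )
        )
    return g4p, inp, peaks


# ---------------------------------------------------------------------------
# whole-fixture convenience
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    """Everything one run of the generator produces."""

    config: SimulationConfig
    genome: list
    genes: list
    tiers: dict
    truth: list
    g4p: CoverageTrack
    input: CoverageTrack
    peaks: list


def simulate_fixture(config: Optional[SimulationConfig] = None) -> Fixture:
    config = config or SimulationConfig()
    genome, truth = make_genome(config)
    genes, tiers = make_genes(config)
    g4p, inp, peaks = simulate_tracks(config, genome, genes, truth)
    return Fixture(config, genome, genes, tiers, truth, g4p, inp, peaks)


def write_fixture(fixture: Fixture, outdir) -> None:
    """Write FASTA, gene BED, two bedGraphs, narrowPeak and a truth TSV."""
    from pathlib import Path

    from .io_formats import write_bed, write_bedgraph, write_fasta, write_narrowpeak

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        write_fasta(fixture.genome, fh)
    with open(outdir / "genes.bed", "w") as fh:
        write_bed(fixture.genes, fh)
    with open(outdir / "g4p.bedgraph", "w") as fh:
        write_bedgraph(fixture.g4p, fh)
    with open(outdir / "input.bedgraph", "w") as fh:
        write_bedgraph(fixture.input, fh)
    with open(outdir / "peaks.narrowPeak", "w") as fh:
        write_narrowpeak(fixture.peaks, fh)
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, n in fixture.g4p.chrom_sizes().items():
            fh.write(f"{chrom}\t{n}\n")
    truth_to_dataframe(fixture.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# biochemical simulators
# ---------------------------------------------------------------------------


def simulate_emsa(
    F1: float,
    Kd1: float,
    Kd2: float,
    x_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingSeries:
    """Titration drawn from the two-population isotherm plus Gaussian noise."""
    fit = BindingFit(Kd1=Kd1, Kd2=Kd2, F1=F1, rss=0.0, degenerate=False)
    x = np.asarray(x_grid, dtype=float)
    y = predict_bound(fit, x)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(x))
    return BindingSeries.from_arrays(x, np.clip(y, 0.0, 1.0))


def simulate_ct(
    true_fold: float,
    ref_ct: float = 25.0,
    efficiency: float = 2.0,
    seed: int = 0,
    sd: float = 0.0,
) -> CtQuad:
    """Ct quadruple constructed so ddCt recovers ``true_fold`` exactly at sd=0."""
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    ct_target = ref_ct - math.log(true_fold, efficiency)
    vals = np.array([ct_target, ref_ct, ref_ct, ref_ct])
    if sd > 0:
        vals = vals + np.random.default_rng(seed).normal(0.0, sd, size=4)
    return CtQuad(*[float(v) for v in vals])
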