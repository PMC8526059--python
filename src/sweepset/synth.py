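"""Synthetic genomes and haplotypes with the structure the analysis assumes.

Real inputs for this kind of analysis are phased population haplotypes
(for the sweep statistics), gene annotation, a per-gene confounder table and
a curated focal (disease) gene list.  The generators here emulate all of
them so the full pipeline is testable end to end:

``synth_genome``
    A fake multi-chromosome genome of genes with (i) confounders whose
    focal/non-focal mean shifts qualitatively match real disease genes
    (higher expression, higher conserved-element density, lower pN, equal
    pS, slightly lower recombination and background-selection B), (ii)
    per-gene window-mean sweep scores built from a spatially clustered
    sweep model (one sweep elevates all genes whose windows cover it), and
    (iii) an injectable true sweep deficit at focal genes: with
    ``focal_deficit`` = d < 1, a candidate sweep landing within a focal
    gene's largest window is kept with probability d and redrawn otherwise,
    so focal windows receive proportionally fewer sweeps.  With d = 1 sweep
    placement is independent of the labels (a true null).

``synth_haplotypes``
    Phased ancestral-polarized haplotypes from an msprime coalescent
    backend, neutral or with a partial sweep at a chosen position
    (structured coalescent sweep model), as a test bed for the haplotype
    statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeMatrix
from .ranking import WINDOW_SIZES

__all__ = [
    "ConfounderModel",
    "SynthGenomeSpec",
    "SynthGenome",
    "synth_genome",
    "SynthHaplotypeSpec",
    "synth_haplotypes",
]


@dataclass(frozen=True)
class ConfounderModel:
    """One gene-level covariate: baseline and focal-gene mean shift (in sds)."""

    name: str
    mean: float
    sd: float
    focal_shift_sd: float = 0.0
    binary: bool = False
    lower: float | None = None


# Qualitative shifts mirror what is seen at real mendelian disease genes:
# modestly higher expression and conservation, lower pN at equal pS,
# slightly lower recombination and B.  Shifts are kept <= 0.3 sd.
DEFAULT_CONFOUNDERS: tuple[ConfounderModel, ...] = (
    ConfounderModel("mean_expression", 5.0, 2.0, +0.30, lower=0.0),
    ConfounderModel("lymphocyte_expr", 3.0, 2.0, +0.20, lower=0.0),
    ConfounderModel("testis_expr", 4.0, 2.0, +0.10, lower=0.0),
    ConfounderModel("recomb_50kb", 1.2, 0.8, -0.10, lower=0.01),
    ConfounderModel("recomb_500kb", 1.2, 0.6, -0.10, lower=0.01),
    ConfounderModel("GC_50kb", 41.0, 3.0, 0.0),
    ConfounderModel("coding_density_50kb", 0.05, 0.02, +0.10, lower=0.0),
    ConfounderModel("conserved_density_50kb", 0.10, 0.04, +0.20, lower=0.0),
    ConfounderModel("conserved_density_500kb", 0.08, 0.03, +0.20, lower=0.0),
    ConfounderModel("regulatory_density_50kb", 0.15, 0.05, +0.10, lower=0.0),
    ConfounderModel("log2_PPI", 4.0, 2.0, +0.20, lower=0.0),
    ConfounderModel("pN", 0.008, 0.003, -0.30, lower=0.0),
    ConfounderModel("pS", 0.010, 0.003, 0.0, lower=0.0),
    ConfounderModel("mcvicker_B", 0.75, 0.15, -0.10, lower=0.05),
    ConfounderModel("is_immune", 0.10, 0.0, +0.02, binary=True),
)


@dataclass(frozen=True)
class SynthGenomeSpec:
    """Conditions of a synthetic genome.

    The generator emulates the *analyzed* gene universe of a sweep
    enrichment study — the genes with complete sweep and confounder data —
    rather than the raw annotation: spacing defaults to ~450 kb (the mean
    spacing of analyzed human genes), the focal fraction to 0.3 (the
    analyzed focal/control balance), and the sweep model to a dense
    continuum of weak-to-strong localized score elevations (roughly one
    per gene on average), mirroring the fact that rank thresholds down to
    the top quarter of all genes still carry sweep signal in real data.
    """

    n_genes: int = 2000
    n_chromosomes: int = 5
    mean_spacing_bp: int = 450_000
    focal_fraction: float = 0.3
    n_sweeps: int | None = None  # default: 1.2 per gene
    sweep_amplitude: float = 1.0
    focal_deficit: float = 1.0
    confounders: tuple[ConfounderModel, ...] = DEFAULT_CONFOUNDERS
    window_sizes: tuple[int, ...] = WINDOW_SIZES
    stats: tuple[str, ...] = ("iHS", "nSL")
    populations: tuple[str, ...] = ("pop",)
    baseline_mean: float = 0.8  # E|N(0,1)|, the neutral window mean of |z|
    gene_sd: float = 0.05
    stratum_sd: float = 0.06
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.focal_deficit <= 1):
            raise ValueError("focal_deficit must lie in (0, 1]")
        if not (0 < self.focal_fraction < 1):
            raise ValueError("focal_fraction must lie in (0, 1)")

    @property
    def sweeps(self) -> int:
        return self.n_sweeps if self.n_sweeps is not None else max(6 * self.n_genes // 5, 1)

    @staticmethod
    def desk_scale(
        n_genes: int = 500, focal_deficit: float = 1.0, seed: int | None = None
    ) -> "SynthGenomeSpec":
        """Reduced-scale conditions used by the fast end-to-end experiments.

        Window sizes are restricted to 50-200 kb so that, at a few hundred
        genes, putative-sweep clusters stay small relative to the genome
        and the block-randomized null retains enough shuffleable blocks.
        """
        return SynthGenomeSpec(
            n_genes=n_genes,
            n_chromosomes=2,
            focal_deficit=focal_deficit,
            window_sizes=(50_000, 100_000, 200_000),
            seed=seed,
        )


@dataclass
class SynthGenome:
    genes: pd.DataFrame
    confounders: pd.DataFrame
    scores: pd.DataFrame  # long: gene_id, stat, window_size, population, mean_abs
    sweep_positions: pd.DataFrame  # chrom, pos, amplitude


def _place_genes(spec: SynthGenomeSpec, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.array_split(np.arange(spec.n_genes), spec.n_chromosomes)
    rows = []
    for ci, idx in enumerate(per_chrom):
        gaps = rng.exponential(spec.mean_spacing_bp, size=len(idx)) + 5_000
        centers = np.cumsum(gaps) + 50_000
        lengths = np.minimum(rng.lognormal(np.log(25_000), 0.7, size=len(idx)), 2_000_000)
        for g, c, ln in zip(idx, centers, lengths):
            start = max(int(c - ln / 2), 0)
            end = int(c + ln / 2)
            rows.append((f"g{g:05d}", f"chr{ci + 1}", start, end, (start + end) / 2.0))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "span_start", "span_end", "center"])
    focal = rng.random(spec.n_genes) < spec.focal_fraction
    genes["is_focal"] = focal
    # disease-variant counts: geometric, so roughly half of focal genes carry
    # five or more variants (matching the split used for gene subsets)
    nv = np.where(focal, rng.geometric(0.16, size=spec.n_genes), 0)
    genes["n_disease_variants"] = nv
    return genes


def _confounder_table(
    spec: SynthGenomeSpec, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    out = {"gene_id": genes["gene_id"].to_numpy()}
    focal = genes["is_focal"].to_numpy()
    n = len(genes)
    for cm in spec.confounders:
        if cm.binary:
            p = cm.mean + cm.focal_shift_sd * focal
            vals = (rng.random(n) < p).astype(float)
        else:
            vals = rng.normal(cm.mean + cm.focal_shift_sd * cm.sd * focal, cm.sd, size=n)
            if cm.lower is not None:
                vals = np.maximum(vals, cm.lower)
        out[cm.name] = vals
    return pd.DataFrame(out)


def _place_sweeps(
    spec: SynthGenomeSpec, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    chrom_len = genes.groupby("chrom")["center"].max() + 500_000
    total_len = float(chrom_len.sum())
    if spec.sweeps > total_len / 50_000:
        raise ValueError(
            f"infeasible spec: {spec.sweeps} sweeps exceed what a {total_len / 1e6:.1f} Mb genome can hold"
        )
    chroms = chrom_len.index.to_numpy()
    probs = chrom_len.to_numpy() / total_len
    largest = max(spec.window_sizes)
    focal_centers = {
        c: np.sort(sub.loc[sub["is_focal"], "center"].to_numpy())
        for c, sub in genes.groupby("chrom")
    }
    rows = []
    for _ in range(spec.sweeps):
        for _try in range(10_000):
            c = chroms[rng.choice(len(chroms), p=probs)]
            pos = rng.uniform(0, chrom_len[c])
            fc = focal_centers[c]
            near_focal = False
            if fc.size:
                j = np.searchsorted(fc, pos)
                d = min(
                    pos - fc[j - 1] if j > 0 else np.inf,
                    fc[j] - pos if j < fc.size else np.inf,
                )
                near_focal = d < largest / 2
            if near_focal and rng.random() >= spec.focal_deficit:
                continue  # rejected: redraw elsewhere
            # heavy-tailed amplitude spectrum: many weak signals, few strong
            amp = spec.sweep_amplitude * (0.25 + rng.exponential(0.6))
            rows.append((c, pos, amp))
            break
        else:
            raise ValueError("could not place sweeps; focal windows cover the whole genome")
    return pd.DataFrame(rows, columns=["chrom", "pos", "amplitude"])


def _score_table(
    spec: SynthGenomeSpec,
    genes: pd.DataFrame,
    sweeps: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(genes)
    gene_base = rng.normal(0.0, spec.gene_sd, size=n)
    strata = [
        (stat, w, p)
        for stat in spec.stats
        for w in spec.window_sizes
        for p in spec.populations
    ]
    # per-sweep, per-stat multiplicative wobble so iHS and nSL curves differ
    stat_mult = {
        stat: rng.uniform(0.85, 1.15, size=len(sweeps)) for stat in spec.stats
    }
    parts = []
    centers = genes["center"].to_numpy()
    chroms = genes["chrom"].to_numpy()
    for stat, w, popn in strata:
        elev = np.zeros(n)
        for k, (c, pos, amp) in enumerate(zip(sweeps["chrom"], sweeps["pos"], sweeps["amplitude"])):
            hit = (chroms == c) & (np.abs(centers - pos) < w / 2)
            elev[hit] += amp * stat_mult[stat][k]
        mean_abs = (
            spec.baseline_mean
            + gene_base
            + rng.normal(0.0, spec.stratum_sd, size=n)
            + elev
        )
        parts.append(
            pd.DataFrame(
                {
                    "gene_id": genes["gene_id"],
                    "stat": stat,
                    "window_size": w,
                    "population": popn,
                    "mean_abs": np.maximum(mean_abs, 0.01),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def synth_genome(spec: SynthGenomeSpec) -> SynthGenome:
    """Generate (GeneTable, ConfounderTable, per-gene window scores).

    Reproducible under ``spec.seed``.  With ``focal_deficit`` = 1 the sweep
    placement is independent of focal labels; with d < 1 focal-gene windows
    receive proportionally fewer sweeps.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _place_genes(spec, rng)
    confounders = _confounder_table(spec, genes, rng)
    sweeps = _place_sweeps(spec, genes, rng)
    scores = _score_table(spec, genes, sweeps, rng)
    return SynthGenome(genes=genes, confounders=confounders, scores=scores, sweep_positions=sweeps)


@dataclass(frozen=True)
class SynthHaplotypeSpec:
    """Conditions for one simulated haplotype sample.

    Neutral by default; setting ``sweep_s`` adds a partial genic sweep at
    ``sweep_position`` that has risen to ``sweep_end_frequency``, the
    configuration iHS/nSL are designed to detect.
    """

    n_haplotypes: int = 100
    sequence_length: int = 200_000
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1.0e-8  # per bp per generation (~1 cM/Mb)
    Ne: int = 10_000
    sweep_position: float | None = None
    sweep_s: float | None = None
    sweep_end_frequency: float = 0.6
    seed: int | None = None


def synth_haplotypes(spec: SynthHaplotypeSpec) -> HaplotypeMatrix:
    """Simulate phased, polarized haplotypes with an msprime backend."""
    import msprime

    seed = (spec.seed or 0) % (2**31 - 2) + 1  # msprime requires seed >= 1
    model: list | str
    if spec.sweep_s is not None:
        pos = spec.sweep_position if spec.sweep_position is not None else spec.sequence_length / 2
        sweep = msprime.SweepGenicSelection(
            position=pos,
            start_frequency=1.0 / (2 * spec.Ne),
            end_frequency=spec.sweep_end_frequency,
            s=spec.sweep_s,
            dt=1.0 / (40 * spec.Ne),
        )
        model = [sweep, msprime.StandardCoalescent()]
    else:
        model = "hudson"
    ts = msprime.sim_ancestry(
        samples=spec.n_haplotypes,
        ploidy=1,
        population_size=spec.Ne,
        sequence_length=spec.sequence_length,
        recombination_rate=spec.recombination_rate,
        model=model,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=spec.mutation_rate, model=msprime.BinaryMutationModel(), random_seed=seed + 1
    )
    cols = []
    positions = []
    last_pos = -1
    for var in mts.variants():
        g = var.genotypes
        # polarize onto {0 ancestral, 1 derived}; keep biallelic segregating sites
        alleles = (g != 0).astype(np.int8)
        if alleles.min() == alleles.max():
            continue
        pos = int(var.site.position)
        if pos <= last_pos:
            pos = last_pos + 1
        last_pos = pos
        if pos >= spec.sequence_length:
            continue
        cols.append(alleles)
        positions.append(pos)
    if not cols:
        raise ValueError("no segregating sites simulated; increase mutation rate or length")
    alleles = np.stack(cols, axis=1)
    positions_bp = np.asarray(positions, dtype=np.int64)
    cm_per_bp = spec.recombination_rate * 100.0
    return HaplotypeMatrix(
        alleles=alleles,
        positions_bp=positions_bp,
        positions_cM=positions_bp * cm_per_bp,
    )
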