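"""Forward Wright-Fisher simulation of advantageous/deleterious interference.

The question modeled here: how much do segregating recessive deleterious
variants slow down (or stop) a linked co-dominant advantageous mutation,
and how does an out-of-Africa-like bottleneck — which purges low-frequency
recessive load — relax that interference?

Two engines are provided.

``simulate_single_locus``
    A vectorized single-locus binomial Wright-Fisher sampler used for every
    "no deleterious mutations" condition.  With no linked variation, an
    unlinked background cannot affect the selected locus, so this fast path
    is exact for those cells; the allele starts at one copy and replicates
    are rerun ("rewound") until fixation, giving both the fixation
    probability (fixations per attempt) and the mean conditional time to
    fixation.

``RegionSimulator``
    An individual-based simulation of a genomic region in which a fraction
    of sites is constrained (can receive deleterious mutations, recurrent
    at a per-site rate with a four-point distribution of fitness effects),
    with a higher constrained fraction in a gene-like core where the
    advantageous mutation arises.  Fitness is multiplicative across loci
    and 1 : 1+hs : 1+s within a locus; recombination is Poisson with
    uniform breakpoints.  The population state is checkpointed at the
    introduction generation and restored on every rewind, so the identical
    deleterious background is reused across attempts within a replicate.

Demographies: constant diploid N, or a bottleneck that drops N at the end
of the burn-in; the advantageous mutation is introduced 500 generations
after the bottleneck (the window in which haplotype statistics retain
power for the resulting sweeps).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Demography",
    "SimConfig",
    "SimResult",
    "simulate_single_locus",
    "RegionSimulator",
    "simulate_linked_region",
    "interference_table",
]


@dataclass(frozen=True)
class Demography:
    """Diploid population-size history.

    The population stays at ``N0`` through the burn-in; if ``bottleneck_to``
    is set, N drops to that size at generation ``burn_in`` and stays there.
    """

    N0: int = 10_000
    bottleneck_to: int | None = None

    def size_at(self, generation: int, burn_in: int) -> int:
        if self.bottleneck_to is not None and generation >= burn_in:
            return self.bottleneck_to
        return self.N0

    @property
    def label(self) -> str:
        if self.bottleneck_to is None:
            return f"{self.N0}->{self.N0}"
        return f"{self.N0}->{self.bottleneck_to}"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated condition (defaults: full-scale study).

    The advantageous mutation is co-dominant (h_adv = 0.5) with selection
    coefficient ``s_adv`` and is introduced as a single copy at
    ``intro_generation`` = burn_in + 500.  Deleterious mutations occur at
    constrained sites only: a background fraction across the whole region
    plus an elevated fraction in a central gene-like core, drawing s
    uniformly from ``deleterious_s`` with dominance ``h_del`` (0 recessive,
    1 dominant).
    """

    demography: Demography = Demography(10_000, None)
    burn_in: int = 20_000
    s_adv: float = 0.005
    h_adv: float = 0.5
    region_length: int = 1_000_000
    core_length: int = 100_000
    background_constrained_fraction: float = 0.08
    core_constrained_fraction: float = 0.40
    deleterious_s: tuple[float, ...] = (-0.002, -0.02, -0.1, -0.5)
    h_del: float = 0.0
    recomb_cM_per_Mb: float = 0.1
    deleterious_rate_per_site: float = 1.25e-8
    n_replicates: int = 1000
    seed: int | None = None

    @property
    def intro_generation(self) -> int:
        return self.burn_in + 500

    def __post_init__(self):
        for frac in (self.background_constrained_fraction, self.core_constrained_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("constrained fractions must lie in [0, 1]")
        if self.s_adv <= 0:
            raise ValueError("s_adv must be positive")
        if self.core_length > self.region_length:
            raise ValueError("core_length cannot exceed region_length")

    @property
    def n_constrained_sites(self) -> float:
        bg = self.background_constrained_fraction * (self.region_length - self.core_length)
        core = self.core_constrained_fraction * self.core_length
        return bg + core

    @property
    def u_per_haplotype(self) -> float:
        return self.deleterious_rate_per_site * self.n_constrained_sites

    @staticmethod
    def scaled(
        core_constrained_fraction: float = 0.40,
        h_del: float = 0.0,
        bottleneck: bool = False,
        s_adv: float = 0.01,
    ) -> "SimConfig":
        """Desk-scale interference condition.

        Population and region are reduced 10-fold (N0 = 1000, bottleneck to
        100; 100 kb region with a 10 kb core; burn-in 10N) while every
        per-meiosis quantity of the full-scale condition is preserved: the
        deleterious input per haplotype per generation (per-site rate
        scaled to 1.25e-7 to offset the 10x smaller constrained target) and
        the total map length of the region (1 cM/Mb over 100 kb = the
        full-scale 0.1 cM/Mb over 1 Mb).  All population-scaled intensities
        (2Ns, 2NU, 2Nr) therefore shrink uniformly 10-fold, compressing
        effect magnitudes but preserving their direction and ordering.
        """
        return SimConfig(
            demography=Demography(1000, 100 if bottleneck else None),
            burn_in=10_000,
            s_adv=s_adv,
            region_length=100_000,
            core_length=10_000,
            core_constrained_fraction=core_constrained_fraction,
            h_del=h_del,
            recomb_cM_per_Mb=1.0,
            deleterious_rate_per_site=1.25e-7,
        )


@dataclass
class SimResult:
    """Fixation summary of one simulated condition."""

    p_fix: float
    t_fix: float
    n_attempts: int
    n_fixed: int
    p_fix_se: float
    t_fix_se: float
    with_deleterious: bool = False

    @staticmethod
    def from_outcomes(times: np.ndarray, n_attempts: int, with_deleterious: bool) -> "SimResult":
        n_fixed = len(times)
        p = n_fixed / n_attempts
        return SimResult(
            p_fix=p,
            t_fix=float(np.mean(times)) if n_fixed else np.nan,
            n_attempts=n_attempts,
            n_fixed=n_fixed,
            p_fix_se=float(np.sqrt(p * (1 - p) / n_attempts)),
            t_fix_se=float(np.std(times, ddof=1) / np.sqrt(n_fixed)) if n_fixed > 1 else np.nan,
            with_deleterious=with_deleterious,
        )


def _selection_step_freq(p: np.ndarray, s: float, h: float) -> np.ndarray:
    """Expected next-generation frequency under viability selection."""
    num = p * p * (1 + s) + p * (1 - p) * (1 + h * s)
    wbar = p * p * (1 + s) + 2 * p * (1 - p) * (1 + h * s) + (1 - p) ** 2
    return num / wbar


def simulate_single_locus(
    N: int,
    s: float,
    h: float = 0.5,
    n_attempts: int = 100_000,
    min_fixations: int = 0,
    seed: int | None = None,
    batch_size: int = 50_000,
    max_generations: int = 2_000_000,
) -> SimResult:
    """Single-locus Wright-Fisher fixation experiment, vectorized.

    Each attempt introduces one copy (frequency 1/2N) of an allele with
    genotype fitnesses 1 : 1+hs : 1+s and evolves it by binomial sampling
    of 2N gametes until loss or fixation.  Attempts are run in vectorized
    batches; the run continues past ``n_attempts`` if needed to reach
    ``min_fixations`` fixing trajectories.  ``p_fix`` is fixations per
    attempt, ``t_fix`` the mean number of generations from introduction to
    fixation among fixing attempts.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    times: list[int] = []
    attempts_done = 0
    while attempts_done < n_attempts or len(times) < min_fixations:
        b = batch_size
        if attempts_done < n_attempts:
            b = min(batch_size, max(n_attempts - attempts_done, 1))
        cnt = np.ones(b, dtype=np.int64)
        gen_of = np.zeros(b, dtype=np.int64)
        gen = 0
        while cnt.size:
            gen += 1
            if gen > max_generations:
                raise RuntimeError("single-locus attempt exceeded max_generations")
            p = cnt / two_n
            cnt = rng.binomial(two_n, _selection_step_freq(p, s, h))
            fixed = cnt == two_n
            if fixed.any():
                times.extend([gen] * int(fixed.sum()))
            alive = (cnt > 0) & ~fixed
            cnt = cnt[alive]
        attempts_done += b
    return SimResult.from_outcomes(np.asarray(times, dtype=float), attempts_done, False)


class MeanFitnessUnderflow(RuntimeError):
    pass


class RegionSimulator:
    """Individual-based forward simulation of a region with deleterious load.

    The population is 2N haplotypes; haplotypes 2i and 2i+1 form diploid
    individual i.  Segregating mutations are columns of a uint8 buffer
    (infinite-sites: each mutation has its own continuous position); the
    per-generation dynamics run in a compiled kernel (see ``_kernels``).
    Fixed and lost columns are compacted every few generations — a lost
    column is all zeros and a fixed deleterious column rescales every
    individual's fitness equally, so neither affects the dynamics in the
    interim — while the advantageous column's copy number is checked every
    generation.

    Note on randomness: the kernel uses numba's process-global RNG, seeded
    per instance, so results are deterministic for a fixed sequence of
    calls across all simulators in the process.
    """

    PRUNE_INTERVAL = 4
    INITIAL_COLS = 256

    def __init__(
        self,
        config: SimConfig,
        rng: np.random.Generator | None = None,
        seed: int | None = None,
    ):
        from ._kernels import seed_kernel

        self.cfg = config
        if seed is None:
            src = rng if rng is not None else np.random.default_rng(config.seed)
            seed = int(src.integers(0, 2**31 - 1))
        seed_kernel(seed)
        N = config.demography.N0
        cap_hap = 2 * N  # demographies here never exceed the founding size
        self.N = N
        self.generation = 0
        self.ncols = 0
        self.H = np.zeros((cap_hap, self.INITIAL_COLS), dtype=np.uint8)
        self.H2 = np.zeros_like(self.H)
        self.pos = np.zeros(self.INITIAL_COLS, dtype=float)
        self.s = np.zeros(self.INITIAL_COLS, dtype=float)
        self.h = np.zeros(self.INITIAL_COLS, dtype=float)
        self.adv_col = -1
        self._adv_outcome: str | None = None
        self._since_prune = 0
        self._dfe = np.asarray(config.deleterious_s, dtype=float)
        # crossover probability per meiosis over the region
        self.r_total = config.recomb_cM_per_Mb * (config.region_length / 1e6) / 100.0
        self._core_lo = (config.region_length - config.core_length) / 2
        self._core_hi = self._core_lo + config.core_length
        bg = config.background_constrained_fraction * (config.region_length - config.core_length)
        core = config.core_constrained_fraction * config.core_length
        self._p_core = core / (bg + core) if (bg + core) > 0 else 0.0

    @property
    def n_segregating(self) -> int:
        return self.ncols - (1 if self.adv_col >= 0 else 0)

    def _grow_columns(self) -> None:
        cap = self.H.shape[1] * 2
        for name in ("H", "H2"):
            old = getattr(self, name)
            new = np.zeros((old.shape[0], cap), dtype=np.uint8)
            new[:, : old.shape[1]] = old
            setattr(self, name, new)
        for name in ("pos", "s", "h"):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=float)
            new[: old.size] = old
            setattr(self, name, new)

    def _prune_now(self) -> None:
        from ._kernels import prune_columns

        self.ncols, self.adv_col = prune_columns(
            self.H, self.H2, 2 * self.N, self.ncols, self.pos, self.s, self.h, self.adv_col
        )
        self._since_prune = 0

    def step(self) -> None:
        """Advance one generation: selection, reproduction, mutation."""
        from ._kernels import wf_generation

        cfg = self.cfg
        N_next = cfg.demography.size_at(self.generation + 1, cfg.burn_in)
        margin = 64 + int(10 * 2 * self.N * cfg.u_per_haplotype)
        while self.ncols + margin >= self.H.shape[1]:
            self._grow_columns()
        ncols, adv_count, status = wf_generation(
            self.H,
            self.H2,
            2 * self.N,
            2 * N_next,
            self.ncols,
            self.pos,
            self.s,
            self.h,
            self.adv_col,
            self.r_total,
            float(cfg.region_length),
            cfg.u_per_haplotype,
            self._p_core,
            self._core_lo,
            self._core_hi,
            self._dfe,
            cfg.h_del,
        )
        from ._kernels import ERR_CAPACITY, ERR_UNDERFLOW

        if status == ERR_UNDERFLOW:
            raise MeanFitnessUnderflow(
                f"population mean fitness underflow at generation {self.generation} "
                f"({self.ncols} segregating mutations)"
            )
        if status == ERR_CAPACITY:
            raise RuntimeError("mutation-column capacity exhausted despite headroom")
        self.H, self.H2 = self.H2, self.H
        self.ncols = ncols
        self.N = N_next
        self.generation += 1
        if self.adv_col >= 0:
            if adv_count == 0:
                self._adv_outcome = "lost"
            elif adv_count == 2 * N_next:
                self._adv_outcome = "fixed"
        self._since_prune += 1
        if self._since_prune >= self.PRUNE_INTERVAL:
            self._prune_now()

    # -- public protocol --------------------------------------------------

    def checkpoint_now(self) -> None:
        """Checkpoint the current state as the rewind target."""
        self._prune_now()
        self._checkpoint = (
            self.H[:, : self.ncols].copy(),
            self.pos[: self.ncols].copy(),
            self.s[: self.ncols].copy(),
            self.h[: self.ncols].copy(),
            self.generation,
            self.N,
        )

    def load_state(
        self,
        H: np.ndarray,
        pos: np.ndarray,
        s: np.ndarray,
        h: np.ndarray,
        generation: int,
        N: int,
    ) -> None:
        """Adopt an externally provided population state (e.g. a snapshot
        from another simulator's equilibrated chain)."""
        n = H.shape[1]
        while n + 128 >= self.H.shape[1]:
            self._grow_columns()
        hi = max(self.ncols, n)
        self.H[:, :hi] = 0
        self.H2[:, :hi] = 0
        self.H[: H.shape[0], :n] = H
        self.pos[:n] = pos
        self.s[:n] = s
        self.h[:n] = h
        self.ncols = n
        self.generation = generation
        self.N = N
        self.adv_col = -1
        self._adv_outcome = None
        self._since_prune = 0

    def run_burn_in(self) -> None:
        """Run to the introduction generation and checkpoint the state."""
        while self.generation < self.cfg.intro_generation:
            self.step()
        self.checkpoint_now()

    def rewind(self) -> None:
        H, pos, s, h, gen, N = self._checkpoint
        n = H.shape[1]
        if self.ncols > n:  # restore the zero invariant beyond the checkpoint
            self.H[:, n : self.ncols] = 0
            self.H2[:, n : self.ncols] = 0
        self.H[:, :n] = H
        self.pos[:n] = pos
        self.s[:n] = s
        self.h[:n] = h
        self.ncols = n
        self.generation = gen
        self.N = N
        self.adv_col = -1
        self._adv_outcome = None
        self._since_prune = 0

    def attempt(self, max_generations: int = 500_000) -> tuple[bool, int]:
        """One rewind-and-introduce attempt; returns (fixed, generations).

        The post-introduction population size is constant under both
        supported demographies, so the whole absorption run executes inside
        the compiled loop.
        """
        from ._kernels import (
            CONTINUE,
            ERR_CAPACITY,
            ERR_UNDERFLOW,
            FIXED,
            LOST,
            kernel_randint,
            wf_run,
        )

        cfg = self.cfg
        self.rewind()
        margin = 128 + int(10 * 2 * self.N * cfg.u_per_haplotype)
        while self.ncols + margin >= self.H.shape[1]:
            self._grow_columns()
        c = self.ncols  # column is all-zero by invariant
        self.H[int(kernel_randint(2 * self.N)), c] = 1
        self.pos[c] = cfg.region_length / 2.0
        self.s[c] = cfg.s_adv
        self.h[c] = cfg.h_adv
        self.adv_col = c
        self.ncols = c + 1
        gens_total = 0
        while True:
            while self.ncols + 128 >= self.H.shape[1]:
                self._grow_columns()
            ncols, adv_col, outcome, gens, parity = wf_run(
                self.H,
                self.H2,
                2 * self.N,
                self.ncols,
                self.pos,
                self.s,
                self.h,
                self.adv_col,
                self.r_total,
                float(cfg.region_length),
                cfg.u_per_haplotype,
                self._p_core,
                self._core_lo,
                self._core_hi,
                self._dfe,
                cfg.h_del,
                max_generations - gens_total,
            )
            self.ncols = ncols
            self.adv_col = adv_col
            if parity:
                self.H, self.H2 = self.H2, self.H
            gens_total += gens
            self.generation += gens
            if outcome == FIXED:
                return True, gens_total
            if outcome == LOST:
                return False, gens_total
            if outcome == ERR_CAPACITY:
                continue  # grow the buffers and resume
            if outcome == ERR_UNDERFLOW:
                raise MeanFitnessUnderflow(
                    f"population mean fitness underflow at generation {self.generation} "
                    f"({self.ncols} segregating mutations)"
                )
            if outcome == CONTINUE:
                warnings.warn(
                    "advantageous allele not absorbed within max_generations; counted as loss"
                )
                return False, gens_total


def simulate_linked_region(
    config: SimConfig,
    n_attempts: int = 1000,
    min_fixations: int = 0,
    n_burn_ins: int = 1,
    seed: int | None = None,
) -> SimResult:
    """Fixation experiment for the advantageous allele on a deleterious background.

    Runs ``n_burn_ins`` independent burn-ins (each checkpointed at the
    introduction generation) and distributes rewind attempts across them
    round-robin until both ``n_attempts`` and ``min_fixations`` are met.
    With a zero deleterious rate this reduces to the single-locus model.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    sims = []
    for _ in range(n_burn_ins):
        sim = RegionSimulator(config, rng)
        sim.run_burn_in()
        sims.append(sim)
    times: list[int] = []
    attempts = 0
    i = 0
    while attempts < n_attempts or len(times) < min_fixations:
        fixed, gens = sims[i % len(sims)].attempt()
        if fixed:
            times.append(gens)
        attempts += 1
        i += 1
    return SimResult.from_outcomes(np.asarray(times, dtype=float), attempts, True)


def interference_experiment(
    config: SimConfig,
    n_fixations: int = 200,
    n_backgrounds: int = 25,
    spacing_gens: int = 2000,
    seed: int | None = None,
) -> SimResult:
    """Fixation experiment averaged over many deleterious backgrounds.

    The variance of interference outcomes is dominated by which deleterious
    variants happen to segregate near the selected site when the allele is
    introduced, so the experiment must average over backgrounds — the full
    protocol draws a fresh burn-in per replicate.  To keep that affordable,
    one long chain at the founding size equilibrates for ``config.burn_in``
    generations and is then snapshotted every ``spacing_gens`` generations
    (long relative to the turnover time of segregating deleterious
    variants).  Each snapshot seeds one background: the demography's
    post-burn-in size applies for the 500 generations before introduction,
    the state is checkpointed, and rewind attempts run until the
    background's equal share of ``n_fixations`` is collected.
    """
    from dataclasses import replace as _replace

    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    s1, s2 = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    chain_cfg = _replace(config, demography=Demography(config.demography.N0, None))
    chain = RegionSimulator(chain_cfg, seed=s1)
    worker = RegionSimulator(config, seed=s2)
    while chain.generation < config.burn_in:
        chain.step()
    times: list[int] = []
    attempts = 0
    for k in range(n_backgrounds):
        target = chain.generation + spacing_gens
        while chain.generation < target:
            chain.step()
        chain._prune_now()
        worker.load_state(
            chain.H[:, : chain.ncols],
            chain.pos[: chain.ncols],
            chain.s[: chain.ncols],
            chain.h[: chain.ncols],
            generation=config.burn_in,
            N=chain.N,
        )
        while worker.generation < config.intro_generation:
            worker.step()
        worker.checkpoint_now()
        quota = n_fixations // n_backgrounds + (1 if k < n_fixations % n_backgrounds else 0)
        got = 0
        while got < quota:
            fixed, gens = worker.attempt()
            attempts += 1
            if fixed:
                times.append(gens)
                got += 1
    return SimResult.from_outcomes(np.asarray(times, dtype=float), attempts, True)


def interference_table(
    cells: list[SimConfig],
    n_attempts: int = 1000,
    min_fixations: int = 0,
    n_burn_ins: int = 1,
    single_locus_attempts: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """With/without-deleterious comparison for a list of conditions.

    For every config, the "with deleterious" cell runs the linked-region
    engine and the paired "without" cell runs the exact single-locus fast
    path at the post-introduction population size.  Output mirrors the
    published comparison layout: one row pair per condition with the
    fixation-time increase (t_with / t_without) and fixation-probability
    decrease (p_with / p_without) ratios and propagated Monte-Carlo errors.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for cfg, child in zip(cells, ss.spawn(len(cells))):
        s1, s2 = child.spawn(2)
        n_intro = cfg.demography.size_at(cfg.intro_generation, cfg.burn_in)
        without = simulate_single_locus(
            n_intro,
            cfg.s_adv,
            cfg.h_adv,
            n_attempts=single_locus_attempts or n_attempts,
            min_fixations=min_fixations,
            seed=int(s1.generate_state(1)[0] % 2**31),
        )
        with_del = simulate_linked_region(
            cfg,
            n_attempts=n_attempts,
            min_fixations=min_fixations,
            n_burn_ins=n_burn_ins,
            seed=int(s2.generate_state(1)[0] % 2**31),
        )
        t_ratio = with_del.t_fix / without.t_fix
        p_ratio = with_del.p_fix / without.p_fix
        t_ratio_se = t_ratio * np.sqrt(
            (with_del.t_fix_se / with_del.t_fix) ** 2 + (without.t_fix_se / without.t_fix) ** 2
        )
        rows.append(
            {
                "s_adv": cfg.s_adv,
                "core_constrained_fraction": cfg.core_constrained_fraction,
                "dominance": "recessive" if cfg.h_del == 0 else "dominant",
                "demography": cfg.demography.label,
                "t_fix_without": without.t_fix,
                "t_fix_with": with_del.t_fix,
                "p_fix_without": without.p_fix,
                "p_fix_with": with_del.p_fix,
                "fix_time_increase": t_ratio,
                "fix_time_increase_se": t_ratio_se,
                "fix_prob_decrease": p_ratio,
                "n_fixed_with": with_del.n_fixed,
                "n_fixed_without": without.n_fixed,
            }
        )
    return pd.DataFrame(rows)
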