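"""Compiled per-generation kernels for the linked-region simulator.

The individual-based Wright-Fisher generation (multiplicative diploid
fitness, fitness-weighted parent sampling via an alias table, gamete
formation with rare crossovers, recurrent deleterious mutation) runs in
numba so the rewind-until-fixation protocol stays tractable at desk scale.
Haplotypes are rows of a uint8 buffer; segregating mutations are columns
with parallel position / selection / dominance arrays.  Fixed and lost
columns are compacted every few generations — a lost column is all zeros
and a fixed deleterious column rescales every individual's fitness
equally, so neither affects the dynamics in the interim — while the
advantageous column's copy number is checked every generation.
"""
from __future__ import annotations

import numpy as np
from numba import njit

PRUNE_INTERVAL = 4

# outcome codes returned by the run loop
CONTINUE = 0
LOST = 1
FIXED = 2
ERR_UNDERFLOW = -1
ERR_CAPACITY = -2


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def kernel_randint(n):
    """Uniform integer in [0, n) from the kernel RNG stream."""
    return np.random.randint(0, n)


@njit(cache=True)
def _build_alias(w, prob, alias):
    """Vose alias table for O(1) weighted sampling."""
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        total += w[i]
    scaled = np.empty(n)
    small = np.empty(n, dtype=np.int64)
    large = np.empty(n, dtype=np.int64)
    ns = 0
    nl = 0
    for i in range(n):
        scaled[i] = w[i] * n / total
        if scaled[i] < 1.0:
            small[ns] = i
            ns += 1
        else:
            large[nl] = i
            nl += 1
    while ns > 0 and nl > 0:
        ns -= 1
        s = small[ns]
        nl -= 1
        big = large[nl]
        prob[s] = scaled[s]
        alias[s] = big
        scaled[big] = scaled[big] + scaled[s] - 1.0
        if scaled[big] < 1.0:
            small[ns] = big
            ns += 1
        else:
            large[nl] = big
            nl += 1
    while nl > 0:
        nl -= 1
        prob[large[nl]] = 1.0
        alias[large[nl]] = large[nl]
    while ns > 0:
        ns -= 1
        prob[small[ns]] = 1.0
        alias[small[ns]] = small[ns]


@njit(cache=True)
def _one_generation(
    H,
    H2,
    n_hap,
    n_hap_next,
    ncols,
    pos,
    sarr,
    harr,
    adv_col,
    r_total,
    region_length,
    u_hap,
    p_core,
    core_lo,
    core_hi,
    dfe,
    h_del,
    prob,
    alias,
):
    """One generation from H into H2; returns (ncols, adv_count, status)."""
    n_ind = n_hap // 2
    # diploid multiplicative fitness via a branchless per-column genotype
    # multiplier table; weight duplicated per haplotype so a single alias
    # draw yields (parent, transmitted haplotype) jointly
    tab = np.empty(3 * ncols)
    for c in range(ncols):
        tab[3 * c] = 1.0
        tab[3 * c + 1] = 1.0 + harr[c] * sarr[c]
        tab[3 * c + 2] = 1.0 + sarr[c]
    w2 = np.empty(n_hap)
    wsum = 0.0
    for i in range(n_ind):
        wi = 1.0
        a = 2 * i
        b = a + 1
        for c in range(ncols):
            wi *= tab[3 * c + H[a, c] + H[b, c]]
        w2[a] = wi
        w2[b] = wi
        wsum += wi
    if wsum <= 0.0 or not np.isfinite(wsum):
        return ncols, -1, ERR_UNDERFLOW
    _build_alias(w2, prob, alias)

    src_of = np.empty(n_hap_next, dtype=np.int64)
    for k in range(n_hap_next):
        u = np.random.random() * n_hap
        i = int(u)
        if u - i >= prob[i]:
            i = alias[i]
        src_of[k] = i
        for c in range(ncols):
            H2[k, c] = H[i, c]

    # crossovers: total events are Poisson(n_gametes * r), each hitting a
    # uniform gamete — equivalent to a per-gamete Poisson number of events
    if r_total > 0.0 and ncols > 0:
        n_events = np.random.poisson(n_hap_next * r_total)
        for _e in range(n_events):
            k = np.random.randint(0, n_hap_next)
            bp = np.random.random() * region_length
            src = src_of[k]
            other = src ^ 1  # the parent's homologous haplotype
            # swap the parental source of all sites beyond the breakpoint
            for c in range(ncols):
                if pos[c] >= bp:
                    H2[k, c] = H[other, c] if H2[k, c] == H[src, c] else H[src, c]

    # recurrent deleterious mutation at constrained sites; columns at and
    # beyond ncols are all-zero by invariant, so no per-column clearing
    n_new = np.random.poisson(n_hap_next * u_hap)
    for _m in range(n_new):
        if ncols >= H.shape[1]:
            return ncols, -1, ERR_CAPACITY
        c = ncols
        H2[np.random.randint(0, n_hap_next), c] = 1
        if np.random.random() < p_core:
            pos[c] = core_lo + np.random.random() * (core_hi - core_lo)
        else:
            pos[c] = np.random.random() * region_length
        sarr[c] = dfe[np.random.randint(0, len(dfe))]
        harr[c] = h_del
        ncols += 1

    adv_count = -1
    if adv_col >= 0:
        cnt = 0
        for k in range(n_hap_next):
            cnt += H2[k, adv_col]
        adv_count = cnt
    return ncols, adv_count, CONTINUE


@njit(cache=True)
def prune_columns(H, H2, n_hap, ncols, pos, sarr, harr, adv_col):
    """Compact away fixed and lost columns; returns (ncols, adv_col).

    Restores the all-zero invariant for columns >= the new ncols in both
    buffers (per-row contiguous writes, so the clearing stays cheap in the
    row-major layout).
    """
    write = 0
    new_adv = -1
    for c in range(ncols):
        cnt = 0
        for k in range(n_hap):
            cnt += H[k, c]
        if 0 < cnt < n_hap:
            if write != c:
                for k in range(n_hap):
                    H[k, write] = H[k, c]
                pos[write] = pos[c]
                sarr[write] = sarr[c]
                harr[write] = harr[c]
            if c == adv_col:
                new_adv = write
            write += 1
    if write < ncols:
        for k in range(n_hap):
            for c in range(write, ncols):
                H[k, c] = 0
                H2[k, c] = 0
    return write, new_adv


@njit(cache=True)
def wf_generation(
    H, H2, n_hap, n_hap_next, ncols, pos, sarr, harr, adv_col,
    r_total, region_length, u_hap, p_core, core_lo, core_hi, dfe, h_del,
):
    """Single exposed generation step (offspring left in H2)."""
    prob = np.empty(n_hap)
    alias = np.empty(n_hap, dtype=np.int64)
    return _one_generation(
        H, H2, n_hap, n_hap_next, ncols, pos, sarr, harr, adv_col,
        r_total, region_length, u_hap, p_core, core_lo, core_hi, dfe, h_del,
        prob, alias,
    )


@njit(cache=True)
def wf_run(
    H, H2, n_hap, ncols, pos, sarr, harr, adv_col,
    r_total, region_length, u_hap, p_core, core_lo, core_hi, dfe, h_del,
    max_gens,
):
    """Run at constant population size until the advantageous allele is
    absorbed (or max_gens elapse, or no allele is tracked).

    Returns (ncols, adv_col, outcome, gens_done, parity); parity 1 means
    the final population sits in H2 rather than H.  Outcome is LOST/FIXED
    for absorption, CONTINUE when max_gens ran out, or an error code.
    """
    prob = np.empty(n_hap)
    alias = np.empty(n_hap, dtype=np.int64)
    A = H
    B = H2
    parity = 0
    gens = 0
    outcome = CONTINUE
    since_prune = 0
    while gens < max_gens:
        if ncols + 64 >= A.shape[1]:
            outcome = ERR_CAPACITY
            break
        ncols, adv_count, status = _one_generation(
            A, B, n_hap, n_hap, ncols, pos, sarr, harr, adv_col,
            r_total, region_length, u_hap, p_core, core_lo, core_hi, dfe, h_del,
            prob, alias,
        )
        if status != CONTINUE:
            outcome = status
            break
        A, B = B, A
        parity ^= 1
        gens += 1
        if adv_col >= 0:
            if adv_count == 0:
                outcome = LOST
                break
            if adv_count == n_hap:
                outcome = FIXED
                break
        since_prune += 1
        if since_prune >= PRUNE_INTERVAL:
            ncols, adv_col = prune_columns(A, B, n_hap, ncols, pos, sarr, harr, adv_col)
            since_prune = 0
    return ncols, adv_col, outcome, gens, parity
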