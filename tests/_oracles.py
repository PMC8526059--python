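"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written by the dumbest correct route —
explicit pair enumeration for the haplotype statistics, direct numerical
integration of the diffusion formulas for fixation quantities — and shares
no code with the package internals it checks.
"""
from __future__ import annotations

import numpy as np
from scipy import integrate


# -- haplotype statistics by brute-force pair enumeration --------------------


def brute_ehh(alleles: np.ndarray, core: int, allele: int, site: int) -> float:
    """EHH at `site`: fraction of carrier pairs identical over core..site."""
    carriers = np.flatnonzero(alleles[:, core] == allele)
    lo, hi = (site, core - 1) if site < core else (core + 1, site)
    block = alleles[carriers][:, lo : hi + 1]
    n = len(carriers)
    pairs = ident = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if np.array_equal(block[i], block[j]):
                ident += 1
    return ident / pairs


def brute_ihh(alleles: np.ndarray, cm: np.ndarray, core: int, allele: int, floor: float):
    """Trapezoid integral of the brute-force EHH curve over cM, both sides.

    Includes the segment on which the curve first crosses the floor;
    returns None when a side reaches the data edge still at/above floor.
    """
    total = 0.0
    n_sites = alleles.shape[1]
    for step in (-1, 1):
        prev_pos, prev_ehh = cm[core], 1.0
        j = core + step
        bounded = False
        while 0 <= j < n_sites:
            e = brute_ehh(alleles, core, allele, j)
            total += 0.5 * (prev_ehh + e) * abs(cm[j] - prev_pos)
            prev_pos, prev_ehh = cm[j], e
            if e < floor:
                bounded = True
                break
            j += step
        if not bounded:
            return None
    return total


def brute_ihs(alleles: np.ndarray, cm: np.ndarray, core: int, floor: float = 0.05):
    a = brute_ihh(alleles, cm, core, 0, floor)
    d = brute_ihh(alleles, cm, core, 1, floor)
    if a is None or d is None or a <= 0 or d <= 0:
        return None
    return np.log(a / d)


def brute_nsl(alleles: np.ndarray, core: int) -> float:
    """ln ratio of mean pairwise identity-tract lengths (in sites)."""
    n_sites = alleles.shape[1]

    def mean_length(allele: int) -> float:
        carriers = np.flatnonzero(alleles[:, core] == allele)
        lengths = []
        for x in range(len(carriers)):
            for y in range(x + 1, len(carriers)):
                hi, hj = alleles[carriers[x]], alleles[carriers[y]]
                left = 0
                j = core - 1
                while j >= 0 and hi[j] == hj[j]:
                    left += 1
                    j -= 1
                right = 0
                j = core + 1
                while j < n_sites and hi[j] == hj[j]:
                    right += 1
                    j += 1
                lengths.append(1 + left + right)
        return float(np.mean(lengths))

    return float(np.log(mean_length(0) / mean_length(1)))


# -- Kimura diffusion formulas ----------------------------------------------


def diffusion_fixation(N: int, s: float, h: float = 0.5, p: float | None = None):
    """Fixation probability and conditional mean fixation time.

    Genic (co-dominant) selection with per-copy coefficient h*s; drift
    variance x(1-x)/2N.  The conditional sojourn density t(x; p) u(x)/u(p)
    is integrated with numerically stable exponential-difference forms.
    """
    if p is None:
        p = 1.0 / (2 * N)
    beta = 4 * N * s * h
    denom = -np.expm1(-beta)

    def u(x):
        return -np.expm1(-beta * x) / denom

    def V(x):
        return x * (1 - x) / (2 * N)

    up = u(p)

    def t_above(x):
        return 2 * u(x) * (-np.expm1(-beta * (1 - x))) / (beta * V(x))

    def t_below(x):
        return 2 * (1 - up) * np.expm1(beta * x) / (beta * V(x)) * u(x) / up

    t1, _ = integrate.quad(t_above, p, 1, limit=800)
    t2, _ = integrate.quad(t_below, 1e-15, p, limit=400)
    return up, t1 + t2
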