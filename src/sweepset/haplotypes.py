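"""Haplotype-based selective-sweep statistics: EHH, iHS and nSL.

A recent, strong positive selection event ("selective sweep") drags the
haplotype carrying the advantageous allele to high frequency faster than
recombination can break it up, so the derived allele at a hitchhiking SNP
sits on unusually long stretches of haplotype homozygosity.  The integrated
haplotype score (iHS) captures this by comparing the area under the extended
haplotype homozygosity (EHH) curve, measured in genetic-map units, between
carriers of the ancestral and of the derived allele at each SNP.  nSL is the
map-free analogue in which haplotype length is counted in number of
segregating sites instead of centimorgans, making it more robust to local
recombination-rate variation.

Both raw statistics are ln ratios (ancestral over derived), so negative
values mean unusually long derived-allele haplotypes, the classic signature
of an incomplete sweep on the derived allele.  Because expected haplotype
length depends strongly on allele frequency, raw values are standardized to
z-scores within derived-allele-frequency bins before use.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeMatrix",
    "ehh_curve",
    "ihs_raw",
    "nsl_raw",
    "standardize",
    "score_haplotypes",
]


class MonomorphicSiteError(ValueError):
    pass


class InsufficientCarriersError(ValueError):
    pass


@dataclass
class HaplotypeMatrix:
    """Phased, ancestral-polarized haplotypes.

    alleles
        (n_haplotypes, n_sites) binary matrix, 0 = ancestral, 1 = derived.
        Missing data is not permitted; the caller must filter incomplete
        sites before constructing the matrix.
    positions_bp
        Strictly increasing physical coordinates.
    positions_cM
        Non-decreasing genetic-map coordinates, same length as positions_bp.
    site_ids
        Optional identifiers; defaults to ``site<i>``.
    """

    alleles: np.ndarray
    positions_bp: np.ndarray
    positions_cM: np.ndarray
    site_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.int8))
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cM = np.asarray(self.positions_cM, dtype=np.float64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotypes x sites) matrix")
        n_hap, n_sites = self.alleles.shape
        if n_hap < 4:
            raise ValueError(f"need at least 4 haplotypes, got {n_hap}")
        if self.positions_bp.shape != (n_sites,):
            raise ValueError("positions_bp length does not match number of sites")
        if self.positions_cM.shape != (n_sites,):
            raise ValueError("positions_cM length does not match number of sites")
        if n_sites > 1 and not np.all(np.diff(self.positions_bp) > 0):
            raise ValueError("positions_bp must be strictly increasing")
        if n_sites > 1 and not np.all(np.diff(self.positions_cM) >= 0):
            raise ValueError("positions_cM must be non-decreasing")
        vals = np.unique(self.alleles)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("alleles must contain only 0/1 (missing data not permitted)")
        if self.site_ids is None:
            self.site_ids = np.array([f"site{i}" for i in range(n_sites)])
        else:
            self.site_ids = np.asarray(self.site_ids)
            if self.site_ids.shape != (n_sites,):
                raise ValueError("site_ids length does not match number of sites")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


def _carriers(hap: HaplotypeMatrix, core_site: int, allele: int) -> np.ndarray:
    col = hap.alleles[:, core_site]
    if col.min() == col.max():
        raise MonomorphicSiteError(f"monomorphic site at index {core_site}")
    carriers = np.flatnonzero(col == allele)
    if carriers.size < 2:
        raise InsufficientCarriersError(
            f"insufficient carriers of allele {allele} at site {core_site}"
        )
    return carriers


def _identity_walk(alleles: np.ndarray, carriers: np.ndarray, core_site: int, step: int):
    """Yield (site_index, n_pairs_identical) walking away from the core.

    Pair identity is tracked by refining a partition of the carrier
    haplotypes: two carriers are in the same group iff they are identical
    over every site between the core (exclusive) and the current site
    (inclusive).  The pair count is sum over groups of C(g, 2).
    """
    n_sites = alleles.shape[1]
    groups = np.zeros(carriers.size, dtype=np.int64)
    j = core_site + step
    while 0 <= j < n_sites:
        key = groups * 2 + alleles[carriers, j]
        _, groups = np.unique(key, return_inverse=True)
        counts = np.bincount(groups)
        pairs = int((counts * (counts - 1) // 2).sum())
        yield j, pairs
        if pairs == 0:
            return
        j += step


def ehh_curve(
    hap: HaplotypeMatrix, core_site: int, allele: int, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Extended haplotype homozygosity away from a core SNP.

    EHH at a site is the fraction of carrier pairs that are identical over
    the whole interval from the core to that site.  Returns (site indices,
    EHH values); EHH at the core itself is 1 by definition and is not
    included.  Once the curve reaches 0 it stays 0, so the remaining sites
    are filled with zeros.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    step = -1 if direction == "left" else 1
    carriers = _carriers(hap, core_site, allele)
    npairs = carriers.size * (carriers.size - 1) // 2
    idx: list[int] = []
    vals: list[float] = []
    for j, pairs in _identity_walk(hap.alleles, carriers, core_site, step):
        idx.append(j)
        vals.append(pairs / npairs)
    # fill the zero tail out to the matrix edge
    if vals and vals[-1] == 0.0:
        j = idx[-1] + step
        while 0 <= j < hap.n_sites:
            idx.append(j)
            vals.append(0.0)
            j += step
    return np.asarray(idx, dtype=np.int64), np.asarray(vals, dtype=np.float64)


def _integrated_ehh(
    hap: HaplotypeMatrix, core_site: int, allele: int, ehh_floor: float
) -> float:
    """Trapezoidal integral of the EHH curve over cM, summed over both sides.

    Integration proceeds outward from the core (where EHH = 1) and stops
    after the segment on which the curve first drops below ``ehh_floor``
    (that crossing segment is included).  If the curve reaches the edge of
    the data while still at or above the floor the integral is unbounded
    and NaN is returned ("unbounded integral": the site cannot be scored
    without extrapolating beyond the data).
    """
    carriers = _carriers(hap, core_site, allele)
    cm = hap.positions_cM
    total = 0.0
    for step in (-1, 1):
        prev_pos = cm[core_site]
        prev_ehh = 1.0
        bounded = False
        for j, pairs in _identity_walk(hap.alleles, carriers, core_site, step):
            npairs = carriers.size * (carriers.size - 1) // 2
            e = pairs / npairs
            d = abs(cm[j] - prev_pos)
            total += 0.5 * (prev_ehh + e) * d
            prev_pos, prev_ehh = cm[j], e
            if e < ehh_floor:
                bounded = True
                break
        if not bounded:
            return np.nan
    return total


def ihs_raw(hap: HaplotypeMatrix, core_site: int, ehh_floor: float = 0.05) -> float:
    """Unstandardized iHS: ln(iHH_ancestral / iHH_derived).

    Positive values mean longer ancestral haplotypes; negative values mean
    longer derived haplotypes (sweep on the derived allele).  Returns NaN
    when either allele's EHH curve fails to decay below ``ehh_floor``
    before the edge of the data, or when an integrated EHH is zero.
    """
    ihh_anc = _integrated_ehh(hap, core_site, 0, ehh_floor)
    ihh_der = _integrated_ehh(hap, core_site, 1, ehh_floor)
    if not np.isfinite(ihh_anc) or not np.isfinite(ihh_der):
        return np.nan
    if ihh_anc <= 0 or ihh_der <= 0:
        return np.nan
    return float(np.log(ihh_anc / ihh_der))


def _mean_identity_length(hap: HaplotypeMatrix, core_site: int, allele: int) -> float:
    """Mean over carrier pairs of the haplotype-identity tract length.

    The tract length for a pair is the number of consecutive sites, in a
    maximal interval containing the core, over which the two haplotypes are
    identical.  Writing L = 1 + left extension + right extension, the mean
    left (right) extension is the sum over k >= 1 of the fraction of pairs
    still identical after extending k sites leftward (rightward).  Tracts
    are truncated at the edges of the matrix.
    """
    carriers = _carriers(hap, core_site, allele)
    npairs = carriers.size * (carriers.size - 1) // 2
    mean_len = 1.0
    for step in (-1, 1):
        for _j, pairs in _identity_walk(hap.alleles, carriers, core_site, step):
            mean_len += pairs / npairs
            if pairs == 0:
                break
    return mean_len


def nsl_raw(hap: HaplotypeMatrix, core_site: int) -> float:
    """Unstandardized nSL: ln(SL_ancestral / SL_derived).

    SL_allele is the mean, over pairs of carrier haplotypes, of the length
    in segregating sites of the identity tract around the core.  No genetic
    map is needed; the statistic ignores ``positions_cM`` entirely.  The
    same sign convention as iHS applies.
    """
    sl_anc = _mean_identity_length(hap, core_site, 0)
    sl_der = _mean_identity_length(hap, core_site, 1)
    return float(np.log(sl_anc / sl_der))


def standardize(scores: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """Standardize raw scores within derived-allele-frequency bins.

    ``scores`` needs columns ``freq`` and ``raw``; a ``std`` column is added
    (z-score: (raw - bin mean) / bin population sd).  Bins partition (0, 1)
    into ``n_bins`` equal-width intervals.  Degenerate bins (sd = 0) yield
    NaN with a warning.  Rows with NaN raw stay NaN.
    """
    out = scores.copy()
    freq = out["freq"].to_numpy(dtype=float)
    raw = out["raw"].to_numpy(dtype=float)
    if np.any((freq <= 0) | (freq >= 1)):
        raise ValueError("scored sites must have derived frequency strictly in (0, 1)")
    bins = np.minimum((freq * n_bins).astype(int), n_bins - 1)
    std = np.full_like(raw, np.nan)
    degenerate = []
    for b in np.unique(bins):
        mask = (bins == b) & np.isfinite(raw)
        if not mask.any():
            continue
        vals = raw[mask]
        sd = vals.std()  # population sd
        if sd == 0:
            degenerate.append(b)
            continue
        std[mask] = (vals - vals.mean()) / sd
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} frequency bin(s) with zero sd; their scores are set to NaN",
            stacklevel=2,
        )
    out["std"] = std
    return out


def score_haplotypes(
    hap: HaplotypeMatrix,
    stats: tuple[str, ...] = ("iHS", "nSL"),
    maf_floor: float = 0.05,
    ehh_floor: float = 0.05,
    n_bins: int = 50,
    sites: "np.ndarray | None" = None,
) -> pd.DataFrame:
    """Score eligible SNPs with the requested statistics.

    Sites with minor-allele frequency below ``maf_floor`` are skipped, as
    are sites where either allele has fewer than 2 carriers.  ``sites``
    restricts the *core* SNPs scored (flanking information still uses every
    site); by default every SNP is a core.  Returns a tidy frame (site_id,
    pos_bp, freq, stat, raw, std); raw NaN marks sites flagged unscorable
    (e.g. unbounded iHH integral near the data edge).
    """
    for s in stats:
        if s not in ("iHS", "nSL"):
            raise ValueError(f"unknown statistic {s!r}")
    freqs = hap.derived_freq()
    rows = []
    core_sites = range(hap.n_sites) if sites is None else np.asarray(sites, dtype=int)
    for i in core_sites:
        f = freqs[i]
        maf = min(f, 1 - f)
        if maf < maf_floor or maf == 0:
            continue
        n_der = int(round(f * hap.n_haplotypes))
        if n_der < 2 or hap.n_haplotypes - n_der < 2:
            continue
        for stat in stats:
            raw = ihs_raw(hap, i, ehh_floor) if stat == "iHS" else nsl_raw(hap, i)
            rows.append((hap.site_ids[i], int(hap.positions_bp[i]), f, stat, raw))
    df = pd.DataFrame(rows, columns=["site_id", "pos_bp", "freq", "stat", "raw"])
    if df.empty:
        df["std"] = pd.Series(dtype=float)
        return df
    parts = []
    for stat, grp in df.groupby("stat", sort=False):
        parts.append(standardize(grp, n_bins=n_bins))
    return pd.concat(parts, ignore_index=True)
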