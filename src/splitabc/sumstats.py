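"""Summary statistics of two-population genotype panels.

The ABC step compares observed and simulated data through a fixed, ordered
vector of 46 statistics: per-population diversity (S, singletons,
doubletons, pi, Tajima's D, mean heterozygosity), within- and
between-population IBD segment counts/lengths in three cM bins, per
population ROH counts/lengths in two size classes, cross-population
divergence (Hudson FST, Dxy and the shared/private/fixed site partition),
and overall S and Tajima's D.  Haplotype-based statistics (IBD, ROH) are
included because segment lengths carry most of the information about recent
demography.

IBD detection is a likelihood-ratio scan on unphased genotypes: per site,
the log10 ratio of the probability of the genotype pair given the pair
shares one haplotype identical by descent versus given independence under
Hardy-Weinberg, using sample allele frequencies.  Maximal positive-scoring
contiguous runs (Ruzzo-Tompa extraction) with cumulative LOD >= threshold
and genetic length >= a minimum cM are reported as segments.  ROH scanning
follows the standard sliding-window procedure (50-SNP windows, low
tolerated heterozygote/missing counts, density and gap constraints).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import MISSING

logger = logging.getLogger(__name__)

#: small probability of a mis-scored genotype mixed into the IBD emission
#: model so that opposite homozygotes penalise but never produce -inf LOD
IBD_GENOTYPE_ERROR = 1e-3


class StatsInputError(ValueError):
    """Invalid input to a summary statistic."""


# ---------------------------------------------------------------------------
# Segment types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IBDSegment:
    """One IBD segment between two diploid individuals.

    ``start_idx``/``end_idx`` are half-open indices into the (MAF-filtered)
    site arrays used by the detector; spans are closed over the boundary
    sites' coordinates.
    """

    id1: int
    id2: int
    start_bp: float
    end_bp: float
    start_cm: float
    end_cm: float
    score: float
    start_idx: int = -1
    end_idx: int = -1

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def n_sites(self) -> int:
        return self.end_idx - self.start_idx if self.end_idx >= 0 else 0


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity within a diploid individual."""

    individual: int
    start_bp: float
    end_bp: float
    n_snps: int

    @property
    def length_kb(self) -> int:
        # bp -> kb by floor division, the convention used for kb thresholds
        return int(self.end_bp - self.start_bp) // 1000


# ---------------------------------------------------------------------------
# Allele counts and diversity
# ---------------------------------------------------------------------------


def _allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count, called allele count), missing-aware."""
    g = np.asarray(genotypes)
    called = 2 * (g != MISSING).sum(axis=0)
    alt = np.where(g == MISSING, 0, g).sum(axis=0)
    return alt.astype(np.int64), called.astype(np.int64)


def site_frequency_spectrum(genotypes: np.ndarray, folded: bool = True) -> np.ndarray:
    """Allele-count histogram over segregating sites.

    Folded (minor-allele) by default; entry k counts sites with (minor)
    allele count k, k = 1 .. floor(n/2) (or n-1 unfolded).
    """
    alt, called = _allele_counts(genotypes)
    n = int(called.max(initial=0))
    seg = (alt > 0) & (alt < called)
    counts = alt[seg]
    if folded:
        counts = np.minimum(counts, called[seg] - counts)
        size = n // 2
    else:
        size = max(n - 1, 0)
    out = np.zeros(size, dtype=np.int64)
    for c in counts:
        out[c - 1] += 1
    return out


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from total pairwise diversity and segregating sites.

    ``n`` is the number of sampled allele copies.  Returns NaN when
    undefined (S == 0 or n < 2).
    """
    if S == 0 or n < 2:
        return float("nan")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi - S / a1) / math.sqrt(var)


def diversity_stats(genotypes: np.ndarray) -> dict[str, float]:
    """Within-population diversity summary from diploid dosages.

    pi is the total (summed over sites) average pairwise difference between
    allele copies, the unbiased per-site estimator 2*p*q*n/(n-1) summed over
    segregating sites.  Singletons and doubletons count sites whose minor
    allele count is exactly 1 resp. 2.  Mean heterozygosity is the fraction
    of heterozygous calls among all non-missing genotype calls.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[0] < 1:
        raise StatsInputError("genotypes must be a non-empty (individuals x sites) matrix")
    if g.shape[1] == 0:
        return {"S": 0.0, "singletons": 0.0, "doubletons": 0.0, "pi": 0.0,
                "tajimas_d": float("nan"), "het_mean": 0.0}
    alt, called = _allele_counts(g)
    ok = called >= 2
    seg = ok & (alt > 0) & (alt < called)
    minor = np.minimum(alt, called - alt)
    S = int(seg.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(
            seg, alt * (called - alt) / (called * (called - 1) / 2.0), 0.0
        )
    pi = float(per_site.sum())
    n_called = int((g != MISSING).sum())
    het = float((g == 1).sum() / n_called) if n_called else 0.0
    return {
        "S": float(S),
        "singletons": float(int((seg & (minor == 1)).sum())),
        "doubletons": float(int((seg & (minor == 2)).sum())),
        "pi": pi,
        "tajimas_d": tajimas_d(S, pi, 2 * g.shape[0]),
        "het_mean": het,
    }


def divergence_stats(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> dict[str, float]:
    """Cross-population divergence and the site partition.

    Hudson FST = 1 - Hw/Hb as a ratio of sums over sites, with Hw the mean
    of the two unbiased within-population heterozygosities and Hb the
    between-population heterozygosity pA(1-pB) + pB(1-pA).  Dxy is the sum
    of Hb over sites.  Sites segregating in the combined sample partition
    exhaustively into shared / private to A / private to B / fixed
    differences.
    """
    ga, gb = np.asarray(genotypes_a), np.asarray(genotypes_b)
    if ga.shape[0] < 1 or gb.shape[0] < 1:
        raise StatsInputError("both populations must be non-empty")
    if ga.shape[1] != gb.shape[1]:
        raise StatsInputError("populations must share the same site set")
    alt_a, called_a = _allele_counts(ga)
    alt_b, called_b = _allele_counts(gb)
    ok = (called_a >= 2) & (called_b >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(ok, alt_a / np.maximum(called_a, 1), 0.0)
        pb = np.where(ok, alt_b / np.maximum(called_b, 1), 0.0)
        hw_a = np.where(ok, alt_a * (called_a - alt_a) / np.maximum(called_a * (called_a - 1) / 2.0, 1), 0.0)
        hw_b = np.where(ok, alt_b * (called_b - alt_b) / np.maximum(called_b * (called_b - 1) / 2.0, 1), 0.0)
    hb = np.where(ok, pa * (1 - pb) + pb * (1 - pa), 0.0)
    hw = (hw_a + hw_b) / 2.0
    hb_sum = float(hb.sum())
    fst = 1.0 - float(hw.sum()) / hb_sum if hb_sum > 0 else float("nan")

    seg_a = (alt_a > 0) & (alt_a < called_a)
    seg_b = (alt_b > 0) & (alt_b < called_b)
    alt_t = alt_a + alt_b
    called_t = called_a + called_b
    seg_total = ok & (alt_t > 0) & (alt_t < called_t)
    shared = seg_total & seg_a & seg_b
    private_a = seg_total & seg_a & ~seg_b
    private_b = seg_total & ~seg_a & seg_b
    fixed = seg_total & ~seg_a & ~seg_b
    return {
        "fst": fst,
        "dxy": float(hb.sum()),
        "shared": float(int(shared.sum())),
        "private_a": float(int(private_a.sum())),
        "private_b": float(int(private_b.sum())),
        "fixed_diff": float(int(fixed.sum())),
    }


# ---------------------------------------------------------------------------
# IBD detection
# ---------------------------------------------------------------------------


def _ibd_score_table(freqs: np.ndarray, eps: float = IBD_GENOTYPE_ERROR) -> np.ndarray:
    """Per-site LOD contributions for the 9 ordered genotype pairs.

    Row index = gA*3 + gB; a 10th all-zero row absorbs pairs with a missing
    genotype.  The IBD emission is mixed with the null with weight ``eps``
    so discordant homozygotes score strongly negative but finite.
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    hwe = np.stack([q * q, 2 * p * q, p * p])  # P(g) under HWE
    # P(g | one shared haplotype carries allele a), a in {0, 1}
    #   a=0: g=0 w.p. q, g=1 w.p. p ; a=1: g=1 w.p. q, g=2 w.p. p
    pg0 = np.stack([q, p, np.zeros_like(p)])
    pg1 = np.stack([np.zeros_like(p), q, p])
    table = np.zeros((10, p.size))
    tiny = 1e-300
    for ga in range(3):
        for gb in range(3):
            null = hwe[ga] * hwe[gb]
            ibd = q * pg0[ga] * pg0[gb] + p * pg1[ga] * pg1[gb]
            mixed = (1.0 - eps) * ibd + eps * null
            table[ga * 3 + gb] = np.log10(np.maximum(mixed, tiny)) - np.log10(
                np.maximum(null, tiny)
            )
    return table


@njit(cache=True)
def _ruzzo_tompa(scores, L, R, st, en, ptr):  # pragma: no cover - via detect_ibd
    """All maximal positive-scoring subsequences of ``scores``.

    Fills the provided work buffers; returns the number of subsequences.
    Half-open index ranges in (st, en); sums recoverable as R - L.
    ``ptr[j]`` links each stacked subsequence to the rightmost earlier one
    with strictly smaller L, making the left-extension search amortised
    linear.
    """
    n = scores.shape[0]
    top = 0
    cum = 0.0
    for i in range(n):
        x = scores[i]
        c0 = cum
        cum = cum + x
        if x <= 0.0:
            continue
        kL, kR, ks, ke = c0, cum, i, i + 1
        while True:
            # rightmost stacked subsequence with L < kL (via skip links)
            j = top - 1
            while j >= 0 and L[j] >= kL:
                j = ptr[j]
            if j < 0 or R[j] >= kR:
                L[top] = kL
                R[top] = kR
                st[top] = ks
                en[top] = ke
                ptr[top] = j
                top += 1
                break
            # absorb subsequences j..top-1 into the current one
            kL = L[j]
            ks = st[j]
            top = j
    return top


@njit(cache=True)
def _scan_pairs(genotypes, pairs, table, cm, lod_threshold, min_cm):
    """LOD scan over all requested pairs; returns qualifying segments as
    parallel arrays (pair row index, start site, end site, score)."""
    n_pairs = pairs.shape[0]
    nS = genotypes.shape[1]
    scores = np.empty(nS)
    L = np.empty(nS)
    R = np.empty(nS)
    st = np.empty(nS, np.int64)
    en = np.empty(nS, np.int64)
    ptr = np.empty(nS, np.int64)
    cap = 256
    out_pair = np.empty(cap, np.int64)
    out_s = np.empty(cap, np.int64)
    out_e = np.empty(cap, np.int64)
    out_sc = np.empty(cap)
    n_out = 0
    for p in range(n_pairs):
        a = pairs[p, 0]
        b = pairs[p, 1]
        for i in range(nS):
            ga = genotypes[a, i]
            gb = genotypes[b, i]
            if ga < 0 or gb < 0:
                scores[i] = 0.0
            else:
                scores[i] = table[ga * 3 + gb, i]
        top = _ruzzo_tompa(scores, L, R, st, en, ptr)
        for k in range(top):
            sc = R[k] - L[k]
            s = st[k]
            e = en[k]
            if sc >= lod_threshold and cm[e - 1] - cm[s] >= min_cm:
                if n_out == cap:
                    cap *= 2
                    out_pair = _grow_i8(out_pair, cap)
                    out_s = _grow_i8(out_s, cap)
                    out_e = _grow_i8(out_e, cap)
                    out_sc = _grow_f8(out_sc, cap)
                out_pair[n_out] = p
                out_s[n_out] = s
                out_e[n_out] = e
                out_sc[n_out] = sc
                n_out += 1
    return out_pair[:n_out].copy(), out_s[:n_out].copy(), out_e[:n_out].copy(), out_sc[:n_out].copy()


@njit(cache=True)
def _grow_i8(arr, cap):  # pragma: no cover
    new = np.empty(cap, np.int64)
    new[: arr.shape[0]] = arr
    return new


@njit(cache=True)
def _grow_f8(arr, cap):  # pragma: no cover
    new = np.empty(cap)
    new[: arr.shape[0]] = arr
    return new


def _pairwise_lod_segments(genotypes, pairs, table, cm, lod_threshold, min_cm):
    """Run the LOD scan for each pair; return raw qualifying segments."""
    pairs_arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    pair_idx, starts, ends, sums = _scan_pairs(
        np.ascontiguousarray(genotypes, dtype=np.int8),
        pairs_arr,
        np.ascontiguousarray(table),
        np.ascontiguousarray(cm, dtype=float),
        float(lod_threshold),
        float(min_cm),
    )
    return [
        (int(pairs_arr[p, 0]), int(pairs_arr[p, 1]), int(s), int(e), float(sc))
        for p, s, e, sc in zip(pair_idx, starts, ends, sums)
    ]


def detect_ibd(
    genotypes: np.ndarray,
    positions: np.ndarray,
    genetic_map,
    min_cm: float = 2.0,
    lod_threshold: float = 3.0,
    maf_min: float = 0.01,
    pairs=None,
) -> list[IBDSegment]:
    """Detect IBD segments between all (or given) pairs of individuals.

    ``genetic_map`` is a :class:`~splitabc.simulate.RecombinationMap` or an
    array of per-site cM positions.  Sites are first filtered to minor
    allele frequency > ``maf_min`` (computed on the supplied genotypes);
    segment coordinates refer to the retained sites.
    """
    g = np.asarray(genotypes)
    if g.shape[0] < 2:
        raise StatsInputError("IBD detection requires >= 2 individuals")
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (g.shape[1],):
        raise StatsInputError("positions must match the site count")
    cm_all = _resolve_cm(genetic_map, positions)

    alt, called = _allele_counts(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf > maf_min
    gk = np.ascontiguousarray(g[:, keep].astype(np.int8))
    cmk = cm_all[keep]
    posk = positions[keep]
    if gk.shape[1] == 0:
        return []

    table = _ibd_score_table(freq[keep])
    if pairs is None:
        n = g.shape[0]
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    raw = _pairwise_lod_segments(gk, pairs, table, cmk, lod_threshold, min_cm)
    return [
        IBDSegment(
            id1=a, id2=b,
            start_bp=float(posk[s]), end_bp=float(posk[e - 1]),
            start_cm=float(cmk[s]), end_cm=float(cmk[e - 1]),
            score=sc, start_idx=s, end_idx=e,
        )
        for a, b, s, e, sc in raw
    ]


def _resolve_cm(genetic_map, positions: np.ndarray) -> np.ndarray:
    if genetic_map is None:
        raise StatsInputError("a genetic map or cM array is required")
    if hasattr(genetic_map, "cm_at"):
        return np.asarray(genetic_map.cm_at(positions), dtype=float)
    cm = np.asarray(genetic_map, dtype=float)
    if cm.shape != positions.shape:
        raise StatsInputError("cM array must match positions")
    return cm


def merge_ibd_gaps(
    segments: list[IBDSegment],
    genotypes: np.ndarray,
    genetic_map,
    positions: np.ndarray | None = None,
    max_gap_cm: float = 0.6,
    max_discordant: int = 1,
) -> list[IBDSegment]:
    """Merge adjacent same-pair segments across short, concordant gaps.

    A gap is closed when it is shorter than ``max_gap_cm`` (genetic length
    between the segments' facing boundary sites) and contains at most
    ``max_discordant`` opposite-homozygote sites for that pair, applied
    iteratively until no further merge is possible.  ``genotypes`` and the
    coordinate arrays must be the same (filtered) site set the detector
    used; segment site indices address into it.
    """
    if not segments:
        return []
    g = np.asarray(genotypes)
    by_pair: dict[tuple[int, int], list[IBDSegment]] = {}
    for seg in segments:
        by_pair.setdefault((seg.id1, seg.id2), []).append(seg)
    merged_all: list[IBDSegment] = []
    for (a, b), segs in by_pair.items():
        segs = sorted(segs, key=lambda s: s.start_cm)
        ga, gb = g[a], g[b]
        opp = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
        out = [segs[0]]
        for nxt in segs[1:]:
            cur = out[-1]
            gap_cm = nxt.start_cm - cur.end_cm
            if cur.end_idx >= 0 and nxt.start_idx >= 0:
                n_disc = int(opp[cur.end_idx : nxt.start_idx].sum())
            else:
                n_disc = max_discordant + 1  # cannot verify -> do not merge
            if gap_cm < max_gap_cm and n_disc <= max_discordant:
                out[-1] = replace(
                    cur,
                    end_bp=nxt.end_bp, end_cm=nxt.end_cm,
                    score=cur.score + nxt.score, end_idx=nxt.end_idx,
                )
            else:
                out.append(nxt)
        merged_all.extend(out)
    return merged_all


def filter_low_density(
    segments: list[IBDSegment], min_snps_per_cm: float = 50.0
) -> list[IBDSegment]:
    """Drop segments whose SNP density (sites per cM) is below threshold.

    Density exactly at the threshold is retained; zero-SNP segments are
    always dropped; zero-cM segments with sites count as infinitely dense.
    """
    kept = []
    for seg in segments:
        n = seg.n_sites
        if n <= 0:
            continue
        length = seg.length_cm
        if length <= 0 or n / length >= min_snps_per_cm:
            kept.append(seg)
    return kept


# ---------------------------------------------------------------------------
# ROH detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH scan thresholds (PLINK-style semantics)."""

    min_snps: int = 50
    min_kb: float = 300.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    window_snps: int = 50
    window_threshold: float = 0.05
    window_het_tol: int = 1
    window_missing_tol: int = 5
    maf_min: float = 0.01


def detect_roh(
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: ROHParams | None = None,
) -> list[ROHSegment]:
    """Scan each individual for runs of homozygosity.

    Windows of ``window_snps`` consecutive SNPs are homozygous when they
    contain at most ``window_het_tol`` heterozygotes and
    ``window_missing_tol`` missing calls; a SNP is in a ROH state when the
    fraction of its overlapping windows that are homozygous is at least
    ``window_threshold``.  Maximal runs of ROH-state SNPs are reported when
    they have >= ``min_snps`` SNPs, span >= ``min_kb`` kb, have density
    <= ``min_density_kb_per_snp`` kb per SNP, and contain no inter-SNP gap
    > ``max_gap_kb`` kb (runs are split at such gaps).
    """
    params = params or ROHParams()
    g = np.asarray(genotypes)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (g.shape[1],):
        raise StatsInputError("positions must match the site count")
    if positions.size and np.any(np.diff(positions) <= 0):
        raise StatsInputError("positions must be strictly increasing")

    alt, called = _allele_counts(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    keep = np.minimum(freq, 1 - freq) > params.maf_min
    gk = g[:, keep]
    posk = positions[keep]
    S = gk.shape[1]
    w = params.window_snps
    segments: list[ROHSegment] = []
    if S == 0:
        return segments

    for ind in range(g.shape[0]):
        row = gk[ind]
        het = (row == 1).astype(np.int64)
        miss = (row == MISSING).astype(np.int64)
        if S >= w:
            het_c = np.concatenate([[0], np.cumsum(het)])
            mis_c = np.concatenate([[0], np.cumsum(miss)])
            het_w = het_c[w:] - het_c[:-w]
            mis_w = mis_c[w:] - mis_c[:-w]
            hom_w = (het_w <= params.window_het_tol) & (mis_w <= params.window_missing_tol)
            # SNP i overlaps windows starting in [i-w+1, i] clipped to valid range
            hw_c = np.concatenate([[0], np.cumsum(hom_w.astype(np.int64))])
            lo = np.clip(np.arange(S) - w + 1, 0, S - w)
            hi = np.clip(np.arange(S), 0, S - w)
            n_hom = hw_c[hi + 1] - hw_c[lo]
            n_tot = hi - lo + 1
            in_roh = n_hom / n_tot >= params.window_threshold
        else:
            in_roh = np.zeros(S, dtype=bool)
        segments.extend(_runs_to_roh(ind, in_roh, posk, params))
    return segments


def _runs_to_roh(ind: int, in_roh: np.ndarray, pos: np.ndarray, params: ROHParams):
    S = in_roh.size
    if S == 0 or not in_roh.any():
        return []
    # consecutive ROH-state SNPs stay in one run only if their gap is small
    conn = in_roh[:-1] & in_roh[1:] & (np.diff(pos) <= params.max_gap_kb * 1000)
    starts = np.where(in_roh & np.concatenate(([True], ~conn)))[0]
    ends = np.where(in_roh & np.concatenate((~conn, [True])))[0]
    out = []
    for i, j in zip(starts, ends):
        n_snps = int(j - i + 1)
        length_kb = int(pos[j] - pos[i]) // 1000
        if (
            n_snps >= params.min_snps
            and length_kb >= params.min_kb
            and length_kb / n_snps <= params.min_density_kb_per_snp
        ):
            out.append(ROHSegment(ind, float(pos[i]), float(pos[j]), n_snps))
    return out


# ---------------------------------------------------------------------------
# Binned IBD summaries and the 46-statistic registry
# ---------------------------------------------------------------------------

DEFAULT_IBD_BINS = ((2.0, 4.0), (4.0, 8.0), (8.0, math.inf))


def ibd_bin_stats(
    segments: list[IBDSegment],
    groups: dict[int, str],
    bins_cm=DEFAULT_IBD_BINS,
) -> dict[tuple[str, str], dict[tuple[float, float], dict[str, float]]]:
    """Count and total segment cM per group pair per length bin.

    Bins are left-closed, right-open; each segment lands in at most one bin.
    Group-pair keys are sorted label tuples.
    """
    out: dict = {}
    for seg in segments:
        key = tuple(sorted((groups[seg.id1], groups[seg.id2])))
        length = seg.length_cm
        for lo, hi in bins_cm:
            if lo <= length < hi:
                cell = out.setdefault(key, {b: {"count": 0.0, "total_cm": 0.0} for b in bins_cm})
                cell[(lo, hi)]["count"] += 1
                cell[(lo, hi)]["total_cm"] += length
                break
    return out


@dataclass(frozen=True)
class StatRegistry:
    """Configuration of the fixed summary-statistic vector."""

    ibd_min_cm: float = 2.0
    ibd_lod: float = 3.0
    ibd_maf_min: float = 0.01
    ibd_max_gap_cm: float = 0.6
    ibd_max_discordant: int = 1
    ibd_min_snps_per_cm: float = 50.0
    ibd_bins: tuple = DEFAULT_IBD_BINS
    roh: ROHParams = field(default_factory=ROHParams)
    roh_split_kb: float = 1000.0  # < 1 Mb vs >= 1 Mb classes
    version: str = "default-46-v1"


def _bin_tag(lo: float, hi: float) -> str:
    return f"{lo:g}_{'inf' if math.isinf(hi) else f'{hi:g}'}"


def registry_names(registry: StatRegistry | None = None) -> tuple[str, ...]:
    """The fixed order of the 46 statistics."""
    registry = registry or StatRegistry()
    names: list[str] = []
    for pop in ("cab", "moz"):
        names += [f"{pop}_{s}" for s in ("S", "singletons", "doubletons", "pi", "tajd", "het")]
    for pop in ("cab", "moz"):
        for lo, hi in registry.ibd_bins:
            tag = _bin_tag(lo, hi)
            names += [f"{pop}_ibd_count_{tag}", f"{pop}_ibd_cm_{tag}"]
    for pop in ("cab", "moz"):
        names += [
            f"{pop}_roh_count_lt1mb", f"{pop}_roh_kb_lt1mb",
            f"{pop}_roh_count_ge1mb", f"{pop}_roh_kb_ge1mb",
        ]
    names += ["fst", "dxy", "shared", "private_a", "private_b", "fixed_diff"]
    for lo, hi in registry.ibd_bins:
        tag = _bin_tag(lo, hi)
        names += [f"cross_ibd_count_{tag}", f"cross_ibd_cm_{tag}"]
    names += ["all_S", "all_tajd"]
    return tuple(names)


@dataclass(frozen=True)
class SummaryVector:
    """Ordered, named vector of the 46 summary statistics."""

    names: tuple[str, ...]
    values: np.ndarray
    version: str = "default-46-v1"

    def __post_init__(self) -> None:
        if len(self.names) != self.values.shape[0]:
            raise StatsInputError("names/values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __len__(self) -> int:
        return len(self.names)


def _roh_class_stats(segments: list[ROHSegment], split_kb: float) -> tuple[float, float, float, float]:
    short = [s for s in segments if s.length_kb < split_kb]
    long_ = [s for s in segments if s.length_kb >= split_kb]
    return (
        float(len(short)), float(sum(s.length_kb for s in short)),
        float(len(long_)), float(sum(s.length_kb for s in long_)),
    )


def _ibd_pipeline(genotypes, positions, genetic_map, registry: StatRegistry, pairs=None):
    segs = detect_ibd(
        genotypes, positions, genetic_map,
        min_cm=registry.ibd_min_cm, lod_threshold=registry.ibd_lod,
        maf_min=registry.ibd_maf_min, pairs=pairs,
    )
    if segs:
        # reconstruct the detector's filtered site view for gap accounting
        g = np.asarray(genotypes)
        alt, called = _allele_counts(g)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
        keep = np.minimum(freq, 1 - freq) > registry.ibd_maf_min
        gk = g[:, keep]
        cmk = _resolve_cm(genetic_map, np.asarray(positions, dtype=float))[keep]
        segs = merge_ibd_gaps(
            segs, gk, cmk,
            max_gap_cm=registry.ibd_max_gap_cm, max_discordant=registry.ibd_max_discordant,
        )
        segs = filter_low_density(segs, registry.ibd_min_snps_per_cm)
    return segs


def compute_summary_vector(
    genotypes: np.ndarray,
    positions: np.ndarray,
    genetic_map,
    ind_labels: np.ndarray,
    registry: StatRegistry | None = None,
) -> SummaryVector:
    """Compute the fixed 46-statistic vector from a two-population panel.

    ``ind_labels`` assigns each diploid individual to one of exactly two
    populations; label order of first appearance maps to the (cab, moz)
    slots of the registry.  Non-finite statistics are replaced by 0 with a
    logged warning.
    """
    registry = registry or StatRegistry()
    g = np.asarray(genotypes)
    labels = np.asarray(ind_labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise StatsInputError(f"exactly two populations required, got {uniq}")
    idx_a = np.where(labels == uniq[0])[0]
    idx_b = np.where(labels == uniq[1])[0]

    values: list[float] = []
    for idx in (idx_a, idx_b):
        d = diversity_stats(g[idx])
        values += [d["S"], d["singletons"], d["doubletons"], d["pi"], d["tajimas_d"], d["het_mean"]]

    groups = {int(i): str(labels[i]) for i in range(len(labels))}
    for idx, pop in ((idx_a, uniq[0]), (idx_b, uniq[1])):
        if len(idx) >= 2:
            sub = g[idx]
            segs = _ibd_pipeline(sub, positions, genetic_map, registry)
            local_groups = {k: pop for k in range(len(idx))}
            binned = ibd_bin_stats(segs, local_groups, registry.ibd_bins).get((pop, pop), None)
        else:
            binned = None
        for b in registry.ibd_bins:
            if binned is None:
                values += [0.0, 0.0]
            else:
                values += [binned[b]["count"], binned[b]["total_cm"]]

    for idx in (idx_a, idx_b):
        roh = detect_roh(g[idx], positions, registry.roh)
        values += list(_roh_class_stats(roh, registry.roh_split_kb))

    div = divergence_stats(g[idx_a], g[idx_b])
    values += [div["fst"], div["dxy"], div["shared"], div["private_a"], div["private_b"], div["fixed_diff"]]

    cross_pairs = [(int(i), int(j)) for i in idx_a for j in idx_b]
    segs = _ibd_pipeline(g, positions, genetic_map, registry, pairs=cross_pairs)
    binned_all = ibd_bin_stats(segs, groups, registry.ibd_bins)
    cross_key = tuple(sorted((str(uniq[0]), str(uniq[1]))))
    cross = binned_all.get(cross_key)
    for b in registry.ibd_bins:
        if cross is None:
            values += [0.0, 0.0]
        else:
            values += [cross[b]["count"], cross[b]["total_cm"]]

    d_all = diversity_stats(g)
    values += [d_all["S"], d_all["tajimas_d"]]

    arr = np.array(values, dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        names = registry_names(registry)
        logger.warning(
            "summary vector: replacing non-finite values with 0 for %s",
            [names[i] for i in np.where(bad)[0]],
        )
        arr[bad] = 0.0
    sv = SummaryVector(registry_names(registry), arr, version=registry.version)
    assert len(sv) == 46
    return sv


def summary_vector_from_panel(panel, registry: StatRegistry | None = None) -> SummaryVector:
    """Convenience: collapse a phased panel to dosages and summarise."""
    from .simulate import panel_to_genotypes

    genotypes = panel_to_genotypes(panel)
    return compute_summary_vector(
        genotypes, panel.positions, panel.genetic_pos_cm, panel.individual_labels, registry
    )


def segments_to_dataframe(segments):
    """Segments as a BED-like table (0-based half-open bp spans) with
    individual/pair, genetic-length and score columns."""
    import pandas as pd

    rows = []
    for s in segments:
        if isinstance(s, ROHSegment):
            rows.append(
                {"id1": s.individual, "id2": s.individual,
                 "start_bp": int(s.start_bp), "end_bp": int(s.end_bp) + 1,
                 "length_cm": float("nan"), "n_sites": s.n_snps,
                 "length_kb": s.length_kb, "score": float("nan")}
            )
        else:
            rows.append(
                {"id1": s.id1, "id2": s.id2,
                 "start_bp": int(s.start_bp), "end_bp": int(s.end_bp) + 1,
                 "length_cm": s.length_cm, "n_sites": s.n_sites,
                 "length_kb": (int(s.end_bp) - int(s.start_bp)) // 1000,
                 "score": s.score}
            )
    columns = ["id1", "id2", "start_bp", "end_bp", "length_cm", "n_sites",
               "length_kb", "score"]
    return pd.DataFrame(rows, columns=columns)
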