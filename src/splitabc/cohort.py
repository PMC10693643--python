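"""Cohort-level haplotype statistics: f2 allele sharing and the one-tailed
permutation test on mean pairwise IBD.

An f2 allele is a variant whose minor allele appears exactly twice in the
whole dataset; which groups co-carry f2 alleles traces very recent shared
ancestry.  Differences in mean pairwise IBD sharing between groups are
tested by permuting individual group labels and recomputing the pair means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MISSING
from .sumstats import IBDSegment, StatsInputError


@dataclass
class F2SharingMatrix:
    """Symmetric group-by-group counts of co-carried f2 alleles.

    An f2 site carried once each by individuals in groups a and b increments
    C[a, b] and C[b, a] (the diagonal once for a == b); a site whose two
    minor copies sit in one homozygous individual is tallied separately in
    ``within_individual``.  Conservation: diag(C).sum() + offdiag(C).sum()/2
    + within_individual == number of f2 sites tallied.
    """

    groups: list[str]
    counts: np.ndarray
    within_individual: int

    @property
    def total_f2(self) -> int:
        off = self.counts.sum() - np.trace(self.counts)
        return int(np.trace(self.counts) + off // 2 + self.within_individual)

    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)


def find_f2_sites(
    genotypes: np.ndarray,
    positions: np.ndarray | None = None,
    mask: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Indices of sites whose dataset-wide minor allele count equals 2.

    ``mask`` is a list of excluded (start, end) intervals in 0-based
    half-open bp coordinates; sites falling inside any interval are dropped
    (requires ``positions``).
    """
    g = np.asarray(genotypes)
    called = 2 * (g != MISSING).sum(axis=0)
    alt = np.where(g == MISSING, 0, g).sum(axis=0)
    minor = np.minimum(alt, called - alt)
    is_f2 = (minor == 2) & (called > 4)
    idx = np.where(is_f2)[0]
    if mask:
        if positions is None:
            raise StatsInputError("positions required when a mask is given")
        positions = np.asarray(positions)
        keep = np.ones(idx.size, dtype=bool)
        for start, end in mask:
            keep &= ~((positions[idx] >= start) & (positions[idx] < end))
        idx = idx[keep]
    return idx


def f2_sharing(
    sites: np.ndarray, genotypes: np.ndarray, groups: np.ndarray
) -> F2SharingMatrix:
    """Tally which group pairs co-carry each f2 allele.

    For each f2 site, the minor allele's two copies either sit in two
    distinct carriers (increment the symmetric group-pair cell) or in one
    homozygous individual (increment the within-individual tally).
    """
    g = np.asarray(genotypes)
    labels = np.asarray(groups)
    if labels.shape[0] != g.shape[0]:
        raise StatsInputError("groups must label every individual")
    uniq = sorted(set(labels.tolist()))
    gidx = {name: k for k, name in enumerate(uniq)}
    counts = np.zeros((len(uniq), len(uniq)), dtype=np.int64)
    within = 0
    called = 2 * (g != MISSING).sum(axis=0)
    alt = np.where(g == MISSING, 0, g).sum(axis=0)
    for s in np.asarray(sites):
        minor_is_alt = alt[s] <= called[s] - alt[s]
        col = g[:, s]
        if minor_is_alt:
            dosage = np.where(col == MISSING, 0, col)
        else:
            dosage = np.where(col == MISSING, 0, 2 - col)
        carriers = np.where(dosage > 0)[0]
        if carriers.size == 1:
            within += 1  # homozygous doubleton in one individual
        elif carriers.size == 2:
            a, b = gidx[labels[carriers[0]]], gidx[labels[carriers[1]]]
            if a == b:
                counts[a, a] += 1
            else:
                counts[a, b] += 1
                counts[b, a] += 1
    return F2SharingMatrix(uniq, counts, within)


# ---------------------------------------------------------------------------
# Mean pairwise IBD and the permutation test
# ---------------------------------------------------------------------------


def _pair_matrix(segments: list[IBDSegment], n_ind: int, bin_cm) -> np.ndarray:
    """Symmetric matrix of total binned segment cM per individual pair."""
    lo, hi = bin_cm
    M = np.zeros((n_ind, n_ind))
    for seg in segments:
        length = seg.length_cm
        if lo <= length < hi:
            M[seg.id1, seg.id2] += length
            M[seg.id2, seg.id1] += length
    return M


def _mean_over_pairs(M: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    same = idx_a.shape == idx_b.shape and np.array_equal(np.sort(idx_a), np.sort(idx_b))
    if same:
        if idx_a.size < 2:
            raise StatsInputError("within-group mean requires >= 2 members")
        sub = M[np.ix_(idx_a, idx_a)]
        n_pairs = idx_a.size * (idx_a.size - 1) / 2
        return float(np.triu(sub, 1).sum() / n_pairs)
    if idx_a.size == 0 or idx_b.size == 0:
        raise StatsInputError("groups must be non-empty")
    sub = M[np.ix_(idx_a, idx_b)]
    return float(sub.sum() / (idx_a.size * idx_b.size))


def mean_pairwise_ibd(
    segments: list[IBDSegment],
    groups: dict[int, str],
    group_a: str,
    group_b: str,
    bin_cm=(2.0, 4.0),
    n_individuals: int | None = None,
) -> float:
    """Mean total segment cM per pair (a in A, b in B) in a length bin.

    For A == B the mean runs over unordered within-group pairs.  Pairs with
    no segment contribute 0.
    """
    n = n_individuals or (max(groups) + 1)
    M = _pair_matrix(segments, n, bin_cm)
    labels = np.array([groups.get(i, "") for i in range(n)])
    return _mean_over_pairs(M, np.where(labels == group_a)[0], np.where(labels == group_b)[0])


def permutation_test_ibd(
    segments: list[IBDSegment],
    groups: dict[int, str],
    group_x: str,
    group_y: str,
    reference_group: str | None = None,
    bin_cm=(2.0, 4.0),
    n_perm: int = 10_000,
    seed: int = 0,
    n_individuals: int | None = None,
) -> float:
    """One-tailed permutation p-value for excess mean pairwise IBD.

    Without a reference group the statistic is (within-X mean) - (within-Y
    mean); with one it is mean(ref, X) - mean(ref, Y).  Labels of X and Y
    individuals are permuted; p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    n = n_individuals or (max(groups) + 1)
    M = _pair_matrix(segments, n, bin_cm)
    labels = np.array([groups.get(i, "") for i in range(n)])
    idx_x = np.where(labels == group_x)[0]
    idx_y = np.where(labels == group_y)[0]
    if reference_group is not None:
        idx_ref = np.where(labels == reference_group)[0]
        if idx_ref.size == 0:
            raise StatsInputError(f"empty reference group {reference_group!r}")
    min_size = 2 if reference_group is None else 1
    if idx_x.size < min_size or idx_y.size < min_size:
        raise StatsInputError("groups too small for the requested statistic")

    def stat(ix, iy):
        if reference_group is None:
            return _mean_over_pairs(M, ix, ix) - _mean_over_pairs(M, iy, iy)
        return _mean_over_pairs(M, idx_ref, ix) - _mean_over_pairs(M, idx_ref, iy)

    observed = stat(idx_x, idx_y)
    pool = np.concatenate([idx_x, idx_y])
    nx = idx_x.size
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        if stat(perm[:nx], perm[nx:]) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
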