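"""Brute-force oracles: direct double/triple-loop implementations of the
diversity and divergence statistics, independent of the package's vectorised
code paths.  Only usable on small panels."""

import itertools

import numpy as np


def hamming(h1, h2) -> int:
    return int(np.sum(np.asarray(h1) != np.asarray(h2)))


def brute_pi(haplotypes) -> float:
    """Mean pairwise Hamming distance over all haplotype pairs."""
    H = np.asarray(haplotypes)
    pairs = list(itertools.combinations(range(H.shape[0]), 2))
    return sum(hamming(H[i], H[j]) for i, j in pairs) / len(pairs)


def brute_segregating(haplotypes) -> int:
    H = np.asarray(haplotypes)
    return int(sum(0 < H[:, j].sum() < H.shape[0] for j in range(H.shape[1])))


def brute_folded_sfs(haplotypes) -> np.ndarray:
    H = np.asarray(haplotypes)
    n = H.shape[0]
    out = np.zeros(n // 2, dtype=np.int64)
    for j in range(H.shape[1]):
        c = int(H[:, j].sum())
        if 0 < c < n:
            out[min(c, n - c) - 1] += 1
    return out


def brute_hudson_fst(hap_a, hap_b) -> float:
    """1 - Hw/Hb with Hw and Hb as explicit sums over allele-copy pairs."""
    A, B = np.asarray(hap_a), np.asarray(hap_b)
    hw = hb = 0.0
    for j in range(A.shape[1]):
        da = sum(
            hamming(A[i, j : j + 1], A[k, j : j + 1])
            for i, k in itertools.combinations(range(A.shape[0]), 2)
        ) / (A.shape[0] * (A.shape[0] - 1) / 2)
        db = sum(
            hamming(B[i, j : j + 1], B[k, j : j + 1])
            for i, k in itertools.combinations(range(B.shape[0]), 2)
        ) / (B.shape[0] * (B.shape[0] - 1) / 2)
        dab = sum(
            hamming(A[i, j : j + 1], B[k, j : j + 1])
            for i in range(A.shape[0])
            for k in range(B.shape[0])
        ) / (A.shape[0] * B.shape[0])
        hw += (da + db) / 2
        hb += dab
    return 1.0 - hw / hb if hb > 0 else float("nan")


def brute_site_partition(hap_a, hap_b) -> dict:
    """Shared / private / fixed classification by explicit per-site logic."""
    A, B = np.asarray(hap_a), np.asarray(hap_b)
    out = {"shared": 0, "private_a": 0, "private_b": 0, "fixed_diff": 0}
    for j in range(A.shape[1]):
        ca, cb = int(A[:, j].sum()), int(B[:, j].sum())
        seg_a = 0 < ca < A.shape[0]
        seg_b = 0 < cb < B.shape[0]
        total = ca + cb
        if not (0 < total < A.shape[0] + B.shape[0]):
            continue
        if seg_a and seg_b:
            out["shared"] += 1
        elif seg_a:
            out["private_a"] += 1
        elif seg_b:
            out["private_b"] += 1
        else:
            out["fixed_diff"] += 1
    return out


def brute_f2_matrix(genotypes, groups):
    """Triple loop over sites x individual pairs, mirroring the f2 contract."""
    g = np.asarray(genotypes)
    labels = list(groups)
    uniq = sorted(set(labels))
    gidx = {name: k for k, name in enumerate(uniq)}
    counts = np.zeros((len(uniq), len(uniq)), dtype=np.int64)
    within = 0
    n_f2 = 0
    for j in range(g.shape[1]):
        col = g[:, j]
        called = 2 * int((col != -1).sum())
        alt = int(col[col != -1].sum())
        minor = min(alt, called - alt)
        if minor != 2 or called <= 4:
            continue
        n_f2 += 1
        dosage = col.copy()
        if alt > called - alt:
            dosage = np.where(col == -1, 0, 2 - col)
        else:
            dosage = np.where(col == -1, 0, col)
        carriers = [i for i in range(g.shape[0]) if dosage[i] > 0]
        if len(carriers) == 1:
            within += 1
        else:
            a, b = gidx[labels[carriers[0]]], gidx[labels[carriers[1]]]
            if a == b:
                counts[a, a] += 1
            else:
                counts[a, b] += 1
                counts[b, a] += 1
    return uniq, counts, within, n_f2
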