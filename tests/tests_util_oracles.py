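"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit pair loops, direct set
comparisons) kept separate from the package so they cannot share code with
the paths they verify.
"""

import numpy as np

MISSING = -1


def brute_force_sq_hamming(alleles):
    """Per-pair site loop: (h/c)^2 * L with pairwise missing exclusion."""
    n, L = alleles.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            h = c = 0
            for s in range(L):
                a, b = alleles[i, s], alleles[j, s]
                if a == MISSING or b == MISSING:
                    continue
                c += 1
                if a != b:
                    h += 1
            out[i, j] = (h / c) ** 2 * L
    return out


def brute_force_ehh(alleles, core, allele, y):
    """Fraction of carrier pairs identical at every SNP in [min(core,y), max(core,y)].

    Missing counts as a mismatch (a missing call is never identical to
    anything, itself included).
    """
    carriers = [i for i in range(alleles.shape[0]) if alleles[i, core] == allele]
    m = len(carriers)
    lo, hi = min(core, y), max(core, y)
    n_ident = 0
    for ai in range(m):
        for bi in range(ai + 1, m):
            a, b = alleles[carriers[ai]], alleles[carriers[bi]]
            same = True
            for s in range(lo, hi + 1):
                if a[s] == MISSING or b[s] == MISSING or a[s] != b[s]:
                    same = False
                    break
            if same:
                n_ident += 1
    return n_ident / (m * (m - 1) / 2)


def brute_force_weighted_ehh(alleles, core, allele, y, U_by_carrier):
    """Weighted pair-homozygosity via explicit haplotype-string grouping."""
    carriers = [i for i in range(alleles.shape[0]) if alleles[i, core] == allele]
    lo, hi = min(core, y), max(core, y)
    groups = {}
    for k, i in enumerate(carriers):
        seg = alleles[i, lo : hi + 1]
        if (seg == MISSING).any():
            key = ("miss", i)
        else:
            key = tuple(int(x) for x in seg)
        groups.setdefault(key, []).append(k)
    U = np.asarray([U_by_carrier[k] for k in range(len(carriers))], dtype=float)
    m = len(carriers)
    sum_w2 = sum(U[list(idx)].sum() ** 2 for idx in groups.values())
    sum_u2 = float((U**2).sum())
    denom = m * m - sum_u2
    return (sum_w2 - sum_u2) / denom if denom > 0 else 0.0


def brute_force_phs(alleles, genetic, x, allele_value):
    """Direct-summation pairwise haplotype sharing score at SNP x."""
    n, S = alleles.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = np.zeros((len(pairs), S))
    for p, (i, j) in enumerate(pairs):
        for s in range(S):
            if alleles[i, s] != alleles[j, s] or alleles[i, s] == MISSING:
                continue
            lo = s
            while lo > 0 and alleles[i, lo - 1] == alleles[j, lo - 1] != MISSING:
                lo -= 1
            hi = s
            while hi < S - 1 and alleles[i, hi + 1] == alleles[j, hi + 1] != MISSING:
                hi += 1
            d[p, s] = genetic[hi] - genetic[lo]
    z = np.zeros_like(d)
    for p in range(len(pairs)):
        sd = d[p].std(ddof=1)
        if sd > 0:
            z[p] = (d[p] - d[p].mean()) / sd
    carrier_pairs = [
        p for p, (i, j) in enumerate(pairs)
        if alleles[i, x] == allele_value and alleles[j, x] == allele_value
    ]
    if not carrier_pairs:
        return np.nan
    return z[carrier_pairs, x].mean() - z[:, x].mean()
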