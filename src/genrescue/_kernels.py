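"""Numba inner loops for the two per-year hot paths.

Both kernels are plain re-expressions of one-line numpy operations that
would otherwise materialize multi-megabyte temporaries every simulated year:
Mendelian allele picking (gather + random copy choice + write, fused) and
per-locus genotype tabulation.  Randomness enters only through pre-drawn
bit words from the caller's generator, so the reproducibility contract stays
with :mod:`numpy.random`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def mendel_pick(geno, parents, words, out, col):  # pragma: no cover - jitted
    """Fill ``out[:, :, col]`` with one random allele per parent per locus.

    ``words`` supplies >= ceil(k * L / 64) uint64 random words; bit ``i*L+l``
    selects which of parent ``i``'s two allele copies is transmitted at
    locus ``l``.
    """
    k = parents.size
    n_loci = geno.shape[1]
    for i in range(k):
        p = parents[i]
        base = i * n_loci
        for l in range(n_loci):
            idx = base + l
            bit = (words[idx >> 6] >> np.uint64(idx & 63)) & np.uint64(1)
            out[i, l, col] = geno[p, l, bit]


@njit(cache=True)
def genotype_counts(geno, start, stop):  # pragma: no cover - jitted
    """Per-locus 3x3 genotype-code counts over loci ``[start, stop)``.

    Returns an ``(stop - start, 9)`` int64 array indexed by
    ``3 * allele1 + allele2``.
    """
    n = geno.shape[0]
    width = stop - start
    cnt = np.zeros((width, 9), dtype=np.int64)
    for i in range(n):
        for l in range(width):
            code = 3 * geno[i, start + l, 0] + geno[i, start + l, 1]
            cnt[l, code] += 1
    return cnt
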