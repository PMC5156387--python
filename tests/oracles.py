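"""Independent brute-force oracles used to verify the implementation.

Everything here is written from first principles against definitions, not
against the library code paths it checks.
"""

from collections import Counter
from itertools import combinations, product

import numpy as np


def r2_from_table(h_a, h_b):
    """Haplotype r² from an explicit 2x2 contingency table.

    Returns None when either site is monomorphic.
    """
    counts = Counter(zip(h_a, h_b))
    n = len(h_a)
    p11 = counts[(1, 1)] / n
    p_a = (counts[(1, 1)] + counts[(1, 0)]) / n
    p_b = (counts[(1, 1)] + counts[(0, 1)]) / n
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        return None
    d = p11 - p_a * p_b
    return d * d / denom


def finemap_filter(panel, index_vid, population, half_window, min_maf, min_r2):
    """Three-rule fine-map filter: window, not-triallelic, MAF, r² to index."""
    rows = panel.pop_rows(population)
    index = panel.site(index_vid)
    h_index = panel.column(index_vid)[rows]
    members = {index_vid}
    for s in panel.sites:
        if s.vid == index_vid or s.chrom != index.chrom:
            continue
        if abs(s.pos - index.pos) > half_window:
            continue
        if len(s.alts) >= 2:
            continue
        h = panel.column(s.vid)[rows]
        f = h.mean()
        if min(f, 1 - f) < min_maf:
            continue
        r2 = r2_from_table(h, h_index)
        if r2 is not None and r2 >= min_r2:
            members.add(s.vid)
    return members


def min_set_cover_size(cover_sets, universe):
    """Smallest number of sets covering the universe, by exhaustive search."""
    items = list(cover_sets)
    for k in range(0, len(items) + 1):
        for combo in combinations(range(len(items)), k):
            covered = set()
            for i in combo:
                covered |= items[i]
            if covered >= universe:
                return k
    raise AssertionError("universe not coverable")


def covered_bp_bitmask(regions, chrom_len=100_000):
    """Total covered bp via an explicit boolean mask per chromosome."""
    masks = {}
    for r in regions:
        masks.setdefault(r.chrom, np.zeros(chrom_len, dtype=bool))
        masks[r.chrom][r.start : r.end] = True
    return sum(int(m.sum()) for m in masks.values())


def hmm_path_posterior(ref_h, obs, p_switch, eps):
    """Posterior state probabilities by exhaustive hidden-path enumeration.

    Transition from state i to j between adjacent sites has probability
    (1-q)·[i==j] + q/N; emission matches with 1-eps else eps.
    """
    ref_h = np.asarray(ref_h)
    n, s = ref_h.shape
    total = 0.0
    post = np.zeros((s, n))
    for path in product(range(n), repeat=s):
        w = 1.0 / n
        for j, state in enumerate(path):
            if j > 0:
                q = p_switch[j - 1]
                w *= (1 - q) * (path[j - 1] == state) + q / n
            w *= (1 - eps) if ref_h[state, j] == obs[j] else eps
        total += w
        for j, state in enumerate(path):
            post[j, state] += w
    return post / total
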