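"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — O(n^2) scans, base-resolution
bitmaps, combinatorial sums — and shares no code with the package paths it
validates.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_contact_pairs(complex_, residue_key, cutoff, include_hydrogens=False):
    """All (protein atom, DNA atom) pairs within cutoff, by exhaustive scan."""
    target = None
    for chain in complex_.chains:
        if chain.role != "protein":
            continue
        for res in chain.residues:
            if (res.chain_id, res.seq_number) == (residue_key[0], residue_key[1]):
                target = res
    assert target is not None
    pairs = []
    for pa in target.atoms:
        if pa.is_hydrogen and not include_hydrogens:
            continue
        for chain in complex_.chains:
            if chain.role != "dna":
                continue
            for dres in chain.residues:
                for da in dres.atoms:
                    if da.is_hydrogen and not include_hydrogens:
                        continue
                    d = math.dist(pa.coords, da.coords)
                    if d <= cutoff:
                        pairs.append((pa.name, da.name, dres.key, d))
    return pairs


def bitmap_cover(intervals, chrom, length):
    cover = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cover[iv.start : iv.end] = True
    return cover


def bitmap_runs(cover):
    """Maximal covered runs of a boolean bitmap as (start, end) half-open."""
    runs = []
    start = None
    for i, bit in enumerate(cover):
        if bit and start is None:
            start = i
        elif not bit and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(cover)))
    return runs


def bitmap_consensus(rep1, rep2, chrom, length):
    both = bitmap_cover(rep1, chrom, length) & bitmap_cover(rep2, chrom, length)
    return bitmap_runs(both)


def bitmap_overlaps(query, targets, chrom, length):
    """Whether each query interval shares >= 1 covered base with targets."""
    cover = bitmap_cover(targets, chrom, length)
    return [bool(cover[iv.start : iv.end].any()) for iv in query if iv.chrom == chrom]


def hypergeom_tail(k, n_a, n_b, universe):
    """P(X >= k) for X ~ Hypergeometric(universe, n_a, n_b), by direct summation."""
    denom = math.comb(universe, n_b)
    total = 0
    for i in range(k, min(n_a, n_b) + 1):
        if n_b - i <= universe - n_a:
            total += math.comb(n_a, i) * math.comb(universe - n_a, n_b - i)
    return total / denom


def naive_set_overlap(a, b):
    """Sorted-merge intersection cardinality of two iterables of strings."""
    xs, ys = sorted(set(a)), sorted(set(b))
    i = j = count = 0
    while i < len(xs) and j < len(ys):
        if xs[i] == ys[j]:
            count += 1
            i += 1
            j += 1
        elif xs[i] < ys[j]:
            i += 1
        else:
            j += 1
    return count


def naive_query_walk(rows, query_row, start):
    """Map alignment columns to query residue numbers by explicit walking."""
    mapping = {}
    resnum = start
    for col in range(len(rows[query_row])):
        if rows[query_row][col] in "-.":
            continue
        mapping[resnum] = col
        resnum += 1
    return mapping
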