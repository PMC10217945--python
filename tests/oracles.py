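"""Brute-force reference implementations used only to cross-check the package.

Everything here loops over plain dicts and lists, with no table indexing
tricks and no shared code with the implementation under test.
"""

from __future__ import annotations

import math

from cubkit.genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    SINGLE_CODON_AA,
    STOP_CODONS,
)


def rscu_oracle(codon_counts: dict[str, int]) -> dict[str, float]:
    """RSCU by direct looping over amino acids and codons."""
    out: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in SINGLE_CODON_AA:
            continue
        total = sum(codon_counts.get(c, 0) for c in codons)
        for c in codons:
            if total == 0:
                out[c] = float("nan")
            else:
                expected = total / len(codons)
                out[c] = codon_counts.get(c, 0) / expected
    return out


def enc_oracle(codon_counts: dict[str, int]) -> float:
    """Wright's ENC by direct looping; NaN when undefined."""
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for k, members in DEGENERACY_CLASSES.items():
        for aa in members:
            codons = AA_TO_CODONS[aa]
            n = sum(codon_counts.get(c, 0) for c in codons)
            if n < 2:
                continue
            s = 0.0
            for c in codons:
                p = codon_counts.get(c, 0) / n
                s += p * p
            f = (n * s - 1.0) / (n - 1.0)
            if f > 0:
                f_by_class[k].append(f)
    means = {}
    for k, vals in f_by_class.items():
        means[k] = sum(vals) / len(vals) if vals else None
    if means[2] is None or means[4] is None or means[6] is None:
        return float("nan")
    if means[3] is None:
        means[3] = (means[2] + means[4]) / 2.0
    enc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(enc, 61.0)


def ols_oracle(xs: list[float], ys: list[float]) -> tuple[float, float, float]:
    """Closed-form simple OLS slope, intercept and Pearson r."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    slope = sxy / sxx
    intercept = my - slope * mx
    r = sxy / math.sqrt(sxx * syy)
    return slope, intercept, r


def welch_oracle(xs: list[float], ys: list[float]) -> tuple[float, float]:
    """Welch t statistic and Satterthwaite df by direct formula."""
    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((v - mx) ** 2 for v in xs) / (nx - 1)
    vy = sum((v - my) ** 2 for v in ys) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def average_linkage_oracle(dist: list[list[float]]) -> list[float]:
    """Merge heights of average-linkage agglomeration, O(n^3), naive.

    Clusters are lists of original item indices; inter-cluster distance
    is the mean over all cross pairs of the original input matrix.
    """
    clusters: list[list[int]] = [[i] for i in range(len(dist))]
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = 0.0
                for a in clusters[i]:
                    for b in clusters[j]:
                        d += dist[a][b]
                d /= len(clusters[i]) * len(clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def positional_gc_oracle(codons: list[str]) -> tuple[float, float, float]:
    """Per-position GC fractions over sense codons by direct looping."""
    sense = [c for c in codons if c not in STOP_CODONS]
    out = []
    for pos in range(3):
        out.append(sum(1 for c in sense if c[pos] in "GC") / len(sense))
    return tuple(out)


def gc3s_oracle(codons: list[str]) -> float:
    syn = [
        c
        for c in codons
        if c not in STOP_CODONS and CODON_TO_AA[c] not in SINGLE_CODON_AA
    ]
    return sum(1 for c in syn if c[2] in "GC") / len(syn)
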