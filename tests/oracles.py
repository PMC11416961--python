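"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact 2x2 tests are
computed by exhaustive hypergeometric enumeration from first principles,
and interval/window logic by per-base membership sets.
"""

from __future__ import annotations

from math import comb

import numpy as np


def hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """P(top-left cell = a) for fixed margins, from binomial coefficients."""
    n = row1 + row2
    if not (max(0, col1 - row2) <= a <= min(row1, col1)):
        return 0.0
    return comb(row1, a) * comb(row2, col1 - a) / comb(n, col1)


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher P by the minimum-likelihood rule, full enumeration."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = hypergeom_pmf(x, row1, row2, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def fisher_one_sided_enum(table, direction: str = "greater") -> float:
    """One-sided Fisher P (tail of the top-left cell) by enumeration."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(row1, col1)
    if direction == "greater":
        xs = range(a, hi + 1)
    else:
        xs = range(lo, a + 1)
    return min(sum(hypergeom_pmf(x, row1, row2, col1) for x in xs), 1.0)


def randomization_mid_p(table, n_perm: int, rng: np.random.Generator) -> float:
    """Monte-Carlo fixed-margins randomization mid-P for positive association.

    Draws the top-left cell from the hypergeometric null and scores
    P(A > a_obs) + 0.5 * P(A = a_obs), the mid-P a continuous statistic
    approximates.
    """
    (a, b), (c, d) = table
    draws = rng.hypergeometric(a + b, c + d, a + c, size=n_perm)
    return float(np.mean(draws > a) + 0.5 * np.mean(draws == a))


# ---------------------------------------------------------------------------
# per-base genome oracles
# ---------------------------------------------------------------------------


def positions(iv) -> set[tuple[str, int]]:
    """Enumerated (chrom, base) membership set of an interval."""
    return {(iv.chrom, p) for p in range(iv.start, iv.end)}


def brute_overlaps(a, b) -> bool:
    return bool(positions(a) & positions(b))


def brute_classify(feature, genes, params):
    """Per-base reimplementation of the location-precedence rule."""
    from epiweave.intervals import promoter_of, tss_window

    fpos = positions(feature)
    body = sorted(
        g.gene_id for g in genes if fpos & positions(g.span)
    )
    if body:
        return "gene_body", body
    prom = sorted(
        g.gene_id for g in genes if fpos & positions(promoter_of(g, params))
    )
    if prom:
        return "promoter", prom
    window = sorted(
        g.gene_id
        for g in genes
        if fpos & positions(tss_window(g, params.gene_window_bp))
    )
    return "intergenic", window
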