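"""Quartet statistics: ABBA/BABA weights, Patterson's D, f4 and the F4 ratio.

All statistics are frequency-based.  Per site with derived-allele frequencies
p1, p2, p3, p4 over (P1, P2, P3, outgroup), the pattern weights are

    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)

and D = (Σ baba − Σ abba) / (Σ baba + Σ abba).  Note the sign convention:
here the numerator is BABA − ABBA so that **positive D means excess
derived-allele sharing between P1 and P3** (P1 is the putative hybrid
radiation, P3 the donor).  Durand et al. and Martin et al. write the opposite
orientation (ABBA − BABA with P2 as recipient); the window-scan module follows
that fd orientation and says so.

Significance comes from a weighted delete-one block jackknife over contiguous
site blocks within scaffolds, with |z| ≥ 3 flagged significant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, UndefinedStatisticError
from .genotype_io import FrequencyTable

Z_THRESHOLD = 3.0
DEFAULT_BLOCK_SIZE = 500


@dataclass
class QuartetResult:
    """Patterson's D with block-jackknife uncertainty."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    d: float
    abba_sum: float
    baba_sum: float
    n_sites: int
    jackknife_se: float
    z: float

    @property
    def significant(self) -> bool:
        return abs(self.z) >= Z_THRESHOLD


@dataclass
class F4RatioResult:
    """Ancestry proportion alpha = f4(A,O;X,C) / f4(A,O;B,C)."""

    a: str
    b: str
    c: str
    outgroup: str
    x: str
    alpha: float
    numerator_f4: float
    denominator_f4: float
    jackknife_se: float
    n_sites: int


def abba_baba_weights(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA weights from derived-allele frequencies.

    A site with frequencies (0, 0.5, 1, 0) counts as half an ABBA site.
    Sites with any frequency missing get NaN weights (callers drop them).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def block_jackknife(
    numerators: np.ndarray,
    denominators: np.ndarray,
    block_sizes: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Ratio-of-sums estimate with weighted delete-one jackknife SE and z.

    Per-block numerator/denominator sums define the estimate
    Σnum / Σden; leave-one-block-out pseudovalues weighted by block size give
    the standard error (blocks of equal size reduce to the textbook delete-one
    jackknife).  Returns ``(estimate, se, z)``.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    g = len(num)
    if g < 2:
        raise UndefinedStatisticError(
            "block jackknife needs at least 2 blocks; use a smaller block_size"
        )
    if block_sizes is None:
        m = np.ones(g)
    else:
        m = np.asarray(block_sizes, dtype=float)
    s_num, s_den = num.sum(), den.sum()
    if s_den == 0:
        raise UndefinedStatisticError("denominator sums to zero")
    theta = s_num / s_den
    loo_den = s_den - den
    if np.any(loo_den == 0):
        raise UndefinedStatisticError("a leave-one-out denominator is zero")
    theta_loo = (s_num - num) / loo_den

    n = m.sum()
    h = n / m
    theta_dot = g * theta - np.sum((1.0 - m / n) * theta_loo)
    pseudo = h * theta - (h - 1.0) * theta_loo
    var = np.sum((pseudo - theta_dot) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    z = theta / se if se > 0 else (0.0 if theta == 0 else np.inf * np.sign(theta))
    return float(theta), se, float(z)


def _complete_case(freqs: FrequencyTable, groups: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Column stack of the groups' frequencies and the complete-case mask."""
    cols = np.column_stack([freqs.freq_of(g) for g in groups])
    ok = ~np.isnan(cols).any(axis=1)
    return cols, ok


def _site_blocks(scaffolds: np.ndarray, block_size: int) -> np.ndarray:
    """Assign retained sites to contiguous blocks of block_size within scaffolds."""
    block = np.empty(len(scaffolds), dtype=int)
    next_id = 0
    i = 0
    while i < len(scaffolds):
        j = i
        while j < len(scaffolds) and scaffolds[j] == scaffolds[i]:
            j += 1
        for k in range(i, j, block_size):
            block[k : min(k + block_size, j)] = next_id
            next_id += 1
        i = j
    return block


def d_statistic(
    freqs: FrequencyTable,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> QuartetResult:
    """Patterson's D over (P1, P2, P3, outgroup) with block-jackknife z.

    D > 0 indicates excess derived-allele sharing between P1 and P3.
    Sites with any of the four group frequencies missing are skipped.
    """
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")
    cols, ok = _complete_case(freqs, [p1, p2, p3, outgroup])
    if not ok.any():
        raise UndefinedStatisticError("no sites with all four groups called")
    cols = cols[ok]
    abba, baba = abba_baba_weights(cols[:, 0], cols[:, 1], cols[:, 2], cols[:, 3])
    total = abba.sum() + baba.sum()
    if total == 0:
        raise UndefinedStatisticError("no ABBA/BABA-informative sites (all weights zero)")

    scaffolds = freqs.sites["scaffold"].to_numpy()[ok]
    block = _site_blocks(scaffolds, block_size)
    nb = block.max() + 1
    num = np.bincount(block, weights=baba - abba, minlength=nb)
    den = np.bincount(block, weights=baba + abba, minlength=nb)
    sizes = np.bincount(block, minlength=nb).astype(float)
    nonempty = den != 0
    d, se, z = block_jackknife(num[nonempty], den[nonempty], sizes[nonempty])
    return QuartetResult(
        p1=p1, p2=p2, p3=p3, outgroup=outgroup,
        d=d, abba_sum=float(abba.sum()), baba_sum=float(baba.sum()),
        n_sites=int(ok.sum()), jackknife_se=se, z=z,
    )


def f4(freqs: FrequencyTable, a: str, b: str, c: str, d: str) -> float:
    """f4(A,B;C,D): mean over complete sites of (pA − pB)(pC − pD)."""
    cols, ok = _complete_case(freqs, [a, b, c, d])
    if not ok.any():
        raise UndefinedStatisticError("no sites with all four groups called")
    cols = cols[ok]
    return float(np.mean((cols[:, 0] - cols[:, 1]) * (cols[:, 2] - cols[:, 3])))


def f4_ratio(
    freqs: FrequencyTable,
    a: str,
    b: str,
    c: str,
    outgroup: str,
    x: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> F4RatioResult:
    """F4-ratio ancestry proportion of X from the B lineage.

    For the genealogy (((A,B)C)O) and hybrid X with ancestry alpha from B and
    1 − alpha from C,

        alpha = f4(A,O; X,C) / f4(A,O; B,C)

    The standard error of the ratio comes from the weighted block jackknife
    over contiguous site blocks.
    """
    cols, ok = _complete_case(freqs, [a, b, c, outgroup, x])
    if not ok.any():
        raise UndefinedStatisticError("no sites with all five groups called")
    pa, pb, pc, po, px = (cols[ok, j] for j in range(5))
    num_site = (pa - po) * (px - pc)
    den_site = (pa - po) * (pb - pc)

    scaffolds = freqs.sites["scaffold"].to_numpy()[ok]
    block = _site_blocks(scaffolds, block_size)
    nb = block.max() + 1
    num = np.bincount(block, weights=num_site, minlength=nb)
    den = np.bincount(block, weights=den_site, minlength=nb)
    sizes = np.bincount(block, minlength=nb).astype(float)
    if abs(den.sum()) < 1e-12:
        raise UndefinedStatisticError("f4 denominator is ~0; A/B/C/O are uninformative")
    alpha, se, _ = block_jackknife(num, den, sizes)
    n = int(ok.sum())
    return F4RatioResult(
        a=a, b=b, c=c, outgroup=outgroup, x=x,
        alpha=alpha,
        numerator_f4=float(num.sum() / n),
        denominator_f4=float(den.sum() / n),
        jackknife_se=se,
        n_sites=n,
    )


def f4_ratio_sweep(
    freqs: FrequencyTable,
    a_candidates: list[str],
    b: str,
    c: str,
    outgroup: str,
    x: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> list[F4RatioResult]:
    """Try each candidate reference population A; return results sorted by
    jackknife SE (smallest first), mirroring the practice of keeping the
    population combination with the lowest standard deviation."""
    results = []
    for a in a_candidates:
        try:
            results.append(f4_ratio(freqs, a, b, c, outgroup, x, block_size))
        except UndefinedStatisticError:
            continue
    if not results:
        raise UndefinedStatisticError("no candidate A population gave a defined ratio")
    return sorted(results, key=lambda r: r.jackknife_se)
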