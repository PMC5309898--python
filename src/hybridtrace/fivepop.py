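"""Five-population directional gene-flow test (partitioned D statistics).

Works on haploidized single individuals over the topology
((P1,P2),(P3a,P3b)),O.  Per site without missing data, each ingroup allele is
coded derived ('B') when it differs from the outgroup allele, ancestral ('A')
otherwise, and the site is classified into one of the eight patterns

    ABBAA, BABAA, ABABA, BAABA, ABBBA, BABBA, BBABA, BBBAA

(the fifth letter, the outgroup, is always 'A').  Four partitioned D
statistics summarise the pattern imbalances:

    D1  = (BABAA − ABBAA) / (BABAA + ABBAA)     P1 vs P2 sharing with P3a only
    D2  = (BAABA − ABABA) / (BAABA + ABABA)     P1 vs P2 sharing with P3b only
    D12 = (BABBA − ABBBA) / (BABBA + ABBBA)     P1 vs P2 sharing with both P3
    D3  = (BBBAA − BBABA) / (BBBAA + BBABA)     P3a vs P3b sharing with P1+P2

Gene flow from the P3 clade into P1 inflates D12 but not D3 (the donor's
sister shares the introgressed derived alleles); gene flow from P1 into P3a
inflates D3 but not D12 (ancestrally shared P1/P2 alleles reach only P3a).
D1/D2 are completed per the Eaton & Ree partitioned-D orientation; the
definitions are isolated in :func:`partitioned_d` so the mapping can be
revised in one place.

z-scores come from 100 bootstrap replicates (sites resampled with
replacement); |z| ≥ 3 is called significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, UndefinedStatisticError
from .genotype_io import MISSING, GenotypeMatrix

PATTERN_NAMES = ("ABBAA", "BABAA", "ABABA", "BAABA", "ABBBA", "BABBA", "BBABA", "BBBAA")

# 4-bit code (P1,P2,P3a,P3b derived flags, MSB = P1) -> pattern index
_CODE_TO_PATTERN = {6: 0, 10: 1, 5: 2, 9: 3, 7: 4, 11: 5, 13: 6, 14: 7}

DIRECTION_P3_TO_P1 = "P3->P1"
DIRECTION_P1_TO_P3A = "P1->P3a"
DIRECTION_P1_TO_P3B = "P1->P3b"
DIRECTION_AMBIGUOUS = "ambiguous"
DIRECTION_NONE = "none"


@dataclass
class PatternCounts8:
    """Counts of the eight five-taxon site patterns.

    ``n_sites_used`` counts only sites matching one of the eight patterns;
    ``n_usable`` counts every site without missing data (the bootstrap
    resamples over those).
    """

    counts: np.ndarray  # length 8, order PATTERN_NAMES
    n_usable: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (8,) or (self.counts < 0).any():
            raise ConfigurationError("need 8 non-negative pattern counts")

    @property
    def n_sites_used(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, name: str) -> int:
        return int(self.counts[PATTERN_NAMES.index(name)])

    def as_dict(self) -> dict[str, int]:
        return {n: int(c) for n, c in zip(PATTERN_NAMES, self.counts)}


@dataclass
class FivePopResult:
    """Partitioned D statistics with bootstrap z-scores and a direction call."""

    counts: PatternCounts8
    d1: float
    d2: float
    d12: float
    d3: float
    z1: float = np.nan
    z2: float = np.nan
    z12: float = np.nan
    z3: float = np.nan
    direction_call: str = DIRECTION_NONE

    def d_values(self) -> dict[str, float]:
        return {"D1": self.d1, "D2": self.d2, "D12": self.d12, "D3": self.d3}

    def z_values(self) -> dict[str, float]:
        return {"z1": self.z1, "z2": self.z2, "z12": self.z12, "z3": self.z3}


def haploidize(gm: GenotypeMatrix, sample: str, seed: int | np.random.Generator) -> np.ndarray:
    """One allele per site for one diploid: 0 = ref, 1 = alt, −1 = missing.

    Homozygous sites give their allele deterministically; at heterozygous
    sites one allele is chosen uniformly at random from a seeded generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dos = gm.calls[:, gm.sample_index(sample)]
    out = np.full(gm.n_sites, MISSING, dtype=np.int8)
    out[dos == 0] = 0
    out[dos == 2] = 1
    het = dos == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def _classify(h1, h2, h3a, h3b, ho) -> tuple[np.ndarray, int]:
    """Pattern index per usable site (8 = none-of-the-eight) and usable count."""
    stack = np.column_stack([h1, h2, h3a, h3b, ho])
    usable = (stack != MISSING).all(axis=1)
    sub = stack[usable]
    derived = (sub[:, :4] != sub[:, 4:5]).astype(np.int8)
    code = derived[:, 0] * 8 + derived[:, 1] * 4 + derived[:, 2] * 2 + derived[:, 3]
    lut = np.full(16, 8, dtype=np.int8)
    for c, p in _CODE_TO_PATTERN.items():
        lut[c] = p
    return lut[code], int(usable.sum())


def count_patterns(h1, h2, h3a, h3b, ho) -> PatternCounts8:
    """Count the eight patterns over sites without missing data.

    Sites matching none of the eight (singletons, invariant, all-derived)
    are usable but uncounted.
    """
    cls, n_usable = _classify(h1, h2, h3a, h3b, ho)
    if n_usable == 0:
        raise UndefinedStatisticError("no sites without missing data across the five sequences")
    counts = np.bincount(cls, minlength=9)[:8]
    return PatternCounts8(counts=counts, n_usable=n_usable)


def _safe_ratio(x: float, y: float) -> float:
    return (x - y) / (x + y) if (x + y) != 0 else np.nan


def partitioned_d(counts: PatternCounts8) -> FivePopResult:
    """The four partitioned D statistics from the eight pattern counts.

    Statistics whose count pair sums to zero are reported NaN (undefined).
    """
    c = counts.as_dict()
    return FivePopResult(
        counts=counts,
        d1=_safe_ratio(c["BABAA"], c["ABBAA"]),
        d2=_safe_ratio(c["BAABA"], c["ABABA"]),
        d12=_safe_ratio(c["BABBA"], c["ABBBA"]),
        d3=_safe_ratio(c["BBBAA"], c["BBABA"]),
    )


def bootstrap_fivepop(
    h1, h2, h3a, h3b, ho,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
    z_threshold: float = 3.0,
) -> FivePopResult:
    """Partitioned D with bootstrap z-scores and a direction call.

    Sites (all usable sites, pattern-matching or not) are resampled with
    replacement ``n_boot`` times; z = observed D / s.d. of the bootstrap D
    values.  A zero bootstrap s.d. with nonzero D yields an infinite z with a
    warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cls, n_usable = _classify(h1, h2, h3a, h3b, ho)
    if n_usable == 0:
        raise UndefinedStatisticError("no usable sites")
    cat_counts = np.bincount(cls, minlength=9)
    observed = partitioned_d(PatternCounts8(counts=cat_counts[:8], n_usable=n_usable))

    probs = cat_counts / n_usable
    boot = rng.multinomial(n_usable, probs, size=n_boot).astype(float)
    pair = lambda i, j: _ratio_vec(boot[:, i], boot[:, j])
    d1b = pair(PATTERN_NAMES.index("BABAA"), PATTERN_NAMES.index("ABBAA"))
    d2b = pair(PATTERN_NAMES.index("BAABA"), PATTERN_NAMES.index("ABABA"))
    d12b = pair(PATTERN_NAMES.index("BABBA"), PATTERN_NAMES.index("ABBBA"))
    d3b = pair(PATTERN_NAMES.index("BBBAA"), PATTERN_NAMES.index("BBABA"))

    zs = []
    for d_obs, db in zip(
        (observed.d1, observed.d2, observed.d12, observed.d3), (d1b, d2b, d12b, d3b)
    ):
        sd = np.nanstd(db, ddof=1)
        if np.isnan(d_obs):
            zs.append(np.nan)
        elif sd == 0:
            if d_obs == 0:
                zs.append(0.0)
            else:
                warnings.warn("bootstrap s.d. is zero with nonzero D; z reported infinite", stacklevel=2)
                zs.append(np.inf * np.sign(d_obs))
        else:
            zs.append(float(d_obs / sd))

    result = FivePopResult(
        counts=observed.counts,
        d1=observed.d1, d2=observed.d2, d12=observed.d12, d3=observed.d3,
        z1=zs[0], z2=zs[1], z12=zs[2], z3=zs[3],
    )
    result.direction_call = infer_direction(result, z_threshold)
    return result


def _ratio_vec(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    tot = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot != 0, (x - y) / tot, np.nan)


def infer_direction(result: FivePopResult, z_threshold: float = 3.0) -> str:
    """Direction call from the D12 / D3 decision table.

    Significant positive D12 with non-significant D3: gene flow from the P3
    clade into P1.  Significant positive (negative) D3 with non-significant
    D12: gene flow from P1 into P3a (P3b).  Both significant: ambiguous;
    neither: none.  A significant negative D12 (sharing with P2 rather than
    P1, outside the tested directions) is reported ambiguous.
    """
    sig12 = np.isfinite(result.z12) and abs(result.z12) >= z_threshold
    sig3 = np.isfinite(result.z3) and abs(result.z3) >= z_threshold
    if sig12 and sig3:
        return DIRECTION_AMBIGUOUS
    if sig12:
        return DIRECTION_P3_TO_P1 if result.d12 > 0 else DIRECTION_AMBIGUOUS
    if sig3:
        return DIRECTION_P1_TO_P3A if result.d3 > 0 else DIRECTION_P1_TO_P3B
    return DIRECTION_NONE


def run_fivepop_panel(
    gm: GenotypeMatrix,
    p1_samples: list[str],
    p2_sample: str,
    p3a_sample: str,
    p3b_sample: str,
    outgroup_sample: str,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[list[FivePopResult], dict[str, float]]:
    """Run the test once per P1 individual; report results plus mean D values.

    Heterozygote haploidization is re-drawn independently for every tested
    combination from per-run substreams of the given seed.
    """
    if not p1_samples:
        raise ConfigurationError("need at least one P1 sample")
    root = np.random.SeedSequence(seed)
    results = []
    for p1, ss in zip(p1_samples, root.spawn(len(p1_samples))):
        rng = np.random.default_rng(ss)
        haps = [haploidize(gm, s, rng) for s in (p1, p2_sample, p3a_sample, p3b_sample, outgroup_sample)]
        results.append(bootstrap_fivepop(*haps, n_boot=n_boot, seed=rng))
    mean = {
        k: float(np.nanmean([r.d_values()[k] for r in results]))
        for k in ("D1", "D2", "D12", "D3")
    }
    return results, mean
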