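"""Sorting of ancestral alleles: per-SNP FST, outliers, ancestry categories.

The analysis asks whether SNPs that were divergently fixed between the two
parental lineages of a hybrid swarm are over-represented among the most
differentiated SNPs of the daughter radiation — the signature expected if
Bateson–Dobzhansky–Muller-like incompatibilities between parental alleles
drove their sorting into different daughter species.

Steps:

1. per-SNP multi-population Weir–Cockerham (1984) θ among the radiation
   species (:func:`global_fst`);
2. one-tailed high-FST outlier flags from a simulated finite-island null
   matched on heterozygosity bins, or an empirical top-quantile fallback
   (:func:`flag_outliers`);
3. ancestry categories of each radiation-polymorphic SNP against the two
   parental lineages (:func:`classify_categories`): (1) only one radiation
   allele observed in the parental taxa together, (2) both alleles in the
   major parental lineage, (3) major lineage monomorphic but minor lineage
   polymorphic for the second allele, (4) the two lineages fixed for
   alternative alleles;
4. a frequency-matched control set (category 5): weighted parental frequency
   w_major·pC + w_minor·pN with weights 0.84/0.16 and a weighted minor-allele
   frequency window of 14–18 %, excluding divergently fixed sites
   (:func:`select_control_set`);
5. two-sided Fisher's exact enrichment of outliers per category against the
   control set (:func:`enrichment`), a weighting robustness sweep over minor
   weights 0.10–0.30, and a fixation check in control species pairs outside
   the radiation (:func:`control_fixation_test`).

Categories 1–4 are disjoint; an optional nested view treats category 4 as a
subset of category 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedStatisticError
from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

CONTROL_LABEL = "5-control"


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-SNP Weir–Cockerham components and θ across populations."""

    theta: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    heterozygosity: np.ndarray  # 2·p̄(1−p̄), the binning variable for the null

    @property
    def overall_theta(self) -> float:
        """Multi-locus ratio-of-sums θ (Σa / Σ(a+b+c))."""
        ok = np.isfinite(self.a)
        denom = (self.a + self.b + self.c)[ok].sum()
        if denom == 0:
            raise UndefinedStatisticError("all sites monomorphic; overall FST undefined")
        return float(self.a[ok].sum() / denom)


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir–Cockerham (1984) a, b, c variance components per site.

    ``n`` called diploids, ``p`` alternate-allele frequency and ``h`` observed
    heterozygote proportion, each (sites × populations) with NaN/0 where a
    population has no calls.  Populations with no calls at a site drop out of
    that site's estimate.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    present = n > 0
    r = present.sum(axis=1).astype(float)
    n_sum = np.where(present, n, 0).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_sum / r
        p_bar = np.where(present, n * p, 0).sum(axis=1) / n_sum
        h_bar = np.where(present, n * h, 0).sum(axis=1) / n_sum
        s2 = np.where(present, n * (p - p_bar[:, None]) ** 2, 0).sum(axis=1) / (
            (r - 1.0) * n_bar
        )
        n_c = (n_sum - np.where(present, n**2, 0).sum(axis=1) / n_sum) / (r - 1.0)

        pq = p_bar * (1.0 - p_bar)
        inner = pq - (r - 1.0) / r * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (inner - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0

    bad = (r < 2) | (n_bar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c, 2.0 * p_bar * (1.0 - p_bar)


def _pop_summaries(gm: GenotypeMatrix, sample_sets: list[list[int]]):
    """(n, p, h) arrays (sites × populations) from dosage columns."""
    n_sites = gm.n_sites
    k = len(sample_sets)
    n = np.zeros((n_sites, k))
    p = np.zeros((n_sites, k))
    h = np.zeros((n_sites, k))
    for j, cols in enumerate(sample_sets):
        sub = gm.calls[:, cols]
        called = sub != MISSING
        cnt = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pj = np.where(called, sub, 0).sum(axis=1) / (2.0 * cnt)
            hj = ((sub == 1).sum(axis=1)) / cnt
        n[:, j] = cnt
        p[:, j] = np.where(cnt > 0, pj, 0.0)
        h[:, j] = np.where(cnt > 0, hj, 0.0)
    return n, p, h


def global_fst(gm: GenotypeMatrix, popmap: PopulationMap, species: list[str]) -> FstResult:
    """Per-SNP Weir–Cockerham θ across the given species.

    Negative estimates are retained (not clamped); sites monomorphic across
    all species have θ = NaN.
    """
    if len(species) < 2:
        raise ConfigurationError("need at least two species for FST")
    sets = [[gm.sample_index(s) for s in popmap.samples_of(g)] for g in species]
    n, p, h = _pop_summaries(gm, sets)
    a, b, c, het = _wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b + c != 0, a / (a + b + c), np.nan)
    return FstResult(theta=theta, a=a, b=b, c=c, heterozygosity=het)


# ---------------------------------------------------------------------------
# Outlier flagging
# ---------------------------------------------------------------------------

@dataclass
class IslandNullConfig:
    """Finite-island null for high-FST outlier detection.

    ``f_island`` is the Balding–Nichols drift parameter of the simulated
    demes; when None it is matched to the data's multi-locus θ by the method
    of moments (E[θ̂] ≈ F under the island model).
    """

    n_demes: int = 6
    n_per_deme: int = 10
    f_island: float | None = None
    n_sim: int = 20_000
    n_bins: int = 10
    min_bin_null: int = 200
    seed: int = 0


def _simulate_island_null(cfg: IslandNullConfig, rng: np.random.Generator):
    """Null θ and heterozygosity from a neutral finite-island simulation."""
    f = cfg.f_island
    p_anc = rng.uniform(0.01, 0.99, size=cfg.n_sim)
    ab = (1.0 - f) / f
    q = rng.beta(p_anc[:, None] * ab, (1.0 - p_anc[:, None]) * ab,
                 size=(cfg.n_sim, cfg.n_demes))
    # HWE genotype counts per deme
    pv = np.stack([q**2, 2 * q * (1 - q), (1 - q) ** 2], axis=-1)
    counts = rng.multinomial(cfg.n_per_deme, pv)
    n = np.full((cfg.n_sim, cfg.n_demes), float(cfg.n_per_deme))
    p_hat = (2 * counts[..., 0] + counts[..., 1]) / (2.0 * cfg.n_per_deme)
    h_hat = counts[..., 1] / cfg.n_per_deme
    a, b, c, het = _wc_components(n, p_hat, h_hat)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b + c != 0, a / (a + b + c), np.nan)
    ok = np.isfinite(theta)
    return theta[ok], het[ok]


def flag_outliers(
    fst: FstResult,
    null_config: IslandNullConfig | None = None,
    p_threshold: float = 0.05,
    method: str = "simulation",
) -> tuple[np.ndarray, np.ndarray]:
    """One-tailed high-FST P per SNP and the outlier flags (P < threshold).

    ``method='simulation'`` compares each SNP's θ with neutral island-model
    θ values in the same heterozygosity bin; ``method='quantile'`` flags the
    empirical top ``p_threshold`` fraction without a simulation.  Returns
    ``(outlier_bool, p_values)``; sites with undefined θ get P = NaN and are
    never flagged.
    """
    theta = fst.theta
    ok = np.isfinite(theta)
    p_vals = np.full(theta.shape, np.nan)

    if method == "quantile":
        obs = theta[ok]
        order = obs.argsort()
        ranks = np.empty_like(order, dtype=float)
        # fraction of SNPs with theta >= this SNP's theta (ties share the high rank)
        ranks[order] = 1.0 - np.searchsorted(obs[order], obs[order], side="left") / len(obs)
        p_vals[ok] = ranks
    elif method == "simulation":
        cfg = null_config or IslandNullConfig()
        if cfg.f_island is None:
            from dataclasses import replace

            cfg = replace(cfg, f_island=float(np.clip(fst.overall_theta, 1e-4, 0.99)))
        rng = np.random.default_rng(cfg.seed)
        null_theta, null_het = _simulate_island_null(cfg, rng)
        # heterozygosity bins with ~equal null occupancy
        n_bins = max(1, min(cfg.n_bins, len(null_theta) // cfg.min_bin_null))
        edges = np.quantile(null_het, np.linspace(0, 1, n_bins + 1)[1:-1])
        null_bin = np.digitize(null_het, edges)
        obs_bin = np.digitize(fst.heterozygosity[ok], edges)
        obs_theta = theta[ok]
        p_ok = np.empty(obs_theta.shape)
        for b in range(n_bins):
            nt = np.sort(null_theta[null_bin == b])
            sel = obs_bin == b
            if len(nt) == 0:
                warnings.warn(f"empty null heterozygosity bin {b}; merging with pooled null", stacklevel=2)
                nt = np.sort(null_theta)
            n_ge = len(nt) - np.searchsorted(nt, obs_theta[sel], side="left")
            p_ok[sel] = (1.0 + n_ge) / (1.0 + len(nt))
        p_vals[ok] = p_ok
    else:
        raise ConfigurationError(f"unknown outlier method {method!r}")

    outlier = np.where(np.isfinite(p_vals), p_vals < p_threshold, False)
    return outlier.astype(bool), p_vals


# ---------------------------------------------------------------------------
# Ancestry categories
# ---------------------------------------------------------------------------

def _allele_presence(gm: GenotypeMatrix, cols: list[int]):
    """Per site: ref-present, alt-present and called count within columns."""
    sub = gm.calls[:, cols]
    called = sub != MISSING
    n = called.sum(axis=1)
    alt_present = (np.where(called, sub, 0) > 0).any(axis=1)
    ref_present = (np.where(called, sub, 2) < 2).any(axis=1)
    return ref_present, alt_present, n


def classify_categories(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    lv_groups: list[str],
    congolese: str,
    upper_nile: str,
    min_parental_individuals: int = 3,
    nested: bool = False,
) -> pd.DataFrame:
    """Assign each radiation-polymorphic SNP to ancestry category 1–4.

    Sites monomorphic within the radiation (LV) species, or with fewer than
    ``min_parental_individuals`` called in either parental lineage, are
    'excluded'.  With ``nested=True`` an extra boolean column marks the
    category-3-or-4 nested view (category 4 as subset of 3).
    """
    lv_cols = [gm.sample_index(s) for g in lv_groups for s in popmap.samples_of(g)]
    congo_cols = [gm.sample_index(s) for s in popmap.samples_of(congolese)]
    nile_cols = [gm.sample_index(s) for s in popmap.samples_of(upper_nile)]

    lv_ref, lv_alt, _ = _allele_presence(gm, lv_cols)
    c_ref, c_alt, c_n = _allele_presence(gm, congo_cols)
    n_ref, n_alt, n_n = _allele_presence(gm, nile_cols)

    lv_poly = lv_ref & lv_alt
    enough = (c_n >= min_parental_individuals) & (n_n >= min_parental_individuals)
    congo_poly = c_ref & c_alt
    nile_poly = n_ref & n_alt
    congo_allele = np.where(c_alt, 1, 0)  # defined when congo monomorphic
    nile_allele = np.where(n_alt, 1, 0)

    category = np.full(gm.n_sites, "excluded", dtype=object)
    usable = lv_poly & enough
    category[usable & congo_poly] = "2"
    category[usable & ~congo_poly & nile_poly] = "3"
    div_fixed = usable & ~congo_poly & ~nile_poly & (congo_allele != nile_allele)
    category[div_fixed] = "4"
    category[usable & ~congo_poly & ~nile_poly & (congo_allele == nile_allele)] = "1"

    congo_freq = _group_freq(gm, congo_cols)
    nile_freq = _group_freq(gm, nile_cols)
    df = pd.DataFrame(
        {
            "category": category,
            "congolese_freq": congo_freq,
            "upper_nile_freq": nile_freq,
            "n_congolese": c_n,
            "n_upper_nile": n_n,
        }
    )
    if nested:
        df["category_3_nested"] = np.isin(category, ("3", "4"))
    return df


def _group_freq(gm: GenotypeMatrix, cols: list[int]) -> np.ndarray:
    sub = gm.calls[:, cols]
    called = sub != MISSING
    cnt = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(called, sub, 0).sum(axis=1) / (2.0 * cnt)
    return np.where(cnt > 0, f, np.nan)


def select_control_set(
    congolese_freq: np.ndarray,
    upper_nile_freq: np.ndarray,
    divergently_fixed: np.ndarray,
    w_congo: float = 0.84,
    w_nile: float = 0.16,
    window: tuple[float, float] = (0.14, 0.18),
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-matched control SNPs (category 5).

    Weighted frequency f = pC·w_congo + pN·w_nile; the weighted minor-allele
    frequency min(f, 1−f) must fall inside ``window`` (inclusive) and the
    site must not be divergently fixed between the parental lineages.
    Returns ``(control_flags, weighted_maf)``.
    """
    if abs(w_congo + w_nile - 1.0) > 1e-9:
        raise ConfigurationError("parental weights must sum to 1")
    pc = np.asarray(congolese_freq, dtype=float)
    pn = np.asarray(upper_nile_freq, dtype=float)
    f = pc * w_congo + pn * w_nile
    wmaf = np.minimum(f, 1.0 - f)
    flags = (
        np.isfinite(wmaf)
        & (wmaf >= window[0])
        & (wmaf <= window[1])
        & ~np.asarray(divergently_fixed, dtype=bool)
    )
    return flags, wmaf


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Outlier proportion and Fisher p per ancestry category vs a reference."""

    table: pd.DataFrame
    reference: str


def enrichment(
    category_masks: dict[str, np.ndarray],
    outliers: np.ndarray,
    reference: str = CONTROL_LABEL,
) -> EnrichmentResult:
    """Outlier proportions per category with two-sided Fisher tests.

    Each category's 2×2 table (outlier yes/no × category vs reference) is
    tested against the designated reference category.  Empty categories are
    skipped with a warning.
    """
    if reference not in category_masks:
        raise ConfigurationError(f"reference category {reference!r} not among masks")
    outliers = np.asarray(outliers, dtype=bool)
    ref_mask = np.asarray(category_masks[reference], dtype=bool)
    ref_out = int((outliers & ref_mask).sum())
    ref_n = int(ref_mask.sum())
    if ref_n == 0:
        raise UndefinedStatisticError(f"reference category {reference!r} is empty")

    rows = []
    for name, mask in category_masks.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"category {name!r} has no SNPs; skipped", stacklevel=2)
            continue
        n_out = int((outliers & mask).sum())
        if name == reference:
            p = np.nan
        else:
            _, p = stats.fisher_exact(
                [[n_out, n - n_out], [ref_out, ref_n - ref_out]], alternative="two-sided"
            )
        rows.append((name, n, n_out, n_out / n, p))
    table = pd.DataFrame(
        rows, columns=["category", "n_snps", "n_outliers", "outlier_proportion", "p_vs_reference"]
    )
    return EnrichmentResult(table=table, reference=reference)


def weight_robustness(
    category_masks: dict[str, np.ndarray],
    congolese_freq: np.ndarray,
    upper_nile_freq: np.ndarray,
    divergently_fixed: np.ndarray,
    outliers: np.ndarray,
    nile_weights: np.ndarray | None = None,
    window: tuple[float, float] = (0.14, 0.18),
    reference: str = CONTROL_LABEL,
) -> dict[float, EnrichmentResult]:
    """Re-run control-set selection and enrichment across minor-lineage weights.

    Default weights sweep 0.10–0.30 in steps of 0.05; weight 0.16 reproduces
    the default analysis exactly.
    """
    if nile_weights is None:
        nile_weights = np.arange(0.10, 0.3001, 0.05)
    out: dict[float, EnrichmentResult] = {}
    for w in nile_weights:
        w = float(round(w, 6))
        flags, _ = select_control_set(
            congolese_freq, upper_nile_freq, divergently_fixed,
            w_congo=1.0 - w, w_nile=w, window=window,
        )
        masks = {k: v for k, v in category_masks.items() if k != reference}
        masks[reference] = flags
        out[w] = enrichment(masks, outliers, reference)
    return out


# ---------------------------------------------------------------------------
# Control-species fixation check
# ---------------------------------------------------------------------------

def _fixation_state(gm: GenotypeMatrix, cols: list[int]):
    """Per site: (qualifying-called count, fixed allele 0/1 or −1 if polymorphic)."""
    sub = gm.calls[:, cols]
    called = sub != MISSING
    n = called.sum(axis=1)
    any_alt = (np.where(called, sub, 0) > 0).any(axis=1)
    any_ref = (np.where(called, sub, 2) < 2).any(axis=1)
    state = np.full(gm.n_sites, -1, dtype=np.int8)
    state[any_alt & ~any_ref] = 1
    state[any_ref & ~any_alt] = 0
    return n, state


def control_fixation_test(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    control_pairs: list[tuple[str, str]],
    cat4_mask: np.ndarray,
    outliers: np.ndarray,
    min_genotypes: int = 3,
) -> pd.DataFrame:
    """Fisher test of outlier × differential fixation in control species pairs.

    For each pair of species outside the radiation, restricted to the
    divergently fixed (category-4) sites with at least ``min_genotypes``
    called in both species: are radiation FST outliers more often fixed for
    alternative alleles between the control species than non-outliers?
    Pairs with no qualifying site are skipped with a warning; a pair with no
    fixed differences reports p = 1 with a warning.
    """
    cat4_mask = np.asarray(cat4_mask, dtype=bool)
    outliers = np.asarray(outliers, dtype=bool)
    rows = []
    for sp_a, sp_b in control_pairs:
        na, state_a = _fixation_state(gm, [gm.sample_index(s) for s in popmap.samples_of(sp_a)])
        nb, state_b = _fixation_state(gm, [gm.sample_index(s) for s in popmap.samples_of(sp_b)])
        qual = cat4_mask & (na >= min_genotypes) & (nb >= min_genotypes)
        if not qual.any():
            warnings.warn(f"no qualifying category-4 sites for pair ({sp_a}, {sp_b}); skipped", stacklevel=2)
            continue
        diff_fixed = qual & (state_a >= 0) & (state_b >= 0) & (state_a != state_b)
        if not diff_fixed.any():
            warnings.warn(f"pair ({sp_a}, {sp_b}) has no fixed differences; p = 1 by convention", stacklevel=2)
        table = [
            [int((qual & outliers & diff_fixed).sum()), int((qual & outliers & ~diff_fixed).sum())],
            [int((qual & ~outliers & diff_fixed).sum()), int((qual & ~outliers & ~diff_fixed).sum())],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            (sp_a, sp_b, int(qual.sum()), int(diff_fixed.sum()),
             table[0][0], table[0][1], table[1][0], table[1][1], float(p))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_a", "species_b", "n_sites", "n_diff_fixed",
            "outlier_fixed", "outlier_not_fixed", "nonoutlier_fixed", "nonoutlier_not_fixed", "p",
        ],
    )
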