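"""Seeded hybrid-swarm simulator with known truth.

Generates the study system the analysis modules expect: two parental lineages
(a major "congolese" and a minor "upper_nile" lineage) diverged by drift from
a common ancestor, a hybrid swarm carrying a minor-lineage ancestry proportion
alpha in recombination-broken ancestry tracts, several daughter species that
drifted apart after admixture (differential sorting), an unadmixed sister
lineage, an eastern lineage related to the minor parent (the F4-ratio
reference), control species pairs outside the radiation, and an outgroup
fixed for the ancestral allele at every site (so the alternate allele IS the
derived allele and polarization is exact).

Drift is modelled with Balding–Nichols beta draws around the ancestral
frequency; local ancestry along a chromosome follows a two-state Markov
process whose tract lengths are exponential with mean 1/((1−alpha)·r·t) for
the minor lineage and 1/(alpha·r·t) for the major lineage.  This encodes
every statistical structure the downstream analyses consume (allele-frequency
correlations, tract-length distributions, divergently fixed loci, optional
exaggerated post-admixture sorting at BDM-flagged loci) without a full
coalescent simulation, and is fully deterministic under the seed.

Besides the main generator three focused helpers built on the same machinery
serve calibration and power checks: :func:`simulate_quartet` (D statistics),
:func:`simulate_fivepop_quintet` (directional introgression) and
:func:`simulate_sorting_dataset` (allele-sorting enrichment; frequency-level
drift so that neutral divergently-fixed and control sites are exchangeable by
construction).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    write_vcf,
)

LINEAGE_CONGO = "congolese"
LINEAGE_NILE = "upper_nile"


@dataclass
class SimulationConfig:
    """Parameters of the hybrid-swarm simulation.

    Defaults are the study conditions: minor-lineage (upper_nile) ancestry
    alpha = 0.2, recombination rate r = 2.5e-8 per bp per generation,
    t_admix = 100,000 generations since admixture (expected minor-ancestry
    tract length 500 bp), parental drift F = 0.2 on each side of a deep
    split, 10 diploids per group and 50,000 SNPs.
    """

    seed: int = 0
    n_sites: int = 50_000
    chrom_length: int = 20_000_000
    scaffold: str = "scaf1"
    r: float = 2.5e-8
    t_admix: float = 100_000.0
    alpha: float = 0.2
    f_congo: float = 0.2
    f_nile: float = 0.2
    f_species: float = 0.05
    f_eastern: float = 0.05
    f_sister: float = 0.05
    f_control: float = 0.2
    f_control_within: float = 0.05
    n_species: int = 3
    n_diploids: int = 10
    n_outgroup: int = 3
    n_control_pairs: int = 2
    frac_bdm: float = 0.05
    bdm_sorting: bool = False
    f_bdm: float = 0.8
    shared_species_tracts: bool = False
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "f_congo", "f_nile", "f_species", "f_eastern",
                     "f_sister", "f_control", "f_control_within", "f_bdm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.frac_bdm <= 1.0 or not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("frac_bdm and missing_rate must lie in [0, 1]")
        if self.r <= 0 or self.t_admix <= 0:
            raise ConfigurationError("r and t_admix must be positive")


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    true_alpha: float
    tracts: pd.DataFrame  # haplotype, start, end, lineage (BED convention)
    parental: pd.DataFrame  # pos, p_ancestral, congolese_freq, upper_nile_freq, fixed, bdm
    category: np.ndarray  # true ancestry category per site ('1'..'4')

    def realized_alpha(self) -> float:
        """Minor-lineage genome fraction actually realized across haplotypes."""
        nile = self.tracts[self.tracts["lineage"] == LINEAGE_NILE]
        return float((nile["end"] - nile["start"]).sum() / (self.tracts["end"] - self.tracts["start"]).sum())


@dataclass
class SwarmDataset:
    """A simulated dataset: genotypes, group map and truth."""

    gm: GenotypeMatrix
    popmap: PopulationMap
    truth: TruthSet
    config: SimulationConfig


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Beta-distributed drifted frequencies around p with drift parameter f.

    f = 0 returns p unchanged; frequencies already fixed (0 or 1) stay fixed.
    """
    p = np.asarray(p, dtype=float)
    if f <= 0.0:
        return p.copy()
    if f >= 1.0:  # complete drift: fixation by Bernoulli(p)
        return (rng.random(p.shape) < p).astype(float)
    out = np.empty_like(p)
    interior = (p > 0.0) & (p < 1.0)
    ab = (1.0 - f) / f
    out[interior] = rng.beta(p[interior] * ab, (1.0 - p[interior]) * ab)
    out[~interior] = p[~interior]
    return out


def draw_parental_freqs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ancestral and parental-lineage allele frequencies per site.

    Ancestral derived-allele frequencies are uniform on (0.05, 0.95); each
    lineage drifts by a Balding–Nichols draw with its F.  A ``frac_bdm``
    subset of sites is forced to divergent fixation (pC, pN) = (0, 1) or
    (1, 0), flagged for optional exaggerated post-admixture sorting.

    Returns ``(p_ancestral, congolese_freq, upper_nile_freq, fixed_flags)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    p = rng.uniform(0.05, 0.95, size=config.n_sites)
    pc = _balding_nichols(rng, p, config.f_congo)
    pn = _balding_nichols(rng, p, config.f_nile)
    fixed = rng.random(config.n_sites) < config.frac_bdm
    orient = rng.random(config.n_sites) < 0.5
    pc[fixed] = np.where(orient[fixed], 0.0, 1.0)
    pn[fixed] = np.where(orient[fixed], 1.0, 0.0)
    return p, pc, pn, fixed


def simulate_ancestry_tracts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One haplotype's ancestry tracts tiling [0, chrom_length).

    A two-state Markov process with stationary probabilities (alpha for the
    minor lineage) and exponential tract lengths: mean 1/((1−alpha)·r·t) for
    minor-lineage tracts, 1/(alpha·r·t) for major-lineage tracts.  Returns a
    DataFrame (start, end, lineage).
    """
    rng = rng or np.random.default_rng(config.seed)
    L = config.chrom_length
    if config.alpha <= 0.0:
        return pd.DataFrame({"start": [0], "end": [L], "lineage": [LINEAGE_CONGO]})
    if config.alpha >= 1.0:
        return pd.DataFrame({"start": [0], "end": [L], "lineage": [LINEAGE_NILE]})
    mean_nile = 1.0 / ((1.0 - config.alpha) * config.r * config.t_admix)
    mean_congo = 1.0 / (config.alpha * config.r * config.t_admix)

    state = int(rng.random() < config.alpha)  # 1 = nile
    starts, lineages = [], []
    pos = 0.0
    # draw segment lengths in batches until the chromosome is tiled
    est = max(16, int(2 * L / (config.alpha * mean_nile + (1 - config.alpha) * mean_congo) + 16))
    while pos < L:
        lens = rng.exponential(1.0, size=est)
        for u in lens:
            mean = mean_nile if state else mean_congo
            starts.append(pos)
            lineages.append(LINEAGE_NILE if state else LINEAGE_CONGO)
            pos += u * mean
            state = 1 - state
            if pos >= L:
                break
    starts = np.floor(np.asarray(starts)).astype(np.int64)
    ends = np.append(starts[1:], L)
    keep = ends > starts
    return pd.DataFrame({"start": starts[keep], "end": ends[keep],
                         "lineage": np.asarray(lineages, dtype=object)[keep]})


def _true_categories(pc: np.ndarray, pn: np.ndarray) -> np.ndarray:
    """Ancestry category each site would have at infinite parental sampling."""
    congo_poly = (pc > 0) & (pc < 1)
    nile_poly = (pn > 0) & (pn < 1)
    cat = np.full(len(pc), "1", dtype=object)
    cat[congo_poly] = "2"
    cat[~congo_poly & nile_poly] = "3"
    cat[~congo_poly & ~nile_poly & (pc != pn)] = "4"
    return cat


def _sample_diploids(rng, freq: np.ndarray, n: int) -> np.ndarray:
    """n diploid dosage columns drawn Binomial(2, freq)."""
    return rng.binomial(2, freq[:, None], size=(len(freq), n)).astype(np.int8)


def _draw_positions(rng, n_sites: int, chrom_length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, chrom_length + 1, size=n_sites))
    while len(pos) < n_sites:
        extra = rng.integers(1, chrom_length + 1, size=n_sites - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n_sites])


def simulate_hybrid_swarm(config: SimulationConfig) -> SwarmDataset:
    """Full hybrid-swarm dataset with genotypes, population map and truth.

    Emitted groups (each ``n_diploids`` unless noted): ``congolese`` and
    ``upper_nile`` parental lineages, ``eastern`` (sister of the minor
    parent; F4-ratio reference A), ``sister`` (unadmixed sister of the
    radiation), ``lv_1..lv_k`` daughter species of the swarm,
    ``control_1a/control_1b`` ... control species pairs, and ``outgroup``
    (``n_outgroup`` diploids, all homozygous ancestral).
    """
    rng = np.random.default_rng(config.seed)
    pos = _draw_positions(rng, config.n_sites, config.chrom_length)
    p_anc, pc, pn, fixed = draw_parental_freqs(config, rng)

    samples: list[str] = []
    groups: dict[str, str] = {}
    columns: list[np.ndarray] = []

    def add_group(name: str, dosages: np.ndarray) -> None:
        for i in range(dosages.shape[1]):
            s = f"{name}_{i}"
            samples.append(s)
            groups[s] = name
        columns.append(dosages)

    add_group("congolese", _sample_diploids(rng, pc, config.n_diploids))
    add_group("upper_nile", _sample_diploids(rng, pn, config.n_diploids))
    add_group("eastern", _sample_diploids(rng, _balding_nichols(rng, pn, config.f_eastern), config.n_diploids))
    add_group("sister", _sample_diploids(rng, _balding_nichols(rng, pc, config.f_sister), config.n_diploids))

    # daughter species of the swarm: tract-structured haplotypes
    tract_frames = []
    is_nile_means = []
    for s in range(1, config.n_species + 1):
        qc = _balding_nichols(rng, pc, config.f_species)
        qn = _balding_nichols(rng, pn, config.f_species)
        if config.bdm_sorting and fixed.any():
            swarm = config.alpha * pn[fixed] + (1.0 - config.alpha) * pc[fixed]
            q_bdm = _balding_nichols(rng, swarm, config.f_bdm)
        dosages = np.zeros((config.n_sites, config.n_diploids), dtype=np.int8)
        shared_tr = simulate_ancestry_tracts(config, rng) if config.shared_species_tracts else None
        for d in range(config.n_diploids):
            for h in range(2):
                tr = shared_tr.copy() if shared_tr is not None else simulate_ancestry_tracts(config, rng)
                hap_name = f"lv_{s}_{d}_h{h}"
                tr.insert(0, "haplotype", hap_name)
                tract_frames.append(tr)
                idx = np.searchsorted(tr["start"].to_numpy(), pos - 1, side="right") - 1
                on_nile = tr["lineage"].to_numpy()[idx] == LINEAGE_NILE
                is_nile_means.append(on_nile.mean())
                p_site = np.where(on_nile, qn, qc)
                if config.bdm_sorting and fixed.any():
                    p_site = p_site.copy()
                    p_site[fixed] = q_bdm
                dosages[:, d] += (rng.random(config.n_sites) < p_site).astype(np.int8)
        add_group(f"lv_{s}", dosages)

    for k in range(1, config.n_control_pairs + 1):
        anc_k = _balding_nichols(rng, p_anc, config.f_control)
        for tag in ("a", "b"):
            add_group(f"control_{k}{tag}",
                      _sample_diploids(rng, _balding_nichols(rng, anc_k, config.f_control_within), config.n_diploids))

    add_group("outgroup", np.zeros((config.n_sites, config.n_outgroup), dtype=np.int8))

    calls = np.concatenate(columns, axis=1)
    if config.missing_rate > 0:
        calls = calls.copy()
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    sites = pd.DataFrame(
        {"scaffold": config.scaffold, "pos": pos, "ref": "A", "alt": "T"}
    )
    gm = GenotypeMatrix(sites=sites, samples=samples, calls=calls)
    roles = {
        "congolese": "congolese",
        "upper_nile": "upper_nile",
        "eastern": "eastern",
        "sister": "P2",
        "outgroup": "outgroup",
    }
    roles.update({f"lv_{s}": "LV_species" for s in range(1, config.n_species + 1)})
    for k in range(1, config.n_control_pairs + 1):
        roles[f"control_{k}a"] = "control"
        roles[f"control_{k}b"] = "control"
    popmap = PopulationMap(groups, roles)

    truth = TruthSet(
        true_alpha=config.alpha,
        tracts=pd.concat(tract_frames, ignore_index=True) if tract_frames else
        pd.DataFrame(columns=["haplotype", "start", "end", "lineage"]),
        parental=pd.DataFrame(
            {"pos": pos, "p_ancestral": p_anc, "congolese_freq": pc,
             "upper_nile_freq": pn, "fixed": fixed,
             "bdm": fixed & config.bdm_sorting}
        ),
        category=_true_categories(pc, pn),
    )
    return SwarmDataset(gm=gm, popmap=popmap, truth=truth, config=config)


def genotypes_from_truth(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SwarmDataset:
    """Simulate a dataset and (optionally) write VCF, popmap and truth tables.

    Files written under ``out_dir``: ``sim.vcf``, ``popmap.tsv``,
    ``roles.json``, ``truth_tracts.tsv``, ``truth_sites.tsv`` and
    ``config.json`` (the provenance echo).  The same seed reproduces the
    files byte for byte.
    """
    ds = simulate_hybrid_swarm(config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(ds.gm, out / "sim.vcf")
        ds.popmap.to_tsv(out / "popmap.tsv")
        (out / "roles.json").write_text(json.dumps(ds.popmap.roles, indent=1))
        ds.truth.tracts.to_csv(out / "truth_tracts.tsv", sep="\t", index=False)
        ds.truth.parental.assign(category=ds.truth.category).to_csv(
            out / "truth_sites.tsv", sep="\t", index=False
        )
        (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=1))
    return ds


# ---------------------------------------------------------------------------
# Focused generators for calibration and power checks
# ---------------------------------------------------------------------------

def simulate_quartet(
    n_sites: int = 10_000,
    n_diploids: int = 10,
    f_gene_flow: float = 0.0,
    f_split: float = 0.2,
    f_within: float = 0.05,
    n_outgroup: int = 3,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Four-population dataset ((P1,P2),P3),O with optional P3→P1 gene flow.

    ``f_gene_flow`` is the fraction of P1's ancestry replaced by P3 at the
    frequency level; 0 gives the no-gene-flow null for type-I calibration.
    The outgroup is fixed ancestral.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_sites)
    p12 = _balding_nichols(rng, p, f_split)
    p3 = _balding_nichols(rng, p, f_split)
    p1 = _balding_nichols(rng, p12, f_within)
    p2 = _balding_nichols(rng, p12, f_within)
    if f_gene_flow > 0:
        p1 = (1.0 - f_gene_flow) * p1 + f_gene_flow * p3

    samples, groups, cols = [], {}, []
    for name, freq, n in (
        ("P1", p1, n_diploids), ("P2", p2, n_diploids), ("P3", p3, n_diploids),
    ):
        dos = _sample_diploids(rng, freq, n)
        for i in range(n):
            samples.append(f"{name}_{i}")
            groups[f"{name}_{i}"] = name
        cols.append(dos)
    cols.append(np.zeros((n_sites, n_outgroup), dtype=np.int8))
    for i in range(n_outgroup):
        samples.append(f"outgroup_{i}")
        groups[f"outgroup_{i}"] = "outgroup"

    sites = pd.DataFrame(
        {"scaffold": "scaf1", "pos": np.arange(1, n_sites + 1), "ref": "A", "alt": "T"}
    )
    gm = GenotypeMatrix(sites=sites, samples=samples, calls=np.concatenate(cols, axis=1))
    popmap = PopulationMap(groups, {"P1": "P1", "P2": "P2", "P3": "P3", "outgroup": "outgroup"})
    return gm, popmap


def simulate_fivepop_quintet(
    n_sites: int = 50_000,
    f_intro: float = 0.2,
    direction: str | None = None,
    f_clade: float = 0.3,
    f_within: float = 0.05,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Single-diploid quintet ((P1,P2),(P3a,P3b)),O with one-way introgression.

    ``direction`` is one of ``'P3a->P1'``, ``'P1->P3a'``, ``'P1->P3b'`` or
    None (no gene flow); ``f_intro`` is the per-site probability that the
    recipient haplotype's allele is drawn from the donor population instead.
    The within-pair splits are shallow relative to the deep clade split so
    donor-side and recipient-side gene flow leave their distinct pattern
    imbalances.
    """
    if direction not in (None, "P3a->P1", "P1->P3a", "P1->P3b"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_sites)
    p12 = _balding_nichols(rng, p, f_clade)
    p34 = _balding_nichols(rng, p, f_clade)
    freqs = {
        "P1": _balding_nichols(rng, p12, f_within),
        "P2": _balding_nichols(rng, p12, f_within),
        "P3a": _balding_nichols(rng, p34, f_within),
        "P3b": _balding_nichols(rng, p34, f_within),
    }

    recipient_donor = {
        "P3a->P1": ("P1", "P3a"), "P1->P3a": ("P3a", "P1"), "P1->P3b": ("P3b", "P1"),
    }
    samples, groups, cols = [], {}, []
    for name in ("P1", "P2", "P3a", "P3b"):
        hap_freq = freqs[name]
        dos = np.zeros(n_sites, dtype=np.int8)
        for _ in range(2):
            src = hap_freq
            if direction is not None and recipient_donor[direction][0] == name:
                donor = freqs[recipient_donor[direction][1]]
                intro = rng.random(n_sites) < f_intro
                src = np.where(intro, donor, hap_freq)
            dos += (rng.random(n_sites) < src).astype(np.int8)
        samples.append(name)
        groups[name] = name
        cols.append(dos[:, None])
    samples.append("outgroup")
    groups["outgroup"] = "outgroup"
    cols.append(np.zeros((n_sites, 1), dtype=np.int8))

    sites = pd.DataFrame(
        {"scaffold": "scaf1", "pos": np.arange(1, n_sites + 1), "ref": "A", "alt": "T"}
    )
    gm = GenotypeMatrix(sites=sites, samples=samples, calls=np.concatenate(cols, axis=1))
    roles = {"P1": "P1", "P2": "P2", "P3a": "P3a", "P3b": "P3b", "outgroup": "outgroup"}
    return gm, PopulationMap(groups, roles)


def simulate_sorting_dataset(
    n_sites: int = 20_000,
    n_species: int = 6,
    n_diploids: int = 10,
    n_congo: int = 5,
    n_nile: int = 9,
    alpha: float = 0.16,
    f_parental: float = 0.2,
    f_species: float = 0.05,
    frac_fixed: float = 0.1,
    bdm_sorting: bool = False,
    f_bdm: float = 0.5,
    n_control_pairs: int = 2,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Frequency-level dataset for the allele-sorting enrichment analysis.

    Radiation species drift from the hybrid-swarm frequency
    q0 = (1−alpha)·pC + alpha·pN with a single drift law applied identically
    to every site, so that under neutrality (``bdm_sorting=False``) the
    divergently fixed sites and the frequency-matched control sites are
    exchangeable — the type-I behaviour of the enrichment test can be checked
    against this exact null.  With ``bdm_sorting=True`` the fixed sites drift
    with ``f_bdm`` instead (exaggerated sorting toward alternative fixation
    in different species).  Returns ``(gm, popmap, truth_frame)`` where the
    truth frame carries pC, pN, q0 and the fixed flags.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_sites)
    pc = _balding_nichols(rng, p, f_parental)
    pn = _balding_nichols(rng, p, f_parental)
    fixed = rng.random(n_sites) < frac_fixed
    orient = rng.random(n_sites) < 0.5
    pc[fixed] = np.where(orient[fixed], 0.0, 1.0)
    pn[fixed] = np.where(orient[fixed], 1.0, 0.0)
    q0 = (1.0 - alpha) * pc + alpha * pn

    samples, groups, cols = [], {}, []

    def add(name: str, dos: np.ndarray) -> None:
        for i in range(dos.shape[1]):
            samples.append(f"{name}_{i}")
            groups[f"{name}_{i}"] = name
        cols.append(dos)

    for s in range(1, n_species + 1):
        qs = _balding_nichols(rng, q0, f_species)
        if bdm_sorting and fixed.any():
            qs = qs.copy()
            qs[fixed] = _balding_nichols(rng, q0[fixed], f_bdm)
        add(f"lv_{s}", _sample_diploids(rng, qs, n_diploids))
    add("congolese", _sample_diploids(rng, pc, n_congo))
    add("upper_nile", _sample_diploids(rng, pn, n_nile))
    for k in range(1, n_control_pairs + 1):
        anc_k = _balding_nichols(rng, p, 0.3)
        for tag in ("a", "b"):
            add(f"control_{k}{tag}", _sample_diploids(rng, _balding_nichols(rng, anc_k, 0.1), 3))

    sites = pd.DataFrame(
        {"scaffold": "scaf1", "pos": np.arange(1, n_sites + 1), "ref": "A", "alt": "T"}
    )
    gm = GenotypeMatrix(sites=sites, samples=samples, calls=np.concatenate(cols, axis=1))
    roles = {f"lv_{s}": "LV_species" for s in range(1, n_species + 1)}
    roles.update({"congolese": "congolese", "upper_nile": "upper_nile"})
    for k in range(1, n_control_pairs + 1):
        roles[f"control_{k}a"] = "control"
        roles[f"control_{k}b"] = "control"
    truth = pd.DataFrame(
        {"congolese_freq": pc, "upper_nile_freq": pn, "swarm_freq": q0, "fixed": fixed,
         "bdm": fixed & bdm_sorting}
    )
    return gm, PopulationMap(groups, roles), truth
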