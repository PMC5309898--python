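"""VCF input, site filtering and per-group allele frequencies.

The genotype substrate for every statistic in the package is a
:class:`GenotypeMatrix`: a site table (scaffold, 1-based position, ref/alt
single-nucleotide alleles) plus a sites × samples matrix of diploid
alternate-allele dosages (0/1/2, −1 for missing).  Sites are biallelic SNPs
only; indels and multiallelic records are dropped on input.  Coordinates are
1-based on VCF input and output; window arithmetic elsewhere in the package is
0-based half-open.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedStatisticError, VCFParseError

MISSING = -1

#: columns every site table carries
SITE_COLUMNS = ("scaffold", "pos", "ref", "alt")


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ConfigurationError(f"site table lacks columns {missing}")
    return sites.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Diploid alternate-allele dosages over a table of biallelic SNPs.

    Parameters
    ----------
    sites
        DataFrame with columns ``scaffold, pos, ref, alt`` (pos 1-based).
    samples
        Ordered sample identifiers, one per matrix column.
    calls
        int8 array of shape ``(n_sites, n_samples)``; values 0/1/2 count
        alternate alleles, −1 marks a missing genotype.
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ConfigurationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ConfigurationError("dosages must be in {0,1,2} or -1 (missing)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ConfigurationError(f"sample {sample!r} not in genotype matrix") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset (boolean mask or integer index), preserving order."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx],
            samples=list(self.samples),
            calls=self.calls[idx],
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return (self.calls == MISSING).mean(axis=1)


@dataclass
class PopulationMap:
    """Sample → group assignment plus optional group → role labels.

    Roles name how a group is used by an analysis (P1, P2, P3, P3a, P3b,
    outgroup, LV_species, congolese, upper_nile, control, ...); a group may
    appear without a role.
    """

    sample_to_group: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_group)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sample_to_group.values():
            seen.setdefault(g)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        out = [s for s, g in self.sample_to_group.items() if g == group]
        if not out:
            raise ConfigurationError(f"group {group!r} has no samples in population map")
        return out

    def groups_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]

    @classmethod
    def from_tsv(cls, path: str | Path, roles: str | Path | dict | None = None) -> "PopulationMap":
        """Read a two-column TSV (sample, group); roles from a JSON file or dict."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ConfigurationError(f"population map {path} needs two columns (sample, group)")
        mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        role_map: dict[str, str] = {}
        if isinstance(roles, dict):
            role_map = dict(roles)
        elif roles is not None:
            role_map = json.loads(Path(roles).read_text())
        return cls(mapping, role_map)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, g in self.sample_to_group.items():
                fh.write(f"{s}\t{g}\n")


@dataclass
class FrequencyTable:
    """Per site × group alternate- (or derived-) allele frequencies.

    ``freq`` is NaN where a group has no called genotypes.  After
    :func:`polarize`, ``freq`` holds derived-allele frequencies and
    ``polarized`` is True; sites that could not be oriented are NaN for all
    groups and flagged in ``unpolarizable``.
    """

    sites: pd.DataFrame
    groups: list[str]
    freq: np.ndarray
    n_called: np.ndarray
    polarized: bool = False
    unpolarizable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_called = np.asarray(self.n_called, dtype=int)
        shape = (len(self.sites), len(self.groups))
        if self.freq.shape != shape or self.n_called.shape != shape:
            raise ConfigurationError("frequency table dimensions inconsistent")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq, initial=0.0) < -1e-12 or np.nanmax(self.freq, initial=0.0) > 1 + 1e-12:
                raise ConfigurationError("frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise ConfigurationError(f"group {group!r} not in frequency table") from None

    def freq_of(self, group: str) -> np.ndarray:
        return self.freq[:, self.group_index(group)]

    def n_called_of(self, group: str) -> np.ndarray:
        return self.n_called[:, self.group_index(group)]

    def to_tsv(self, path: str | Path) -> None:
        df = self.sites.copy()
        for j, g in enumerate(self.groups):
            df[f"freq_{g}"] = self.freq[:, j]
            df[f"n_{g}"] = self.n_called[:, j]
        df.to_csv(path, sep="\t", index=False)


# cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(
    path: str | Path,
    popmap: PopulationMap | None = None,
    min_depth: int | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Indels and multiallelic records are dropped.  When ``min_depth`` is given
    and the VCF carries FORMAT/DP, genotypes below the threshold are set
    missing; without FORMAT/DP the threshold is ignored (depth filtering is
    assumed done upstream).

    Raises
    ------
    ConfigurationError
        if a population-map sample is absent from the VCF header.
    VCFParseError
        if the file cannot be parsed as VCF.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VCFParseError(f"cannot open {path} as VCF: {exc}") from exc

    header_samples = list(vcf.samples)
    if popmap is not None:
        absent = [s for s in popmap.samples if s not in header_samples]
        if absent:
            raise ConfigurationError(
                f"population-map sample(s) absent from VCF header: {', '.join(absent)}"
            )
        vcf.close()
        vcf = VCF(str(path), samples=popmap.samples)
    samples = list(vcf.samples)

    rows = []
    dosages = []
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                continue  # indel / symbolic
            if var.REF not in "ACGT" or var.ALT[0] not in "ACGT":
                continue
            dos = _GT_TYPE_TO_DOSAGE[var.gt_types]
            if min_depth is not None:
                dp = var.format("DP")
                if dp is not None:
                    dp = dp.reshape(-1).astype(float)
                    dos = dos.copy()
                    dos[np.nan_to_num(dp, nan=-1.0) < min_depth] = MISSING
            rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
            dosages.append(dos)
    except Exception as exc:
        raise VCFParseError(f"error parsing {path}: {exc}") from exc
    finally:
        vcf.close()

    sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    calls = (
        np.asarray(dosages, dtype=np.int8)
        if dosages
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix back out as an uncompressed VCFv4.2 with GT only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridtrace\n")
        for scaffold in gm.sites["scaffold"].unique():
            fh.write(f"##contig=<ID={scaffold}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for i, row in enumerate(gm.sites.itertuples(index=False)):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in gm.calls[i])
            fh.write(f"{row.scaffold}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def filter_sites(
    gm: GenotypeMatrix,
    maf_min: float = 0.0,
    max_missing: float = 1.0,
    groups_min_called: dict[str, int] | None = None,
    popmap: PopulationMap | None = None,
) -> GenotypeMatrix:
    """Keep sites passing a minor-allele-frequency cutoff, a missing-data cap
    and optional per-group minimum called-individual counts, all applied
    simultaneously; site order is preserved.
    """
    if not 0.0 <= maf_min <= 1.0 or not 0.0 <= max_missing <= 1.0:
        raise ConfigurationError("maf_min and max_missing must lie in [0, 1]")
    if gm.n_sites == 0:
        return gm

    called = gm.calls != MISSING
    n_called = called.sum(axis=1)
    keep = (gm.calls == MISSING).mean(axis=1) <= max_missing

    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, gm.calls, 0).sum(axis=1) / (2.0 * n_called)
    maf = np.minimum(alt, 1.0 - alt)
    keep &= np.where(n_called > 0, maf >= maf_min, False)

    if groups_min_called:
        if popmap is None:
            raise ConfigurationError("groups_min_called requires a population map")
        for group, minimum in groups_min_called.items():
            cols = [gm.sample_index(s) for s in popmap.samples_of(group)]
            keep &= called[:, cols].sum(axis=1) >= minimum

    if not keep.any():
        warnings.warn("all sites removed by filters", stacklevel=2)
    return gm.take_sites(keep)


def allele_freqs(gm: GenotypeMatrix, popmap: PopulationMap) -> FrequencyTable:
    """Per-group alternate-allele frequencies: Σ dosage / (2 × called)."""
    groups = popmap.group_names
    n_sites = gm.n_sites
    freq = np.full((n_sites, len(groups)), np.nan)
    n_called = np.zeros((n_sites, len(groups)), dtype=int)
    for j, group in enumerate(groups):
        cols = [gm.sample_index(s) for s in popmap.samples_of(group)]
        sub = gm.calls[:, cols]
        called = sub != MISSING
        cnt = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(called, sub, 0).sum(axis=1) / (2.0 * cnt)
        freq[:, j] = np.where(cnt > 0, f, np.nan)
        n_called[:, j] = cnt
    return FrequencyTable(sites=gm.sites, groups=groups, freq=freq, n_called=n_called)


def polarize(freqs: FrequencyTable, outgroup: str) -> FrequencyTable:
    """Re-express frequencies as derived-allele frequencies using the outgroup.

    The outgroup major allele is taken as ancestral; the derived allele is the
    minority (or absent) allele in the outgroup.  Sites where the outgroup is
    missing, or is polymorphic with both alleles at exactly 0.5, cannot be
    oriented: they are flagged unpolarizable and set NaN for every group.
    """
    og = freqs.freq_of(outgroup)
    flip = og > 0.5  # outgroup major allele is ALT -> derived allele is REF
    tie = np.isclose(og, 0.5)
    unpolarizable = np.isnan(og) | tie

    freq = freqs.freq.copy()
    freq[flip] = 1.0 - freq[flip]
    freq[unpolarizable] = np.nan
    n_unpol = int(unpolarizable.sum())
    if n_unpol:
        warnings.warn(f"{n_unpol} site(s) unpolarizable against outgroup {outgroup!r}", stacklevel=2)
    return FrequencyTable(
        sites=freqs.sites,
        groups=list(freqs.groups),
        freq=freq,
        n_called=freqs.n_called.copy(),
        polarized=True,
        unpolarizable=unpolarizable,
    )
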