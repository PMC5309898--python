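"""One-config orchestration of the full analysis.

A run config (YAML/JSON mapping) names either a ``simulate`` block (passed to
:class:`~hybridtrace.synthetic_data.SimulationConfig`) or an ``input`` block
(``vcf``, ``popmap``, optional ``roles`` paths), a list of ``stages``, and
per-stage parameter mappings.  Defaults bake in the analysis constants:
block-jackknife significance at |z| = 3, 100 bootstrap replicates, 10-kb fd
windows with a minimum of 5 weighted patterns, 3-kb ancestry windows with
0.7/0.3 colour thresholds and weighted total > 1, parental weights 0.84/0.16
with a 14–18 % control window, and P < 0.05 outliers.  Every default is
overridable.  All randomness derives from one root seed with per-stage
substreams, so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from . import allele_sorting, fivepop, genotype_io, site_patterns, synthetic_data, window_scan

log = logging.getLogger("hybridtrace")

STAGES = ("simulate", "dstat", "f4ratio", "fivepop", "fd_scan", "blocks", "sort_alleles")


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run."""

    version: str
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


def run_pipeline(config: dict, out_dir: str | Path) -> RunReport:
    """Execute the configured stages in dependency order.

    Outputs (TSV/BED/JSON) are written under ``out_dir``; the report lists
    every stage's outputs, summary statistics and wall-clock seconds.  A
    failure aborts with an error naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {unknown}")
    report = RunReport(version=__version__, config_hash=config_hash(config), seed=seed)

    gm = popmap = freqs = polarized = None
    if "simulate" in stages or "simulate" in config:
        t0 = time.perf_counter()
        sim_params = dict(config.get("simulate") or {})
        sim_params.setdefault("seed", _stage_seed(seed, "simulate"))
        sim_cfg = synthetic_data.SimulationConfig(**sim_params)
        log.info("simulate: %s", sim_cfg)
        ds = synthetic_data.genotypes_from_truth(sim_cfg, out / "simulated")
        gm, popmap = ds.gm, ds.popmap
        report.stages["simulate"] = {
            "outputs": [str(out / "simulated")],
            "summary": {"n_sites": gm.n_sites, "n_samples": gm.n_samples,
                        "true_alpha": ds.truth.true_alpha,
                        "realized_alpha": ds.truth.realized_alpha()},
            "seconds": time.perf_counter() - t0,
        }
    elif "input" in config:
        inp = config["input"]
        popmap = genotype_io.PopulationMap.from_tsv(inp["popmap"], inp.get("roles"))
        gm = genotype_io.read_vcf(inp["vcf"], popmap, inp.get("min_depth"))
    else:
        raise ConfigurationError("config needs a 'simulate' or 'input' block")

    filt = config.get("filter", {})
    if filt:
        gm = genotype_io.filter_sites(
            gm, filt.get("maf_min", 0.0), filt.get("max_missing", 1.0),
            filt.get("groups_min_called"), popmap,
        )
    freqs = genotype_io.allele_freqs(gm, popmap)

    def _polarized(outgroup: str):
        nonlocal polarized
        if polarized is None:
            polarized = genotype_io.polarize(freqs, outgroup)
        return polarized

    for stage in stages:
        if stage == "simulate":
            continue
        t0 = time.perf_counter()
        params = dict(config.get(stage) or {})
        log.info("stage %s: %s", stage, params or "defaults")
        try:
            outputs, summary = _RUNNERS[stage](gm, popmap, freqs, _polarized, params, out, seed)
        except ConfigurationError:
            raise
        except Exception as exc:
            raise ConfigurationError(f"stage {stage!r} failed: {exc}") from exc
        report.stages[stage] = {
            "outputs": outputs, "summary": summary,
            "seconds": time.perf_counter() - t0,
        }

    report.to_json(out / "report.json")
    return report


def _run_dstat(gm, popmap, freqs, polarized, params, out, seed):
    og = params.get("outgroup", "outgroup")
    res = site_patterns.d_statistic(
        _maybe_polarized(polarized, params, og),
        params.get("p1", "lv_1"), params.get("p2", "sister"),
        params.get("p3", "upper_nile"), og,
        params.get("block_size", site_patterns.DEFAULT_BLOCK_SIZE),
    )
    path = out / "dstat.tsv"
    pd.DataFrame([dataclasses.asdict(res) | {"significant": res.significant}]).to_csv(
        path, sep="\t", index=False
    )
    return [str(path)], {"D": res.d, "z": res.z, "significant": res.significant}


def _run_f4ratio(gm, popmap, freqs, polarized, params, out, seed):
    og = params.get("outgroup", "outgroup")
    res = site_patterns.f4_ratio(
        _maybe_polarized(polarized, params, og),
        params.get("a", "eastern"), params.get("b", "upper_nile"),
        params.get("c", "congolese"), og, params.get("x", "lv_1"),
        params.get("block_size", site_patterns.DEFAULT_BLOCK_SIZE),
    )
    path = out / "f4ratio.tsv"
    pd.DataFrame([dataclasses.asdict(res)]).to_csv(path, sep="\t", index=False)
    return [str(path)], {"alpha": res.alpha, "se": res.jackknife_se}


def _run_fivepop(gm, popmap, freqs, polarized, params, out, seed):
    p1_group = params.get("p1_group", "lv_1")
    p1_samples = params.get("p1_samples") or popmap.samples_of(p1_group)[:3]
    results, mean = fivepop.run_fivepop_panel(
        gm, p1_samples,
        params.get("p2", popmap.samples_of("sister")[0] if "sister" in popmap.group_names else None),
        params.get("p3a", popmap.samples_of("upper_nile")[0]),
        params.get("p3b", popmap.samples_of("eastern")[0]),
        params.get("outgroup", popmap.samples_of("outgroup")[0]),
        n_boot=params.get("n_boot", 100),
        seed=params.get("seed", _stage_seed(seed, "fivepop")),
    )
    rows = [
        {"p1": s} | r.counts.as_dict() | r.d_values() | r.z_values()
        | {"direction_call": r.direction_call}
        for s, r in zip(p1_samples, results)
    ]
    path = out / "fivepop.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    calls = [r.direction_call for r in results]
    return [str(path)], {"mean_D": mean, "direction_calls": calls}


def _run_fd_scan(gm, popmap, freqs, polarized, params, out, seed):
    og = params.get("outgroup", "outgroup")
    table = window_scan.fd_windows(
        _maybe_polarized(polarized, params, og),
        params.get("p1", "congolese"), params.get("p2", "lv_1"),
        params.get("p3", "upper_nile"), og,
        params.get("window_bp", 10_000), params.get("min_patterns", 5.0),
    )
    path = out / "fd_windows.tsv"
    table.to_csv(path, sep="\t", index=False)
    return [str(path)], {
        "n_windows": len(table),
        "mean_fd": float(table["fd"].mean()) if table["fd"].notna().any() else None,
    }


def _run_blocks(gm, popmap, freqs, polarized, params, out, seed):
    og = params.get("outgroup", "outgroup")
    table = window_scan.ancestry_windows(
        _maybe_polarized(polarized, params, og),
        params.get("congolese", "congolese"), params.get("target", "lv_1"),
        params.get("upper_nile", "upper_nile"), og,
        params.get("window_bp", 3_000), params.get("min_total", 1.0),
        params.get("hi", 0.7), params.get("lo", 0.3),
        params.get("min_scaffold_bp", 100_000),
    )
    tracts = window_scan.merge_tracts(table)
    hist = window_scan.tract_length_summary(tracts)
    paths = [out / "ancestry_windows.tsv", out / "ancestry_tracts.bed", out / "tract_histogram.tsv"]
    table.to_csv(paths[0], sep="\t", index=False)
    window_scan.tracts_to_bed(tracts, paths[1])
    hist.to_csv(paths[2], sep="\t", index=False)
    nile = [t.length for t in tracts if t.colour == window_scan.COLOUR_NILE]
    return [str(p) for p in paths], {
        "n_tracts": len(tracts),
        "mean_upper_nile_tract_bp": float(np.mean(nile)) if nile else None,
    }


def _run_sort_alleles(gm, popmap, freqs, polarized, params, out, seed):
    lv_groups = params.get("lv_groups") or popmap.groups_with_role("LV_species")
    congolese = params.get("congolese", "congolese")
    upper_nile = params.get("upper_nile", "upper_nile")
    fst = allele_sorting.global_fst(gm, popmap, lv_groups)
    null_cfg = allele_sorting.IslandNullConfig(
        n_demes=len(lv_groups),
        n_per_deme=max(len(popmap.samples_of(g)) for g in lv_groups),
        seed=params.get("seed", _stage_seed(seed, "sort_alleles")),
        n_sim=params.get("n_null_sim", 20_000),
    )
    outliers, p_vals = allele_sorting.flag_outliers(
        fst, null_cfg, params.get("p_threshold", 0.05),
        method=params.get("outlier_method", "simulation"),
    )
    cats = allele_sorting.classify_categories(
        gm, popmap, lv_groups, congolese, upper_nile,
        params.get("min_parental_individuals", 3),
    )
    cat4 = (cats["category"] == "4").to_numpy()
    control, wmaf = allele_sorting.select_control_set(
        cats["congolese_freq"].to_numpy(), cats["upper_nile_freq"].to_numpy(), cat4,
        params.get("w_congo", 0.84), params.get("w_nile", 0.16),
        tuple(params.get("control_window", (0.14, 0.18))),
    )
    masks = {c: (cats["category"] == c).to_numpy() for c in ("1", "2", "3", "4")}
    masks[allele_sorting.CONTROL_LABEL] = control
    enr = allele_sorting.enrichment(masks, outliers)

    per_snp = gm.sites.copy()
    per_snp["fst"] = fst.theta
    per_snp["outlier_p"] = p_vals
    per_snp["lv_outlier"] = outliers
    per_snp["category"] = cats["category"]
    per_snp["control_set"] = control
    per_snp["weighted_maf"] = wmaf
    paths = [out / "snp_categories.tsv", out / "enrichment.tsv"]
    per_snp.to_csv(paths[0], sep="\t", index=False)
    enr.table.to_csv(paths[1], sep="\t", index=False)

    summary = {
        "overall_fst": fst.overall_theta,
        "n_outliers": int(outliers.sum()),
        "enrichment": enr.table.to_dict("records"),
    }
    pair_groups = params.get("control_pairs")
    if pair_groups is None:
        ctrl = sorted(popmap.groups_with_role("control"))
        pair_groups = [(a, b) for a, b in zip(ctrl[::2], ctrl[1::2])]
    if pair_groups:
        pairs = allele_sorting.control_fixation_test(
            gm, popmap, pair_groups, cat4, outliers,
            params.get("min_genotypes", 3),
        )
        p3 = out / "control_fixation.tsv"
        pairs.to_csv(p3, sep="\t", index=False)
        paths.append(p3)
        summary["control_fixation_p"] = pairs["p"].tolist()
    return [str(p) for p in paths], summary


def _maybe_polarized(polarized_getter, params, outgroup):
    return polarized_getter(outgroup)


_RUNNERS = {
    "dstat": _run_dstat,
    "f4ratio": _run_f4ratio,
    "fivepop": _run_fivepop,
    "fd_scan": _run_fd_scan,
    "blocks": _run_blocks,
    "sort_alleles": _run_sort_alleles,
}
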