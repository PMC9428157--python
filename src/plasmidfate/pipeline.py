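"""End-to-end report: simulate/load -> decay -> SP -> community -> summary.

`run_report` executes every analysis stage on one experiment, writes
machine-readable TSV/JSON outputs into the run directory, and returns the
in-memory results. Stage failures are re-raised with the stage name so a
caller can tell which part of the pipeline broke.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from plasmidfate import __version__, community_analysis as ca, decay_kinetics as dk
from plasmidfate import io as pfio
from plasmidfate import spread_potential as spm
from plasmidfate import synthetic_data as sd

__all__ = ["StageError", "run_report", "removal_efficiency_table"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def removal_efficiency_table(
    abundance: pd.DataFrame, *, genes=("dsRed", "gfp")
) -> pd.DataFrame:
    """Removal efficiency per treatment x gene at each phase boundary.

    C0 and Ct are replicate means of the day-0 sample and of the last
    sampling day within each phase (TP, MP).
    """
    rows = []
    for (treatment, gene), sub in abundance[abundance["gene"].isin(genes)].groupby(
        ["treatment", "gene"], sort=True
    ):
        means = sub.groupby(["phase", "day"])["copies_per_g_dw"].mean()
        c0 = means.get(("IP", 0))
        if c0 is None or c0 <= 0:
            raise ValueError(f"no positive day-0 mean for {treatment}/{gene}")
        for phase in ("TP", "MP"):
            if phase not in means.index.get_level_values("phase"):
                continue
            day = max(means[phase].index)
            rows.append({
                "treatment": treatment,
                "gene": gene,
                "phase_end": phase,
                "day": day,
                "c0": float(c0),
                "ct": float(means[(phase, day)]),
                "removal_pct": dk.removal_efficiency(float(c0), float(means[(phase, day)])),
            })
    return pd.DataFrame(rows)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage label
                raise StageError(name, exc) from exc
        return wrapper
    return deco


@_stage("inputs")
def _load_inputs(cfg: pfio.RunConfig):
    if cfg.abundance_path is not None:
        abundance = pfio.read_abundance_table(cfg.abundance_path)
        gene_counts = abundance.groupby(["treatment", "replicate", "day"])["gene"] \
            .nunique()
        if (gene_counts < 3).any():
            bad = gene_counts[gene_counts < 3].index[0]
            raise ValueError(
                f"sample {tuple(bad)} is missing a marker gene "
                "(need dsRed, gfp and 16S)"
            )
        otu_table = None
        if cfg.otu_path is not None:
            otu_table = pfio.read_otu_inputs(cfg.otu_path, cfg.tax_path, cfg.meta_path)
        return abundance, otu_table, None
    exp = cfg.experiment or sd.SyntheticExperimentConfig(seed=cfg.seed)
    bundle = sd.make_experiment(exp)
    return bundle.abundance, bundle.otu_table, bundle


def run_report(cfg: pfio.RunConfig) -> dict[str, Any]:
    """Run all stages and write the report bundle under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash scientific settings only, not output paths
    meta = {"plasmidfate_version": __version__, "seed": cfg.seed,
            "config_hash": pfio.config_hash((
                cfg.seed, cfg.breakpoint_day, cfg.search_breakpoint,
                cfg.copies_per_cell, cfg.group_col, cfg.n_permutations,
                cfg.experiment))}

    abundance, otu_table, bundle = _load_inputs(cfg)
    if bundle is not None:
        pfio.write_abundance_table(abundance, outdir / "abundance.csv", meta)
        pfio.write_otu_inputs(
            otu_table, outdir / "otu_counts.tsv", outdir / "taxonomy.tsv",
            outdir / "sample_metadata.tsv", meta)
        pfio.write_ground_truth(bundle, outdir / "ground_truth.json")

    results: dict[str, Any] = {"meta": meta}

    @_stage("decay")
    def decay_stage():
        usable = abundance[abundance["copies_per_g_dw"] > 0]
        fits = dk.fit_decay_table(
            usable, breakpoint_day=cfg.breakpoint_day,
            search_breakpoint=cfg.search_breakpoint)
        removal = removal_efficiency_table(abundance)
        return fits, removal

    fits, removal = decay_stage()
    fits.to_csv(outdir / "decay_fits.tsv", sep="\t", index=False)
    removal.to_csv(outdir / "removal_efficiency.tsv", sep="\t", index=False)
    results["decay_fits"] = fits
    results["removal"] = removal

    @_stage("spread_potential")
    def sp_stage():
        series = spm.sp_timeseries(abundance, cfg.copies_per_cell)
        return series, spm.sp_summary(series)

    sp_series, sp_sum = sp_stage()
    sp_series.to_csv(outdir / "sp_series.tsv", sep="\t", index=False)
    sp_sum.to_csv(outdir / "sp_summary.tsv", sep="\t", index=False)
    results["sp_series"] = sp_series
    results["sp_summary"] = sp_sum

    if otu_table is not None:
        @_stage("community")
        def community_stage():
            alpha = ca.alpha_diversity_table(otu_table)
            dm = ca.bray_curtis(otu_table.counts)
            ordination = ca.pcoa(dm)
            perm = ca.permanova(
                dm, otu_table.metadata[cfg.group_col],
                n_permutations=cfg.n_permutations, seed=cfg.seed)
            sets = ca.genus_presence_sets(otu_table, cfg.group_col)
            hosts = ca.host_range_summary(sets)
            genus = ca.aggregate_taxonomy(otu_table, "genus")
            top = ca.top_n_matrix(genus, 30)
            return alpha, dm, ordination, perm, hosts, top

        alpha, dm, ordination, perm, hosts, top = community_stage()
        alpha.rename_axis("sample_id").to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        dm.rename_axis("sample_id").to_csv(outdir / "bray_curtis.tsv", sep="\t")
        ordination.coordinates.rename_axis("sample_id").to_csv(
            outdir / "pcoa_coordinates.tsv", sep="\t")
        top.rename_axis("taxon").to_csv(outdir / "top30_genera.tsv", sep="\t")
        results.update(alpha=alpha, bray_curtis=dm, ordination=ordination,
                       permanova=perm, host_range=hosts, top_genera=top)
        summary = {
            "permanova": {
                "pseudo_f": perm.pseudo_f, "r_squared": perm.r_squared,
                "p_value": perm.p_value, "n_permutations": perm.n_permutations,
            },
            "host_range": {
                "core_size": len(hosts.core),
                "shared_pct_of_union": hosts.shared_pct_of_union,
                "unique": hosts.unique,
            },
        }
        (outdir / "community_summary.json").write_text(
            json.dumps(summary, indent=2))

    lines = [
        f"plasmidfate report (version {__version__}, seed {cfg.seed})",
        f"decay fits: {len(fits)} segments "
        f"(breakpoint day {cfg.breakpoint_day}, "
        f"{'grid-searched' if cfg.search_breakpoint else 'fixed'})",
        f"spread potential: {int(sp_series['sp'].notna().sum())} samples",
    ]
    if otu_table is not None:
        lines.append(
            f"community: {otu_table.counts.shape[0]} OTUs x "
            f"{otu_table.counts.shape[1]} samples; "
            f"PERMANOVA p = {results['permanova'].p_value:.4g}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return results
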