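"""Readers and writers for abundance tables, OTU inputs, and configs.

Abundance tables are CSV (comma, dot decimal); OTU count and taxonomy
tables are TSV in the Mothur/QIIME-classic flavor (a leading ``#OTU ID``
header is tolerated). All writers prepend ``# key=value`` comment lines
carrying a config hash for provenance; readers skip such lines (``#``
followed by a space) while preserving ``#OTU ID`` headers.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from plasmidfate.community_analysis import OtuTable
from plasmidfate.synthetic_data import SyntheticExperimentConfig

__all__ = [
    "AbundanceRecord",
    "RunConfig",
    "ABUNDANCE_COLUMNS",
    "config_hash",
    "read_abundance_table",
    "write_abundance_table",
    "abundance_records",
    "read_otu_inputs",
    "write_otu_inputs",
    "read_experiment_config",
    "read_run_config",
    "write_ground_truth",
]

ABUNDANCE_COLUMNS = (
    "sample_id", "treatment", "replicate", "day", "phase", "gene",
    "copies_per_g_dw", "n_pos_droplets", "n_total_droplets",
)
_KEY_COLUMNS = ["treatment", "replicate", "day", "gene"]
_PHASES = {"IP", "TP", "MP"}
_GENES = {"dsRed", "gfp", "16S"}


@dataclass(frozen=True)
class AbundanceRecord:
    """One marker-gene concentration measurement at one time point."""

    sample_id: str
    treatment: str
    replicate: int
    day: float
    phase: str
    gene: str
    copies_per_g_dw: float
    n_pos_droplets: int = -1
    n_total_droplets: int = -1


@dataclass
class RunConfig:
    """End-to-end pipeline run: inputs, knobs, seed, output directory."""

    outdir: Path
    seed: int = 1
    abundance_path: Path | None = None  # None -> simulate
    otu_path: Path | None = None
    tax_path: Path | None = None
    meta_path: Path | None = None
    experiment: SyntheticExperimentConfig | None = None
    breakpoint_day: float = 15.0
    search_breakpoint: bool = False
    copies_per_cell: float = 4.0
    group_col: str = "group"
    n_permutations: int = 999


def config_hash(obj: Any) -> str:
    """Short stable hash of a configuration object (for file provenance)."""
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


def _read_table(path: Path | str, **kwargs) -> pd.DataFrame:
    """Read a delimited file, skipping ``# ``-prefixed comment lines but
    keeping a ``#OTU ID`` style header line."""
    text = Path(path).read_text()
    kept = [ln for ln in text.splitlines() if not ln.startswith("# ")]
    return pd.read_csv(_io.StringIO("\n".join(kept)), **kwargs)


def _comment_header(meta: dict[str, Any]) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_abundance_table(
    abundance: pd.DataFrame, path: Path | str, meta: dict[str, Any] | None = None
) -> None:
    path = Path(path)
    cols = [c for c in ABUNDANCE_COLUMNS if c in abundance.columns]
    cols += [c for c in abundance.columns if c not in cols]
    with path.open("w") as fh:
        if meta:
            fh.write(_comment_header(meta))
        abundance[cols].to_csv(fh, index=False)


def read_abundance_table(path: Path | str) -> pd.DataFrame:
    """Read and validate a long-format abundance CSV.

    Enforces: required columns present, concentrations numeric and
    non-negative, known phase/gene labels, and uniqueness of the
    (treatment, replicate, day, gene) key.
    """
    df = _read_table(path)
    missing = set(ABUNDANCE_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    conc = pd.to_numeric(df["copies_per_g_dw"], errors="coerce")
    if conc.isna().any():
        bad = df.loc[conc.isna(), "sample_id"].tolist()[:5]
        raise ValueError(f"non-numeric copies_per_g_dw for samples {bad}")
    df["copies_per_g_dw"] = conc
    if (conc < 0).any():
        raise ValueError("copies_per_g_dw must be non-negative")
    unknown_phase = set(df["phase"]) - _PHASES
    if unknown_phase:
        raise ValueError(f"unknown phase labels: {sorted(unknown_phase)}")
    unknown_gene = set(df["gene"]) - _GENES
    if unknown_gene:
        raise ValueError(f"unknown gene labels: {sorted(unknown_gene)}")
    dupes = df.duplicated(subset=_KEY_COLUMNS, keep=False)
    if dupes.any():
        key = df.loc[dupes, _KEY_COLUMNS].iloc[0].tolist()
        raise ValueError(
            f"duplicate (treatment, replicate, day, gene) key: {key}"
        )
    return df


def abundance_records(df: pd.DataFrame) -> list[AbundanceRecord]:
    """Typed view of an abundance table's rows."""
    names = {f.name for f in fields(AbundanceRecord)}
    return [
        AbundanceRecord(**{k: v for k, v in row.items() if k in names})
        for row in df.to_dict(orient="records")
    ]


def write_otu_inputs(
    table: OtuTable,
    otu_path: Path | str,
    tax_path: Path | str,
    meta_path: Path | str,
    meta: dict[str, Any] | None = None,
) -> None:
    header = _comment_header(meta) if meta else ""
    with Path(otu_path).open("w") as fh:
        fh.write(header)
        out = table.counts.copy()
        out.index.name = "#OTU ID"
        out.to_csv(fh, sep="\t")
    with Path(tax_path).open("w") as fh:
        fh.write(header)
        fh.write("otu_id\tlineage\n")
        for otu in table.otu_ids:
            fh.write(f"{otu}\t{table.taxonomy[otu]}\n")
    with Path(meta_path).open("w") as fh:
        fh.write(header)
        table.metadata.rename_axis("sample_id").to_csv(fh, sep="\t")


def read_otu_inputs(
    otu_path: Path | str, tax_path: Path | str, meta_path: Path | str
) -> OtuTable:
    """Read OTU counts + taxonomy + sample metadata and cross-validate.

    Every sample column must have metadata and every OTU a lineage;
    counts must be non-negative integers.
    """
    counts = _read_table(otu_path, sep="\t", index_col=0)
    counts.index.name = "otu_id"
    tax = _read_table(tax_path, sep="\t")
    if not {"otu_id", "lineage"} <= set(tax.columns):
        raise ValueError("taxonomy table needs otu_id and lineage columns")
    taxonomy = dict(zip(tax["otu_id"], tax["lineage"]))
    metadata = _read_table(meta_path, sep="\t").set_index("sample_id")
    orphan_otus = [o for o in counts.index if o not in taxonomy]
    if orphan_otus:
        raise ValueError(f"OTUs missing from taxonomy: {orphan_otus[:5]}")
    orphan_samples = [s for s in counts.columns if s not in metadata.index]
    if orphan_samples:
        raise ValueError(f"samples missing from metadata: {orphan_samples[:5]}")
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"non-numeric counts in sample {col!r}")
        if (vals < 0).any() or not (vals == vals.round()).all():
            raise ValueError(f"negative or fractional counts in sample {col!r}")
    return OtuTable(counts=counts.astype(int), taxonomy=taxonomy, metadata=metadata)


def read_experiment_config(path: Path | str) -> SyntheticExperimentConfig:
    """Load a synthetic-experiment config from YAML (missing keys default)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(SyntheticExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("treatments", "sampling_days"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticExperimentConfig(**raw)


def read_run_config(path: Path | str) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "experiment" in raw and raw["experiment"] is not None:
        exp = raw["experiment"]
        for key in ("treatments", "sampling_days"):
            if key in exp:
                exp[key] = tuple(exp[key])
        raw["experiment"] = SyntheticExperimentConfig(**exp)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    for key in ("outdir", "abundance_path", "otu_path", "tax_path", "meta_path"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    return RunConfig(**raw)


def write_ground_truth(bundle, path: Path | str) -> None:
    """Structured ground-truth sidecar (JSON) for a simulated experiment."""
    payload = {
        "true_d_values": bundle.true_d_values,
        "true_sp": bundle.true_sp.to_dict(orient="records"),
        "template_phylum_proportions": bundle.template_phylum_proportions,
        "seed": bundle.config.seed,
        "config_hash": config_hash(bundle.config),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
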