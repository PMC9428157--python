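"""Spread potential (SP): transconjugants per recipient from ddPCR counts.

The statistic combines three absolute concentrations (copies per gram dry
weight): ``gfp`` counts every plasmid copy, ``dsRed`` counts donor cells,
and the 16S rRNA gene pool divided by a per-cell copy number approximates
total bacteria. Assuming one plasmid per donor,

    SP = (C_gfp - C_dsRed) / (C_16S / copies_per_cell - C_dsRed)

so the numerator counts transconjugants and the denominator recipients.
The divisor defaults to 4; rRNA-database surveys put the average closer to
4.1, and both are supported (the choice moves SP by well under 3% whenever
recipients vastly outnumber donors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpreadPotentialResult", "spread_potential", "sp_timeseries", "sp_summary"]


@dataclass(frozen=True)
class SpreadPotentialResult:
    """SP for one sample, with the three input concentrations and flags.

    ``sp`` is NaN when the recipient denominator is non-positive
    (flag ``invalid_denominator``). A negative numerator — measurement noise
    when ``gfp`` and ``dsRed`` are near equal — is clamped to zero and
    flagged ``negative_numerator_clamped``.
    """

    sample_id: str
    c_gfp: float
    c_dsred: float
    c_16s: float
    copies_per_cell: float
    sp: float
    flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return not math.isnan(self.sp)


def spread_potential(
    c_gfp: float,
    c_dsred: float,
    c_16s: float,
    copies_per_cell: float = 4.0,
    *,
    sample_id: str = "",
) -> SpreadPotentialResult:
    """Compute SP = (C_gfp - C_dsRed) / (C_16S/copies_per_cell - C_dsRed)."""
    if copies_per_cell <= 0:
        raise ValueError("copies_per_cell must be positive")
    if min(c_gfp, c_dsred, c_16s) < 0:
        raise ValueError("concentrations must be non-negative")
    flags: list[str] = []
    numerator = c_gfp - c_dsred
    if numerator < 0:
        numerator = 0.0
        flags.append("negative_numerator_clamped")
    denominator = c_16s / copies_per_cell - c_dsred
    if denominator <= 0:
        flags.append("invalid_denominator")
        sp = float("nan")
    else:
        sp = numerator / denominator
    return SpreadPotentialResult(
        sample_id=sample_id,
        c_gfp=c_gfp,
        c_dsred=c_dsred,
        c_16s=c_16s,
        copies_per_cell=copies_per_cell,
        sp=sp,
        flags=tuple(flags),
    )


def sp_timeseries(
    abundance: pd.DataFrame,
    copies_per_cell: float = 4.0,
    *,
    gene_labels: tuple[str, str, str] = ("gfp", "dsRed", "16S"),
) -> pd.DataFrame:
    """Per-sample SP over time from a long-format abundance table.

    Expects columns ``treatment``, ``replicate``, ``day``, ``gene``,
    ``copies_per_g_dw``. Every (treatment, replicate, day) must carry all
    three marker genes; a sample missing one is kept in the output with
    ``sp = NaN`` and flag ``missing_gene:<name>`` rather than silently
    dropped. Returns a frame ordered by (treatment, day, replicate).
    """
    gfp_label, dsred_label, s16_label = gene_labels
    required = {"treatment", "replicate", "day", "gene", "copies_per_g_dw"}
    missing = required - set(abundance.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    rows = []
    for (treatment, replicate, day), sub in abundance.groupby(
        ["treatment", "replicate", "day"], sort=True
    ):
        conc = dict(zip(sub["gene"], sub["copies_per_g_dw"]))
        sid = f"{treatment}_r{replicate}_d{day}"
        absent = [g for g in gene_labels if g not in conc]
        if absent:
            rows.append({
                "sample_id": sid, "treatment": treatment, "replicate": replicate,
                "day": day, "c_gfp": np.nan, "c_dsred": np.nan, "c_16s": np.nan,
                "sp": np.nan,
                "flags": ";".join(f"missing_gene:{g}" for g in absent),
            })
            continue
        res = spread_potential(
            conc[gfp_label], conc[dsred_label], conc[s16_label],
            copies_per_cell, sample_id=sid,
        )
        rows.append({
            "sample_id": sid, "treatment": treatment, "replicate": replicate,
            "day": day, "c_gfp": res.c_gfp, "c_dsred": res.c_dsred,
            "c_16s": res.c_16s, "sp": res.sp, "flags": ";".join(res.flags),
        })
    out = pd.DataFrame(rows).sort_values(["treatment", "day", "replicate"])
    return out.reset_index(drop=True)


def sp_summary(sp_table: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment, per-day geometric mean SP across replicates.

    SP spans orders of magnitude, so replicate aggregation is geometric;
    zero or invalid SP values are excluded from the mean and counted in
    ``n_excluded``.
    """
    rows = []
    for (treatment, day), sub in sp_table.groupby(["treatment", "day"], sort=True):
        vals = sub["sp"].to_numpy(dtype=float)
        ok = vals[np.isfinite(vals) & (vals > 0)]
        rows.append({
            "treatment": treatment,
            "day": day,
            "sp_geomean": float(np.exp(np.mean(np.log(ok)))) if len(ok) else np.nan,
            "n": len(ok),
            "n_excluded": len(vals) - len(ok),
        })
    return pd.DataFrame(rows)
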