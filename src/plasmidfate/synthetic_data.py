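"""Synthetic composting experiments with known ground truth.

The generator emulates a donor-inoculation composting study: two treatments
(NT, normal thermophilic; CT, continuous/prolonged thermophilic), three
replicate reactors, marker genes ``dsRed`` (donor chromosome), ``gfp``
(plasmid) and ``16S`` (total bacteria) sampled on fixed days, and
FACS-sorted transconjugant pools sequenced per composting phase
(IP initial, TP thermophilic, MP mature).

Three layers of truth are produced:

1. *Trajectories* — piecewise log10-linear marker decay: a fast phase with
   decimal reduction time ``phase1_d_value`` up to ``breakpoint_day``, then
   either slow decay (``phase2_d_value``) or, for treatments listed in
   ``rebound``, log-linear regrowth. The 16S pool is held constant.
2. *ddPCR observations* — Poisson droplet occupancy: a droplet of volume
   ``v`` is positive with probability ``1 - exp(-lambda v)``; the
   concentration estimate inverts the observed positive fraction.
3. *Communities* — Dirichlet-multinomial OTU counts around per-group
   templates encoding a Firmicutes-dominated transconjugant pool (8 phyla)
   with a Proteobacteria rebound at maturation and lower richness under the
   prolonged thermophilic treatment.

Default trajectory parameters are calibrated so the ground-truth spread
potential runs from ``SP_INITIAL`` (3.91e-4 transconjugants per recipient in
the raw material) to ``SP_FINAL`` (2.54e-6 in the finished prolonged-phase
compost); see :func:`solve_trajectory_parameters`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from plasmidfate.community_analysis import OtuTable

__all__ = [
    "GENES",
    "SP_INITIAL",
    "SP_FINAL",
    "SyntheticExperimentConfig",
    "CommunityTemplate",
    "TrueTrajectory",
    "DdpcrObservation",
    "ExperimentBundle",
    "solve_trajectory_parameters",
    "default_community_template",
    "simulate_decay_trajectory",
    "true_log10_concentration",
    "true_spread_potential",
    "simulate_ddpcr",
    "ddpcr_estimate",
    "simulate_transconjugant_table",
    "make_experiment",
    "phase_of",
]

GENES = ("dsRed", "gfp", "16S")

# Measured initial marker concentrations (copies per g dry weight) and the
# spread-potential endpoints the defaults are calibrated to.
DONOR_C0 = 3.30e6
PLASMID_C0 = 1.04e7
SP_INITIAL = 3.91e-4
SP_FINAL = 2.54e-6


def solve_trajectory_parameters(
    sp_initial: float = SP_INITIAL,
    sp_final: float = SP_FINAL,
    *,
    donor_c0: float = DONOR_C0,
    plasmid_c0: float = PLASMID_C0,
    phase1_d_value: float = 7.0,
    breakpoint_day: float = 15.0,
    final_day: float = 40.0,
    copies_per_cell: float = 4.0,
) -> tuple[float, float]:
    """Return ``(total_16s_c0, phase2_d_value)`` hitting given SP endpoints.

    With both marker genes decaying at the same rate and a constant 16S
    pool, SP(0) fixes the 16S concentration and SP(final_day) fixes the
    phase-II decimal reduction time (closed form).
    """
    if not 0 < sp_final < sp_initial:
        raise ValueError("need 0 < sp_final < sp_initial")
    diff0 = plasmid_c0 - donor_c0
    if diff0 <= 0:
        raise ValueError("plasmid_c0 must exceed donor_c0")
    denom0 = diff0 / sp_initial
    total_16s_c0 = copies_per_cell * (denom0 + donor_c0)
    # u = total log10 survival fraction at final_day, solved from SP(final)
    u = sp_final * (denom0 + donor_c0) / (diff0 + sp_final * donor_c0)
    drop_total = -math.log10(u)
    drop_phase2 = drop_total - breakpoint_day / phase1_d_value
    if drop_phase2 <= 0:
        raise ValueError(
            "phase-I decay alone overshoots sp_final; increase phase1_d_value"
        )
    phase2_d_value = (final_day - breakpoint_day) / drop_phase2
    return total_16s_c0, phase2_d_value


_TOTAL_16S_C0, _PHASE2_D_VALUE = solve_trajectory_parameters()


# ---------------------------------------------------------------------------
# Community templates
# ---------------------------------------------------------------------------

@dataclass
class CommunityTemplate:
    """Expected OTU proportions per sample group, with taxonomy lineages.

    The taxa are a synthetic composite community: the dominant genera carry
    real names typical of composting transconjugant pools (Bacillaceae-family
    Firmicutes, halophilic/thermophilic Proteobacteria) while the rare tail
    uses synthetic placeholder genera. Per-group proportions sum to 1.
    """

    proportions: dict[str, dict[str, float]]  # group -> otu_id -> proportion
    taxonomy: dict[str, str]  # otu_id -> lineage string

    def validate(self) -> None:
        for group, props in self.proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {group!r} proportions sum to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"group {group!r} has negative proportions")
            missing = [o for o in props if o not in self.taxonomy]
            if missing:
                raise ValueError(f"template OTUs without taxonomy: {missing[:5]}")

    def phylum_proportions(self, group: str) -> dict[str, float]:
        from plasmidfate.community_analysis import parse_lineage

        out: dict[str, float] = {}
        for otu, p in self.proportions[group].items():
            phylum = parse_lineage(self.taxonomy[otu])["phylum"]
            out[phylum] = out.get(phylum, 0.0) + p
        return out


# genus label -> (phylum, class, order, family, genus-field-or-empty)
_NAMED_GENERA: dict[str, tuple[str, str, str, str, str]] = {
    "Oceanobacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Oceanobacillus"),
    "Bacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus"),
    "Bacillaceae": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", ""),
    "Sinibacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Sinibacillus"),
    "Staphylococcus": ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    "Solibacillus": ("Firmicutes", "Bacilli", "Bacillales", "Planococcaceae", "Solibacillus"),
    "Atopostipes": ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae", "Atopostipes"),
    "Amphibacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Amphibacillus"),
    "Cerasibacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Cerasibacillus"),
    "Pseudogracilibacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Pseudogracilibacillus"),
    "Anaerobacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Anaerobacillus"),
    "Marinococcaceae": ("Firmicutes", "Bacilli", "Bacillales", "Marinococcaceae", ""),
    "Halocella": ("Halanaerobiaeota", "Halanaerobiia", "Halanaerobiales", "Halanaerobiaceae", "Halocella"),
    "Halomonas": ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Halomonadaceae", "Halomonas"),
    "Pseudomonas": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    "Escherichia-Shigella": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia-Shigella"),
    "Burkholderia": ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Burkholderia"),
    "Paracoccus": ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Paracoccus"),
    "Fodinicurvataceae": ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Fodinicurvataceae", ""),
    "Ellin6055": ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Ellin6055"),
    "Rubellimicrobium": ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Rubellimicrobium"),
    "Corynebacterium": ("Actinobacteriota", "Actinobacteria", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium"),
    "Saccharomonospora": ("Actinobacteriota", "Actinobacteria", "Pseudonocardiales", "Pseudonocardiaceae", "Saccharomonospora"),
    "Thermobifida": ("Actinobacteriota", "Actinobacteria", "Streptosporangiales", "Nocardiopsaceae", "Thermobifida"),
    "Sphingobacterium": ("Bacteroidota", "Sphingobacteriia", "Sphingobacteriales", "Sphingobacteriaceae", "Sphingobacterium"),
    "Flavobacterium": ("Bacteroidota", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Flavobacterium"),
    "Truepera": ("Deinococcota", "Deinococci", "Deinococcales", "Trueperaceae", "Truepera"),
}

# number of 97%-identity OTUs assigned to each named genus (others get 1)
_OTUS_PER_GENUS = {"Bacillus": 3, "Oceanobacillus": 2, "Bacillaceae": 2}
_OTU_SPLIT = {1: (1.0,), 2: (0.75, 0.25), 3: (0.65, 0.25, 0.10)}

_FILLER_POOL_SIZES = {
    "Firmicutes": 105, "Proteobacteria": 40, "Actinobacteriota": 20,
    "Bacteroidota": 10, "Halanaerobiaeota": 4, "Cyanobacteria": 4,
    "Myxococcota": 4, "Deinococcota": 3,
}

# per group: phylum -> total expected proportion (sums to 1)
_PHYLUM_TOTALS = {
    "IP": {"Firmicutes": 0.780, "Proteobacteria": 0.100, "Actinobacteriota": 0.060,
           "Halanaerobiaeota": 0.030, "Bacteroidota": 0.015, "Cyanobacteria": 0.005,
           "Myxococcota": 0.005, "Deinococcota": 0.005},
    "NT-TP": {"Firmicutes": 0.901, "Proteobacteria": 0.043, "Actinobacteriota": 0.030,
              "Halanaerobiaeota": 0.010, "Bacteroidota": 0.008, "Cyanobacteria": 0.003,
              "Myxococcota": 0.003, "Deinococcota": 0.002},
    "NT-MP": {"Firmicutes": 0.753, "Proteobacteria": 0.168, "Actinobacteriota": 0.040,
              "Halanaerobiaeota": 0.0, "Bacteroidota": 0.020, "Cyanobacteria": 0.007,
              "Myxococcota": 0.007, "Deinococcota": 0.005},
    "CT-TP": {"Firmicutes": 0.880, "Proteobacteria": 0.082, "Actinobacteriota": 0.020,
              "Halanaerobiaeota": 0.005, "Bacteroidota": 0.005, "Cyanobacteria": 0.003,
              "Myxococcota": 0.003, "Deinococcota": 0.002},
    "CT-MP": {"Firmicutes": 0.753, "Proteobacteria": 0.222, "Actinobacteriota": 0.015,
              "Halanaerobiaeota": 0.0, "Bacteroidota": 0.003, "Cyanobacteria": 0.003,
              "Myxococcota": 0.002, "Deinococcota": 0.002},
}

# per group: named genus -> expected proportion (dominant-genus anchors)
_NAMED_PROPORTIONS = {
    "IP": {"Oceanobacillus": 0.2741, "Bacillus": 0.100, "Bacillaceae": 0.080,
           "Atopostipes": 0.050, "Sinibacillus": 0.040, "Amphibacillus": 0.030,
           "Cerasibacillus": 0.030, "Solibacillus": 0.030, "Staphylococcus": 0.030,
           "Halocella": 0.025, "Pseudomonas": 0.030, "Escherichia-Shigella": 0.020,
           "Halomonas": 0.015, "Burkholderia": 0.008, "Corynebacterium": 0.030,
           "Sphingobacterium": 0.008, "Truepera": 0.002},
    "NT-TP": {"Bacillaceae": 0.1966, "Bacillus": 0.180, "Oceanobacillus": 0.150,
              "Sinibacillus": 0.060, "Pseudogracilibacillus": 0.030,
              "Anaerobacillus": 0.020, "Staphylococcus": 0.020, "Halocella": 0.008,
              "Halomonas": 0.010, "Fodinicurvataceae": 0.010, "Paracoccus": 0.008,
              "Saccharomonospora": 0.012, "Thermobifida": 0.008},
    "NT-MP": {"Bacillus": 0.4841, "Oceanobacillus": 0.0966, "Bacillaceae": 0.0592,
              "Sinibacillus": 0.0307, "Staphylococcus": 0.0307, "Halomonas": 0.0765,
              "Fodinicurvataceae": 0.0341, "Paracoccus": 0.0150, "Ellin6055": 0.0120,
              "Rubellimicrobium": 0.0100, "Corynebacterium": 0.0100},
    "CT-TP": {"Bacillus": 0.4466, "Oceanobacillus": 0.180, "Bacillaceae": 0.120,
              "Sinibacillus": 0.050, "Pseudogracilibacillus": 0.020, "Halocella": 0.004,
              "Halomonas": 0.030, "Fodinicurvataceae": 0.020, "Paracoccus": 0.012,
              "Saccharomonospora": 0.008},
    "CT-MP": {"Oceanobacillus": 0.3023, "Bacillaceae": 0.1363, "Bacillus": 0.1265,
              "Sinibacillus": 0.0549, "Marinococcaceae": 0.0372,
              "Fodinicurvataceae": 0.0637, "Halomonas": 0.0400, "Ellin6055": 0.0300,
              "Paracoccus": 0.0285, "Rubellimicrobium": 0.0250},
}

# template richness targets (observed-OTU counts the groups are built toward;
# prolonged thermophilic groups are species-poorer than NT ones)
_RICHNESS_TARGETS = {"IP": 80, "NT-TP": 130, "NT-MP": 88, "CT-TP": 62, "CT-MP": 67}

GROUPS = tuple(_PHYLUM_TOTALS)

_PHYLUM_CLASS = {
    "Firmicutes": ("Bacilli", "Bacillales"),
    "Proteobacteria": ("Alphaproteobacteria", "Rhodospirillales"),
    "Actinobacteriota": ("Actinobacteria", "Micrococcales"),
    "Bacteroidota": ("Bacteroidia", "Chitinophagales"),
    "Halanaerobiaeota": ("Halanaerobiia", "Halanaerobiales"),
    "Cyanobacteria": ("Cyanobacteriia", "Chloroplast"),
    "Myxococcota": ("Polyangia", "Polyangiales"),
    "Deinococcota": ("Deinococci", "Deinococcales"),
}


def _lineage(phylum: str, class_: str, order: str, family: str, genus: str) -> str:
    return (
        f"k__Bacteria;p__{phylum};c__{class_};o__{order};"
        f"f__{family};g__{genus}"
    )


def _build_registry() -> tuple[dict[str, str], dict[str, list[str]], dict[str, list[str]]]:
    """OTU registry: taxonomy, OTUs per named genus, filler OTUs per phylum."""
    taxonomy: dict[str, str] = {}
    named_otus: dict[str, list[str]] = {}
    idx = 0
    for label, (phylum, cls, order, family, genus) in _NAMED_GENERA.items():
        n = _OTUS_PER_GENUS.get(label, 1)
        otus = []
        for _ in range(n):
            idx += 1
            otu = f"OTU{idx:04d}"
            taxonomy[otu] = _lineage(phylum, cls, order, family, genus)
            otus.append(otu)
        named_otus[label] = otus
    fillers: dict[str, list[str]] = {}
    for phylum, size in _FILLER_POOL_SIZES.items():
        cls, order = _PHYLUM_CLASS[phylum]
        pool = []
        for k in range(1, size + 1):
            idx += 1
            otu = f"OTU{idx:04d}"
            family = f"{phylum[:5]}_family_{(k - 1) // 4 + 1:02d}"
            genus = f"{phylum[:5]}_genus_{k:03d}"
            taxonomy[otu] = _lineage(phylum, cls, order, family, genus)
            pool.append(otu)
        fillers[phylum] = pool
    return taxonomy, named_otus, fillers


def _allocate(total: int, weights: Mapping[str, float], caps: Mapping[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` slots, capped per key."""
    keys = [k for k in weights if weights[k] > 0 and caps.get(k, 0) > 0]
    wsum = sum(weights[k] for k in keys)
    raw = {k: total * weights[k] / wsum for k in keys}
    out = {k: min(int(raw[k]), caps[k]) for k in keys}
    while sum(out.values()) < total:
        candidates = [k for k in keys if out[k] < caps[k]]
        if not candidates:
            break
        k = max(candidates, key=lambda k: raw[k] - out[k])
        out[k] += 1
    return out


def default_community_template() -> CommunityTemplate:
    """Build the default five-group transconjugant community template.

    Dominant genera are anchored at their printed-composition proportions;
    the remaining mass in each phylum is spread over a rare tail whose size
    per group follows the richness targets, with log-spaced tail weights
    spanning 1.5 decades. Tail membership is rotated between groups so the
    groups share a realistic core of taxa without being identical.
    """
    taxonomy, named_otus, fillers = _build_registry()
    proportions: dict[str, dict[str, float]] = {}
    for gi, group in enumerate(GROUPS):
        props: dict[str, float] = {}
        named = _NAMED_PROPORTIONS[group]
        named_by_phylum: dict[str, float] = {}
        n_named_otus = 0
        for label, p in named.items():
            phylum = _NAMED_GENERA[label][0]
            named_by_phylum[phylum] = named_by_phylum.get(phylum, 0.0) + p
            otus = named_otus[label]
            for otu, w in zip(otus, _OTU_SPLIT[len(otus)]):
                props[otu] = p * w
            n_named_otus += len(otus)
        tail_mass = {
            ph: _PHYLUM_TOTALS[group][ph] - named_by_phylum.get(ph, 0.0)
            for ph in _PHYLUM_TOTALS[group]
        }
        for ph, m in tail_mass.items():
            if m < -1e-12:
                raise ValueError(f"named proportions exceed phylum total for {ph} in {group}")
        n_tail = max(_RICHNESS_TARGETS[group] - n_named_otus, 0)
        caps = {ph: len(fillers[ph]) for ph in fillers}
        counts = _allocate(n_tail, tail_mass, caps)
        for ph, k in counts.items():
            if k == 0 or tail_mass[ph] <= 0:
                continue
            pool = fillers[ph]
            offset = (gi * 7) % len(pool)
            chosen = [pool[(offset + j) % len(pool)] for j in range(k)]
            weights = np.power(10.0, -1.5 * np.arange(k) / max(k - 1, 1))
            weights *= tail_mass[ph] / weights.sum()
            for otu, w in zip(chosen, weights):
                props[otu] = props.get(otu, 0.0) + float(w)
        total = sum(props.values())
        props = {o: p / total for o, p in props.items() if p > 0}
        proportions[group] = props
    template = CommunityTemplate(proportions=proportions, taxonomy=taxonomy)
    template.validate()
    return template


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperimentConfig:
    """Full parameterization of a simulated composting experiment.

    Concentrations are gene copies per gram dry weight. ``phase1_d_value``
    governs decay up to ``breakpoint_day`` (inclusive); afterwards
    treatments in ``rebound`` regrow log-linearly at the mapped rate
    (log10/day) while the rest decay with ``phase2_d_value``.
    ``dilution_to_droplet`` converts copies/g DW to copies/uL in the
    droplet reaction, per gene (the 16S assay is diluted far more).
    """

    treatments: tuple[str, ...] = ("NT", "CT")
    sampling_days: tuple[float, ...] = (0, 1, 4, 7, 11, 15, 19, 27, 40)
    treatment_end_day: dict[str, float] = field(
        default_factory=lambda: {"NT": 27.0, "CT": 40.0})
    tp_end_day: dict[str, float] = field(
        default_factory=lambda: {"NT": 11.0, "CT": 27.0})
    n_replicates: int = 3
    donor_c0: float = DONOR_C0
    plasmid_c0: float = PLASMID_C0
    total_16s_c0: float = _TOTAL_16S_C0
    phase1_d_value: float = 7.0
    phase2_d_value: float = _PHASE2_D_VALUE
    breakpoint_day: float = 15.0
    rebound: dict[str, float] = field(default_factory=lambda: {"NT": 0.02})
    replicate_sigma_log10: float = 0.1
    ddpcr_n_droplets: int = 20_000
    ddpcr_droplet_volume_ul: float = 8.5e-4
    dilution_to_droplet: dict[str, float] = field(
        default_factory=lambda: {"dsRed": 1e-4, "gfp": 1e-4, "16S": 2e-8})
    community_template: CommunityTemplate | None = None
    dm_concentration: float = 500.0
    seq_depth: int = 60_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.community_template is None:
            self.community_template = default_community_template()
        self.validate()

    def validate(self) -> None:
        for name in ("donor_c0", "plasmid_c0", "total_16s_c0", "phase1_d_value",
                     "phase2_d_value", "dm_concentration",
                     "ddpcr_droplet_volume_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        days = tuple(self.sampling_days)
        if len(days) < 2 or days[0] != 0:
            raise ValueError("sampling_days must start at 0 with >= 2 days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be strictly increasing")
        if self.n_replicates < 1 or self.seq_depth < 1 or self.ddpcr_n_droplets < 1:
            raise ValueError("n_replicates, seq_depth and ddpcr_n_droplets must be >= 1")
        if self.replicate_sigma_log10 < 0:
            raise ValueError("replicate_sigma_log10 must be >= 0")
        for t in self.treatments:
            if t not in self.treatment_end_day or t not in self.tp_end_day:
                raise ValueError(f"treatment {t!r} missing phase boundaries")
        for gene in GENES:
            if self.dilution_to_droplet.get(gene, 0) <= 0:
                raise ValueError(f"dilution_to_droplet missing/invalid for {gene!r}")
        self.community_template.validate()
        needed = {"IP"} | {
            f"{t}-{ph}" for t in self.treatments for ph in ("TP", "MP")
        }
        missing = needed - set(self.community_template.proportions)
        if missing:
            raise ValueError(f"community template missing groups: {sorted(missing)}")

    def days_for(self, treatment: str) -> tuple[float, ...]:
        if treatment not in self.treatments:
            raise ValueError(f"unknown treatment {treatment!r}")
        end = self.treatment_end_day[treatment]
        return tuple(d for d in self.sampling_days if d <= end)


def phase_of(config: SyntheticExperimentConfig, treatment: str, day: float) -> str:
    """Composting phase label: IP on day 0, TP up to the thermophilic-phase
    end day (inclusive), MP afterwards."""
    if day == 0:
        return "IP"
    return "TP" if day <= config.tp_end_day[treatment] else "MP"


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueTrajectory:
    """Noise-free marker trajectory for one (treatment, gene)."""

    treatment: str
    gene: str
    days: tuple[float, ...]
    log10_concentration: tuple[float, ...]

    def concentration(self, day: float) -> float:
        try:
            i = self.days.index(day)
        except ValueError as exc:
            raise KeyError(f"day {day} not in trajectory") from exc
        return 10.0 ** self.log10_concentration[i]


def true_log10_concentration(
    config: SyntheticExperimentConfig, treatment: str, gene: str, day: float
) -> float:
    """Piecewise-linear log10 concentration of a marker gene at ``day``."""
    if treatment not in config.treatments:
        raise ValueError(f"unknown treatment {treatment!r}")
    if gene not in GENES:
        raise ValueError(f"unknown gene {gene!r}")
    if day < 0:
        raise ValueError("day must be >= 0")
    c0 = {"dsRed": config.donor_c0, "gfp": config.plasmid_c0,
          "16S": config.total_16s_c0}[gene]
    if gene == "16S":  # total bacterial pool held constant
        return math.log10(c0)
    bp = config.breakpoint_day
    log_c = math.log10(c0) - min(day, bp) / config.phase1_d_value
    if day > bp:
        if treatment in config.rebound:
            log_c += config.rebound[treatment] * (day - bp)
        else:
            log_c -= (day - bp) / config.phase2_d_value
    return log_c


def simulate_decay_trajectory(
    config: SyntheticExperimentConfig, treatment: str, gene: str
) -> TrueTrajectory:
    """Ground-truth trajectory over the treatment's sampling days."""
    days = config.days_for(treatment)
    logs = tuple(
        true_log10_concentration(config, treatment, gene, d) for d in days
    )
    return TrueTrajectory(treatment=treatment, gene=gene, days=days,
                          log10_concentration=logs)


def true_spread_potential(
    config: SyntheticExperimentConfig, treatment: str, day: float,
    copies_per_cell: float = 4.0,
) -> float:
    """Ground-truth SP at ``day`` from the noise-free trajectories."""
    c_gfp = 10.0 ** true_log10_concentration(config, treatment, "gfp", day)
    c_dsred = 10.0 ** true_log10_concentration(config, treatment, "dsRed", day)
    c_16s = 10.0 ** true_log10_concentration(config, treatment, "16S", day)
    return (c_gfp - c_dsred) / (c_16s / copies_per_cell - c_dsred)


# ---------------------------------------------------------------------------
# ddPCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdpcrObservation:
    """One simulated ddPCR measurement.

    ``flag`` is ``"saturated"`` when every droplet is positive (the Poisson
    inversion is undefined and the estimate is NaN) and
    ``"below_detection"`` when none is (estimate 0).
    """

    n_positive: int
    n_total: int
    estimated_concentration: float
    true_concentration: float
    flag: str = ""


def ddpcr_estimate(
    n_positive: int, n_total: int, droplet_volume_ul: float, dilution: float = 1.0
) -> float:
    """Poisson inversion of a droplet count: ``-ln(1 - p_hat) / v``, scaled
    back to sample units by ``dilution``. Undefined (NaN) at saturation."""
    if not 0 <= n_positive <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_positive <= n_total, n_total >= 1")
    if n_positive == n_total:
        return float("nan")
    lam_hat = -math.log(1.0 - n_positive / n_total) / droplet_volume_ul
    return lam_hat / dilution


def simulate_ddpcr(
    true_concentration: float,
    config: SyntheticExperimentConfig,
    seed: int | np.random.Generator | None = None,
    *,
    gene: str = "dsRed",
) -> DdpcrObservation:
    """Simulate droplet digital PCR of a sample at ``true_concentration``.

    Each of ``ddpcr_n_droplets`` droplets of volume ``v`` uL is positive
    independently with probability ``1 - exp(-lambda v)``, where ``lambda``
    is the per-uL template concentration after dilution. The estimator
    inverts the positive fraction: ``lambda_hat = -ln(1 - p_hat) / v``,
    rescaled back to copies/g DW.
    """
    if true_concentration <= 0:
        raise ValueError("true_concentration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = config.ddpcr_droplet_volume_ul
    dilution = config.dilution_to_droplet[gene]
    lam = true_concentration * dilution
    p = 1.0 - math.exp(-lam * v)
    n = config.ddpcr_n_droplets
    n_pos = int(rng.binomial(n, p))
    if n_pos == n:
        return DdpcrObservation(n_pos, n, float("nan"), true_concentration, "saturated")
    if n_pos == 0:
        return DdpcrObservation(n_pos, n, 0.0, true_concentration, "below_detection")
    est = ddpcr_estimate(n_pos, n, v, dilution)
    return DdpcrObservation(n_pos, n, est, true_concentration, "")


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def simulate_transconjugant_table(
    config: SyntheticExperimentConfig,
    seed: int | np.random.Generator | None = None,
) -> OtuTable:
    """Dirichlet-multinomial OTU counts for every (group, replicate) sample.

    Per sample, proportions are drawn from a Dirichlet with mean equal to
    the group template and precision ``dm_concentration``, then
    ``seq_depth`` reads are drawn multinomially. Column sums therefore
    equal ``seq_depth`` exactly, and the same seed reproduces the table.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = config.community_template
    groups = ["IP"] + [
        f"{t}-{ph}" for t in config.treatments for ph in ("TP", "MP")
    ]
    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    all_otus = sorted(template.taxonomy)
    otu_index = {o: i for i, o in enumerate(all_otus)}
    for group in groups:
        if group not in template.proportions:
            raise ValueError(f"community template missing group {group!r}")
        props = template.proportions[group]
        otus = list(props)
        alpha = np.array([props[o] for o in otus]) * config.dm_concentration
        for r in range(1, config.n_replicates + 1):
            p = rng.dirichlet(alpha)
            draw = rng.multinomial(config.seq_depth, p)
            col = np.zeros(len(all_otus), dtype=int)
            for o, c in zip(otus, draw):
                col[otu_index[o]] = c
            sid = f"{group.replace('-', '_')}_r{r}"
            counts[sid] = col
            treatment, _, phase = group.partition("-")
            meta_rows.append({
                "sample_id": sid,
                "treatment": treatment if phase else "raw",
                "phase": phase or "IP",
                "replicate": r,
                "group": group,
            })
    counts_df = pd.DataFrame(counts, index=all_otus)
    keep = counts_df.sum(axis=1) > 0
    counts_df = counts_df[keep]
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return OtuTable(counts=counts_df, taxonomy=dict(template.taxonomy),
                    metadata=metadata)


# ---------------------------------------------------------------------------
# Whole experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentBundle:
    """A complete simulated experiment plus its recoverable ground truth."""

    abundance: pd.DataFrame
    otu_table: OtuTable | None
    true_d_values: dict[str, dict[str, dict[str, float]]]
    true_sp: pd.DataFrame
    true_trajectories: dict[tuple[str, str], TrueTrajectory]
    template_phylum_proportions: dict[str, dict[str, float]]
    config: SyntheticExperimentConfig


def make_experiment(
    config: SyntheticExperimentConfig, include_community: bool = True
) -> ExperimentBundle:
    """Simulate abundances, communities, and bundle the ground truth.

    One abundance record is produced per (treatment, replicate, sampling
    day, gene), each combining replicate-level lognormal biological
    variation (``replicate_sigma_log10``) with a droplet-level ddPCR
    observation. Everything derives from ``config.seed``.
    """
    master = np.random.default_rng(config.seed)
    abundance_rng = np.random.default_rng(master.integers(2**31))
    community_rng = np.random.default_rng(master.integers(2**31))

    rows = []
    trajectories: dict[tuple[str, str], TrueTrajectory] = {}
    for treatment in config.treatments:
        for gene in GENES:
            trajectories[(treatment, gene)] = simulate_decay_trajectory(
                config, treatment, gene)
        for day in config.days_for(treatment):
            for rep in range(1, config.n_replicates + 1):
                for gene in GENES:
                    true_log = true_log10_concentration(config, treatment, gene, day)
                    noisy = 10.0 ** (
                        true_log
                        + abundance_rng.normal(0.0, config.replicate_sigma_log10)
                    )
                    obs = simulate_ddpcr(noisy, config, abundance_rng, gene=gene)
                    rows.append({
                        "sample_id": f"{treatment}_r{rep}_d{day:g}",
                        "treatment": treatment,
                        "replicate": rep,
                        "day": day,
                        "phase": phase_of(config, treatment, day),
                        "gene": gene,
                        "copies_per_g_dw": obs.estimated_concentration,
                        "n_pos_droplets": obs.n_positive,
                        "n_total_droplets": obs.n_total,
                        "flag": obs.flag,
                    })
    abundance = pd.DataFrame(rows)

    otu_table = (
        simulate_transconjugant_table(config, community_rng)
        if include_community else None
    )

    d2 = {
        t: (float("inf") if t in config.rebound else config.phase2_d_value)
        for t in config.treatments
    }
    true_d_values = {
        t: {
            gene: {"phase I": config.phase1_d_value, "phase II": d2[t]}
            for gene in ("dsRed", "gfp")
        }
        for t in config.treatments
    }
    sp_rows = [
        {"treatment": t, "day": d, "sp": true_spread_potential(config, t, d)}
        for t in config.treatments for d in config.days_for(t)
    ]
    return ExperimentBundle(
        abundance=abundance,
        otu_table=otu_table,
        true_d_values=true_d_values,
        true_sp=pd.DataFrame(sp_rows),
        true_trajectories=trajectories,
        template_phylum_proportions={
            g: config.community_template.phylum_proportions(g)
            for g in config.community_template.proportions
        },
        config=config,
    )
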