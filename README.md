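# plasmidfate

Quantitative analysis of the fate of a conjugative multidrug-resistance
plasmid during manure composting: decay kinetics of a fluorescently tagged
donor strain and its plasmid, the plasmid's *spread potential* among
indigenous bacteria, and the community structure of FACS-sorted
transconjugant pools.

## Who this is for

Researchers studying antibiotic-resistance-gene dissemination in organic
waste treatment, who track a *dsRed*-tagged donor (*Pseudomonas putida*
carrying a *gfp*-tagged broad-host-range plasmid such as RP4) through
composting with droplet digital PCR (ddPCR) and profile the plasmid's
recipient community by cell sorting plus 16S rRNA amplicon sequencing.
The package turns the raw abundance tables and OTU tables of such an
experiment into the standard summary statistics — and ships a
synthetic-data generator with known ground truth so every estimator can be
validated by recovery.

## The statistics at the core

**Decay kinetics.** Marker abundances (copies per g dry weight) are
transformed to lg(*C*<sub>t</sub>/*C*<sub>0</sub>) and fitted by ordinary
least squares, either as a single segment or biphasically (fast thermophilic
decay, then slow decay or a rebound, split at a breakpoint day — default
day 15, optionally grid-searched). The decimal reduction time is
*D* = |1/slope| days per log<sub>10</sub> drop. Removal efficiency is
100·(1 − *C*<sub>t</sub>/*C*<sub>0</sub>).

**Spread potential.** With *C*<sub>gfp</sub> counting plasmid copies,
*C*<sub>dsRed</sub> counting donors, and *C*<sub>16S</sub>/4 approximating
total bacteria (≈4 rRNA gene copies per cell),

> SP = (*C*<sub>gfp</sub> − *C*<sub>dsRed</sub>) / (*C*<sub>16S</sub>/4 − *C*<sub>dsRed</sub>)

is the ratio of transconjugants to recipients. Replicates are aggregated by
geometric mean (SP spans orders of magnitude).

**Community analysis.** Alpha diversity (Sobs, Chao1, ACE, Shannon in nats,
Simpson dominance Σp², Good's coverage) implemented from the estimator
formulas; Bray–Curtis dissimilarity; PCoA by classical metric scaling;
PERMANOVA (Adonis) with seeded permutation p-values; taxonomic aggregation,
top-N genus matrices, and shared/unique/core host-genus set analysis.

**Synthetic experiments.** Piecewise log-linear trajectories; a Poisson
droplet-occupancy ddPCR model (20 000 droplets of 0.85 nL by default);
Dirichlet-multinomial transconjugant communities around per-phase templates
(Firmicutes-dominated, eight phyla, Proteobacteria rebound at maturation,
lower richness under prolonged thermophilic composting). Defaults are
calibrated so the ground-truth SP runs from 3.91 × 10⁻⁴ in raw material to
2.54 × 10⁻⁶ in the finished prolonged-thermophilic compost.

## Worked example

```python
from plasmidfate import decay_kinetics as dk
from plasmidfate.spread_potential import spread_potential

# removal of the donor marker in prolonged thermophilic composting:
# C0 = 3.30e6, final Ct = 1.63e5 copies/g DW
print(f"removal = {dk.removal_efficiency(3.30e6, 1.63e5):.1f}%")

# log reduction after 27 days (Ct = 1.31e5)
print(f"log reduction = {dk.log_ratio(1.31e5, 3.30e6):.2f}")

# phase-I decay fit on a lg(Ct/C0) series sampled on days 0-15
fit = dk.fit_linear_decay([0, 1, 4, 7, 11, 15],
                          [0.0, -0.14, -0.57, -1.0, -1.57, -2.14])
print(f"slope = {fit.slope:.4f} log10/day, "
      f"D-value = {fit.d_value:.2f} days, r^2 = {fit.r_squared:.4f}")

# spread potential from one sample's three marker concentrations
res = spread_potential(c_gfp=2.14e5, c_dsred=1.13e5, c_16s=7.26e10)
print(f"SP = {res.sp:.3g} transconjugants per recipient")
```

prints

```
removal = 95.1%
log reduction = -1.40
slope = -0.1428 log10/day, D-value = 7.00 days, r^2 = 1.0000
SP = 5.56e-06 transconjugants per recipient
```

i.e. 95.1 % of the donor marker is removed, the abundance fell 1.40 logs,
the fast phase has a 7-day decimal reduction time, and roughly 6 in a
million recipient cells carry the plasmid at that time point.

A complete simulated experiment, end to end:

```bash
plasmidfate report --seed 1 --outdir run/
# or stage by stage:
plasmidfate simulate --seed 1 --outdir sim/
plasmidfate decay --input sim/abundance.csv --breakpoint 15 --out decay.tsv
plasmidfate sp --input sim/abundance.csv --out sp.tsv
plasmidfate community --otu sim/otu_counts.tsv --tax sim/taxonomy.tsv \
    --meta sim/sample_metadata.tsv --permutations 999 --seed 1 --outdir comm/
```

The report directory contains the simulated inputs, a ground-truth sidecar,
decay fits and removal efficiencies, the SP time series (geometric-mean SP
drops from ~4 × 10⁻⁴ at day 0 to ~3 × 10⁻⁶ at day 40 in the prolonged
treatment), alpha diversity, ordination coordinates, and the PERMANOVA
summary (p = 0.001 at 999 permutations for the five phase groups).

## Layout

- `src/plasmidfate/synthetic_data.py` — generator and its configuration
- `src/plasmidfate/decay_kinetics.py` — log ratios, OLS/biphasic fits, D-values, Tukey comparisons
- `src/plasmidfate/spread_potential.py` — SP per sample and as a time series
- `src/plasmidfate/community_analysis.py` — diversity, PCoA, PERMANOVA, host ranges
- `src/plasmidfate/io.py`, `pipeline.py`, `cli.py` — file formats, report pipeline, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
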