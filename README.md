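# clicklabel

Quantitative toolkit for **controlled average-degree-of-labeling (aDoL)
protein conjugation** by copper-free click chemistry (SPAAC).

## The problem

Labeling proteins through lysine-reactive NHS/SDP esters is easy but
imprecise: ester hydrolysis and variable reaction efficiency make the
final dye-to-protein ratio hard to control. A two-step protocol fixes
this: first activate the protein with a small azide-NHS reagent to an
incorporation ratio (I.R.) comfortably above the target, purify once,
then react the protein-N₃ with dye-DBCO at a molar ratio *equal to the
desired aDoL*. Because the strained-alkyne click reaction runs to
completion overnight, the dye is fully consumed and

> **aDoL = input molar ratio of click tag to protein**,

with no second purification. `clicklabel` implements the quantitative
machinery that makes this protocol predictable and checkable, for
bioconjugation chemists and assay developers:

* **Kinetics** — the integrated second-order rate law for azide sites A
  and dye-DBCO B,

  `x/[B]₀ = [A]₀(e^{Kt([A]₀−[B]₀)} − 1) / ([A]₀e^{Kt([A]₀−[B]₀)} − [B]₀)`,

  with K ≈ 4.31 M⁻¹s⁻¹; forward evaluation, inversion to incubation
  times, and rate-constant fitting from monitoring data.
* **Chromatogram analysis** — peak detection/integration on SEC-HPLC
  traces (conjugate 8.8 min, free dye 16.5 min) and extraction of
  reaction-progress curves from a chromatogram time course.
* **Spectrophotometric aDoL** — Beer–Lambert arithmetic with the dye's
  280 nm correction factor, e.g. for AZ488 on an antibody:
  `[AZ488] = A₄₉₅/70,000`, `[Ab] = (A₂₈₀ − 0.147·A₄₉₅)/217,500`,
  `aDoL = [AZ488]/[Ab]`.
* **MS incorporation ratio** — adduct counting on deconvoluted
  intact-protein mass ladders (83.05 Da per azidoacetyl),
  `I.R. = Σ(nᵢ·Iᵢ)/Σ(Iᵢ)`, and activation efficiency `100·I.R./excess`.
* **Poisson label multiplicity** — the per-molecule label-count
  distribution at a given aDoL (at aDoL 2, ~18% of molecules carry
  exactly 3 dyes).
* **FCS quality control** — 3D-diffusion autocorrelation fitting for
  free-dye fractions and counts-per-molecule brightness.
* **Protocol planner** — the design rules in one call: required
  I.R. = 2×target aDoL, azide-NHS excess = ⌈I.R./efficiency⌉ (~30%
  efficiency prior), concentration gates (≥10 µM DBCO, ≥25 µM azide),
  and the incubation time from the rate law.
* **Synthetic data** — deterministic, seeded generators for
  chromatogram series, absorption spectra, mass ladders and FCS curves,
  so the entire pipeline is testable without an instrument.

## Worked example

```python
from clicklabel import lookup_protein, molar_concentration, plan_labeling

ab = lookup_protein("Ab")                      # 150 kDa, eps280 = 217,500
conc = molar_concentration(2.0, ab)            # 2 mg/mL -> 13.33 uM
plan = plan_labeling(target_adol=2.0, protein=ab, protein_conc=conc)
```

Running `python examples/01_plan_protocol.py` prints:

```
protein:            13.33 uM antibody
required I.R.:      4.0 azides/protein
azide-NHS excess:   14x molar
click dye:          2.0x = 26.67 uM
incubate:           9.5 h for 99% completion
warnings:           none
```

Read: to end up with 2 dyes per antibody, activate with a 14× molar
excess of azide-NHS (at ~30% efficiency this yields ~4 azides per
protein, twice the target), click with dye at exactly 2× the protein,
and 99% of the dye is consumed after 9.5 h — comfortably inside the
standard 24 h incubation. The other scripts in `examples/` walk through
kinetic monitoring, aDoL from a spectrum, MS-based I.R., label
multiplicity, and FCS QC, each printing the numbers it computes.

A thin CLI mirrors the library:
`clicklabel plan --target-adol 2 --protein-um 13.33`,
`clicklabel simulate chromatograms --seed 1 --out sim/`,
`clicklabel fit-kinetics sim/*.csv --a0-um 74.67 --b0-um 26.67 --out fit.json`.

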