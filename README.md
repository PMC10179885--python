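# argentms

Silver-ion HPLC / APCI-MS profiling of long-chain aliphatic hydrocarbons,
built for insect cuticular hydrocarbon (CHC) analysis.

## The problem

Insect cuticles carry complex blends of n-alkanes and unsaturated
hydrocarbons that act as semiochemicals.  The heavier members (C40+) are
hard to analyze by GC (low volatility, thermal decomposition) and MALDI
cannot separate isomers.  Silver-ion (argentation) HPLC separates
hydrocarbons by their C=C chemistry — retention grows with the number of
double bonds, *trans* isomers elute ahead of *cis*, and positional isomers
resolve — while APCI-MS detection identifies each peak's molecular weight.
A species is reported at the CN:DB level: carbon number and double-bond
count (e.g. `c-C41:2`, a di-unsaturated C41 chain with cis double bonds).

In positive-mode APCI a hydrocarbon M = CnH(2n+2−2d) appears as a
mobile-phase-dependent mixture of ions:

    [M−H]+  [M+H]+  [M]+•  [M+C3H3]+ (+39)  [M+C4H9]+ (+57)
    [M+C6H13]+ (+85)  [M+C7H9]+ (+93, protonated toluene)

Saturated chains give mostly [M−H]+; unsaturated chains give [M+H]+
(maximal near 40–60 % toluene) plus [M]+• and [M+93]+ at high toluene.
Peak areas are quantified from chromatograms reconstructed for the sum of
the [M−H]+, [M]+• and [M+H]+ ions and reported as *relative areas within
each double-bond class* — never across classes, because APCI response
rises steeply with unsaturation.

## What the package provides

* `argentms.chem` — CN:DB formula/mass arithmetic on nominal and
  monoisotopic scales, the seven-adduct APCI registry, isotope envelopes,
  and reverse lookup from an observed m/z to candidate (species, adduct)
  pairs.  Note the intrinsic degeneracy: CnH2n+2 − H+ and CnH2n + H+ are
  the same ion, so mass alone cannot separate an alkane from an alkene —
  the retention class can.
* `argentms.simulate` — a seeded generative model of a full run:
  class-anchored retention model (calibrated on the packaged apex table),
  %toluene-dependent adduct fractions, double-bond-dependent response
  factors, Gaussian peaks, isotope envelopes, fragment floor, log-normal
  noise; output as in-memory scans or mzML plus a ground-truth TSV.
* `argentms.annotate` — the inference pipeline: summed-ion EICs, peak
  detection/integration, CN:DB assignment (class from the retention
  window, CN from the averaged spectrum), cis/trans calls from retention
  against per-class boundaries, within-class quantification, and recovery
  metrics against a known ground truth.
* `argentms.fixtures` — two packaged reference profiles (a 136-species
  flesh-fly profile and a 44-species cockroach profile) with integrity
  digests, plus report comparison/rendering utilities.
* `argentms` CLI — `simulate`, `annotate`, `evaluate`, `report`.

## Worked example

Simulate the packaged 44-species cockroach profile at default noise and
annotate it back:

```python
import argentms as am

table = am.load_fixture("table4")
comp = am.composition_from_report(list(table.rows), table.class_shares)
run = am.simulate_run(comp, seed=1)
result = am.annotate_run(run)
metrics = am.evaluate_recovery(result, comp)

print(f"annotated species: {len(result.annotations)}")
print(f"recall: {metrics.species_recall:.3f}  precision: {metrics.species_precision:.3f}")
print(f"geometry accuracy: {metrics.geometry_accuracy:.3f}")
```

prints

```
annotated species: 44
recall: 1.000  precision: 1.000
geometry accuracy: 1.000
```

i.e. all 44 species (31 alkanes, 7 monoenes, 3 dienes, 3 trienes) come
back with correct carbon number, double-bond class and geometry; the
within-class relative areas agree with the ground truth to fractions of a
percentage point (RMSE 0.16 / 0.09 / 0.00 / 0.01 pp for the 0–3
double-bond classes in this run).  The same workflow from the shell:

```sh
argentms simulate --fixture table4 --seed 1 --out run.mzml
argentms annotate run.mzml --out report.tsv
argentms evaluate report.tsv run.mzml.truth.tsv --out metrics.tsv
```

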