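# steromet

Interpretation toolkit for quantified urinary steroid metabolome profiles,
plus a pathway-flux simulator for generating synthetic profiles of inborn
errors of steroidogenesis and steroid metabolism.

The package covers the full interpretation loop used in clinical urinary
steroid profiling:

* **registry** — a versioned, immutable knowledge base of 33 urinary
  analytes (tetrahydro metabolites, cortols/cortolones, free cortisol and
  cortisone, …), the steroidogenesis pathway with enzyme/cofactor
  annotations (including the POR-dependent microsomal CYPs and the
  back-door androgen route), and the 23-ratio diagnostic panel for nine
  disorders (21-OHD, 11β-OHD, 17α-OHD, HSD3B2, ORD, AME, ACRD, SRD5A2,
  HSD17B3).
* **profile_io** — long/wide TSV reading and writing of per-sample
  analyte → µg/24 h maps, with strict validation.
* **reference** — per-analyte, per-group and per-ratio reference ranges
  (mean, empirical 5th/95th centiles) from a normal cohort, and
  low/normal/high/undefined flagging.
* **diagnostics** — precursor/product ratio evaluation with careful
  missing-value semantics, disorder calling (positive only when *all* of a
  disorder's ratios are high), and grouped excretion totals.
* **simulator** — exact steady-state flux propagation through the pathway
  under configurable enzyme activities, optional compensatory ACTH/LH
  drive, 5α/5β and 11-oxo/11-hydroxy metabolite partitions, and
  multiplicative log-normal noise; one preset per disorder.
* **reporting_cli** — structured JSON/TSV reports, log-axis figures, and a
  `steromet` command-line interface.

## Test

```bash
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), independent oracles for
the flux solver and centile estimator, and an acceptance suite
(`tests/test_acceptance.py`) covering panel composition, mass
conservation, monotonicity/directionality of the disease presets, and
end-to-end parameter recovery (≥ 90 % correct top-ranked calls for each of
the nine simulated disorders).

## Command line

```bash
# simulate a normal reference cohort and a patient
steromet simulate --preset normal -n 200 --seed 11 -o normals.tsv
steromet simulate --preset ORD -n 1 --seed 13 -o patient.tsv

# build reference ranges and diagnose
steromet reference build -i normals.tsv -o ref.json
steromet diagnose -i patient.tsv --ref ref.json -o panel.json

# render reports (figure or structured output, by extension)
steromet report quant -i patient.tsv --ref ref.json -o quant.svg
steromet report panel -i patient.tsv --ref ref.json -o panel.tsv

# inspect the built-in registry
steromet registry show --ratios
```

Exit code 2 signals a validation error; `--verbose` logs to stderr.

## Profile formats

Long format (TSV or CSV, sniffed): columns `sample_id`, `metabolite`,
`amount_ug_per_24h`, one row per measurement.  Wide format: `sample_id`
plus one column per canonical analyte abbreviation; empty cells mean *not
measured* (distinct from an explicit `0`, which means *below detection*
and makes any ratio denominator containing only such values undefined).
Greek analyte spellings (`5αTHF`, `11β-OH-An`) are accepted on input;
canonical ASCII (`5aTHF`, `11b-OH-An`) is emitted on output.
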