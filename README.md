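# nmrbin

Differential fecal-metabolite analysis for ¹H-NMR cohort studies:
spectral binning, bin filtering, per-bin linear models with FDR control,
and bin→metabolite ratio tables — built around the design of a pig
study contrasting high (HSC) and low (LSC) sanitary housing conditions
at 14 and 22 weeks of age. It is aimed at metabolomics analysts who want
the whole path from raw (δ, intensity) traces to a publication-style
metabolite ratio table as tested, scriptable code, plus a synthetic
cohort generator for validating the statistics.

## What it computes

1. **Binning.** Each spectrum is bucketed onto half-open 0.01-ppm bins
   over [0, 10) ppm — 1000 bins/sample, labelled by left edge ("7.93").
   Bin value = Σ point intensities (conserves total in-window signal).
2. **Filter cascade.** Drop 20 water-region interference bins
   ([4.70, 4.90) by default) → 980 bins; then keep bins whose per-bin
   maximum across samples ≥ 100,000 intensity units.
3. **Per-bin statistics.** For bin *j* at week *w*, the HSC/LSC ratio of
   group means, and an OLS fit of
   `log2(v + c) ~ treatment` (per week; a `treatment + age` pooled model
   is available), giving a two-sided t-test with n − 2 df. P-values are
   Benjamini–Hochberg adjusted within week across retained bins;
   significance tiers are q < 0.05, q < 0.1, "ns".
4. **Metabolite table.** Annotated bins aggregate per metabolite as the
   unweighted mean of bin ratios and the mean of bin q-values, rendered
   as per-bin rows plus "Mean …" rows.

The synthetic generator plants known HSC/LSC ratios at the published
bin positions (Lorentzian peaks, log-normal animal effects, Gaussian
noise, water-region interference hump) and emits a ground-truth table,
so ratio recovery, type-I calibration and power are all testable.
See `docs/methods.md` for the full model description.

## Worked example

Either drive the library through the numbered analysis scripts:

```sh
python analysis/01_simulate_cohort.py   # 24 synthetic spectra -> scratch/
python analysis/02_bin_and_filter.py    # 1000 -> 980 -> retained bins
python analysis/03_differential_stats.py
python analysis/04_metabolite_table.py
python analysis/05_calibration_power.py
```

or use the CLI (`nmrbin simulate … && nmrbin analyze …`). The cascade
step prints

```
cascade: 1000 bins -> 980 after water-region exclusion -> 66 above the 100,000 intensity threshold (max)
```

i.e. the 20 interference bins were removed and 66 bins carry signal in
at least one sample. The statistics step prints

```
week 14: 66 bins tested, 51 at q<0.05, 4 more at q<0.1, 11 not significant
week 22: 66 bins tested, 64 at q<0.05, 1 more at q<0.1, 1 not significant
```

and the table step renders rows such as

```
| Diet | 7.93 | Xanthine | 1.78 | <0.05 | 1.46 | <0.05 |
| Microbiome | 5.63 | UDP-glucose | 1.08 | ns | 5.00 | <0.05 |
...
recovered vs planted ratios: median |rel err| = 0.047, worst = +0.164 (Xanthine, week 14)
```

— recovered HSC/LSC ratios sit within sampling error of the planted
values (xanthine planted at 1.53/1.41, UDP-glucose at 1.15/4.76), and
the calibration step reports a null raw-p rate of ≈0.04–0.05 at nominal
0.05 with power 1.00 for a planted ratio of 0.5 at a single bin.

Real data enter through `nmrbin analyze --spectra DIR` (two-column
ppm,intensity text files) or `--bin-matrix FILE` (pre-binned
samples×bins CSV) with a metadata CSV
(`sample_id,animal_id,pen_id,treatment,week`).

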