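# amide3

Two-stage chemometric analysis of FTIR **Amide III** spectra of gingival
crevicular fluid (GCF), for spectroscopists and dental researchers studying
how oral disease transforms the secondary structure of GCF proteins.

The Amide III band (≈1330–1185 cm⁻¹, coupled N–H bending / C–N stretching)
is sensitive to protein conformation and free of water interference. The
package implements:

1. **Screening** — PCA of the samples × wavenumbers intensity matrix with a
   statistical description of each principal component by categorical
   clinical factors (one-way ANOVA with R² = SS_between/SS_total, per-level
   contrast t-tests, v-test values, Euclidean level-barycenter distances).
2. **Deconvolution** — decomposition of the band into a fixed library of
   twelve Gaussian components A(ν) = Σₖ aₖ·N(ν; cₖ, σₖ²) with
   FWHM wₖ = 2√(2 ln 2)·σₖ, each assigned to a secondary-structure class
   (I–V β-sheet, VI–VII random coil, VIII–IX β-turn, X–XII α-helix).
   Initialization from Savitzky–Golay second/fourth derivatives; bounded
   Levenberg–Marquardt-style least squares with centers boxed ±2 cm⁻¹
   around initialization and FWHM in [7, 19] cm⁻¹; χ² = RSS/(N−36).
3. **Comparison** — component-wise two-sample t-tests from across-portion
   summary statistics (Welch or pooled) with Bonferroni family-wise
   control, for integral intensities and relative percentage contents.

A fully seeded synthetic-data module emulates the study cohort
(17 participants, ten portions per sample, clinical factor codes), so the
entire pipeline is testable without measured spectra. Pre-treatment
(Savitzky–Golay smoothing, asymmetric-least-squares baseline, band
cropping) and CSV spectrum I/O round out the toolkit. See
`docs/methods.md` for the model, conventions and known limitations.

## Worked example

Reconstruct the published parameter set of sample FOMLG (female, older
group, multiple caries, mild periodontitis, gastrointestinal comorbidity)
as a noiseless band and recover it with the full pipeline:

```python
import amide3 as a

s = a.spectrum_from_table("FOMLG")            # noiseless 12-Gaussian band
res = a.fit_gaussians(s, a.initialize_peaks(s))
rel = a.relative_content(res)

for c, r in zip(res.components, rel):
    print(f"{c.index:>5} {c.assignment:<12} {c.center:8.1f} {c.fwhm:6.1f} {r:7.1f}")
```

```
    I β-sheet        1196.4    9.6     0.5
   II β-sheet        1203.5   10.4     3.1
  III β-sheet        1213.8   14.2     7.2
   IV β-sheet        1224.7   14.3    19.9
    V β-sheet        1238.5   13.4    30.2
   VI random coil    1251.0   13.0    17.8
  VII random coil    1261.8   16.4     6.0
 VIII β-turn         1269.9   18.0     4.5
   IX β-turn         1283.0   16.5     1.6
    X α-helix        1298.6   13.9     2.1
   XI α-helix        1309.8   13.0     3.5
  XII α-helix        1317.5    8.1     3.6
```

Every center, width and relative share matches the generating values: the
strongest component V (β-sheet) sits at 1238.5 cm⁻¹ with 30.2% of the band
area. Class totals via `a.class_totals(res)` give β-sheet 60.9%,
random coil 23.8%, β-turn 6.1%, α-helix 9.2% — the β-sheet contribution
dominating the α-helix one, as expected for GCF. The fit residual is at
machine precision (χ² ≈ 2·10⁻²⁹).

A full synthetic-cohort run — generation, preprocessing, PCA screening,
deconvolution of the selected samples and all pairwise comparisons — is one
call (`a.run_pipeline(a.RunConfig(seed=0))`) or one shell command:

```sh
amide3 run --seed 0 --out results/demo
```

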