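# octcornea

Corneal sublayer analysis for ultra-high-resolution anterior-segment OCT
(UHR-OCT), aimed at refractive-surgery imaging studies that track the
epithelium, Bowman's layer, the lamellar flap, and total corneal
thickness after thin-flap keratomileusis (SBK). The package bundles:

- a **synthetic B-scan generator** that renders curved, layered corneal
  reflectivity rasters with exact per-column ground truth — including the
  central specular reflex, horizontal artifact bands, and multiplicative
  speckle — plus a two-group, five-visit cohort simulator with
  between-subject, between-visit, and between-scan variance components;
- an **automated segmentation pipeline** that suppresses noise and
  artifacts, excludes the 128 A-scans around the specular reflex,
  averages depth-aligned A-scans in two 0.5-mm flanking regions into
  longitudinal reflectivity profiles, and assigns ordered profile peaks
  to the air–epithelium, epithelium–Bowman's, Bowman's–stroma, flap, and
  endothelium–aqueous interfaces with sub-pixel parabolic refinement and
  a manual-override path;
- **thickness conversion** from optical-path pixels to geometric
  micrometres via the corneal group index (n = 1.376), two-scan
  averaging, and cohort assembly;
- the **statistics of a repeatability + longitudinal study**: ICC
  (two-way absolute agreement, single measures), coefficient of
  repeatability CoR = 2·SD(difference), CoR% = CoR/mean × 100,
  Bland–Altman 95 % limits of agreement (mean ± 1.96 SD),
  repeated-measures ANOVA with Bonferroni-corrected consecutive-visit
  paired t-tests, pooled-variance two-sample t confidence intervals,
  and exact noncentral-t sample-size planning.

The native raster is 1365 depth px × 2048 lateral px covering
2.01 mm × 8.41 mm with a ~3 µm axial point-spread function; the depth
axis stores optical path length, so a layer of geometric thickness *t*
spans *n·t* optical micrometres.

## Worked example

Render one noisy post-operative B-scan, segment it, and compare against
the generator's ground truth:

```python
import numpy as np
from octcornea import (CorneaTruth, generate_bscan, segment_bscan,
                       interfaces_to_thickness, group_difference_ci,
                       coefficient_of_repeatability, limits_of_agreement)

truth = CorneaTruth(epi_um=53.1, bowman_um=17.0,
                    stroma_to_flap_um=95.8 - 53.1 - 17.0, total_um=439.5)
image, gt = generate_bscan(truth, noise_level=1.0, seed=42)
interfaces = segment_bscan(image, post_op=True)
thickness = interfaces_to_thickness(interfaces, image.geometry)
print("estimated:", {k: round(v, 2) for k, v in thickness.as_dict().items()})
print("truth:    ", {k: round(v, 2) for k, v in gt.thickness_um.items()})

diffs = np.array([-2.07, -0.07, 1.93])   # paired scan differences, um
print("CoR =", round(coefficient_of_repeatability(diffs), 2), "um")
print("LoA =", tuple(round(v, 2) for v in limits_of_agreement(diffs)), "um")
res = group_difference_ci(20, 95.8, 7.6, 21, 105.6, 8.2)
print(f"flap difference = {res.diff_mean_um:.1f} um "
      f"(95% CI {res.ci_low_um:.1f} to {res.ci_high_um:.1f}), p = {res.p_value:.4f}")
```

prints

```
estimated: {'epithelium': 53.16, 'bowman': 16.75, 'total': 439.41, 'flap': 95.82}
truth:     {'epithelium': 53.1, 'bowman': 17.0, 'total': 439.5, 'flap': 95.8}
CoR = 4.0 um
LoA = (-3.99, 3.85) um
flap difference = 9.8 um (95% CI 4.8 to 14.8), p = 0.0003
```

The segmentation recovers every sublayer to a fraction of a micrometre
on this scan; the CoR/LoA lines show the repeatability arithmetic on a
difference vector with mean −0.07 µm and SD 2.00 µm; the last line is
the pooled-t comparison of mechanical-microkeratome vs femtosecond-laser
flap thickness at day 1 (the femtosecond flap is 9.8 µm thicker).

A full simulate → segment → analyze → report run (images, manifest,
interfaces CSV, cohort table, repeatability/change/group-difference
tables, QC JSON, markdown report) is available from the CLI:

```bash
octcornea all --seed 1 --outdir demo_run
```

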