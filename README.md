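# qdcoloc

Quantifying how strongly quantum-dot (QD) conjugates localize to plant cell
boundaries in fluorescence micrographs — plus the companion statistics for
the same kind of study: Mendelian segregation chi-square tests and
plate-averaged growth/gravitropism ANOVA procedures.

The intended user images roots exposed to QD-labelled small molecules (e.g.
a QD–melatonin conjugate, with or without receptor agonists such as
ramelteon or tasimelteon) and asks: *what fraction of the emitters sits on
cell walls rather than inside cells, and does a treatment change that
fraction?*

## The statistic

For each image the pipeline computes

1. a per-pixel **boundary probability map** `P(x, y) ∈ [0, 1]` from the
   brightfield-like wall channel — either a supervised pixel classifier
   (multiscale filter-bank features + random forest) or a training-free
   multiscale ridge filter;
2. **spot centroids** from the QD channel: local maxima of the
   scale-normalized Laplacian-of-Gaussian response at the PSF scale,
   refined to sub-pixel positions by background-subtracted intensity-weighted
   centroids;
3. the **boundary-colocalized fraction**

   `f̂ = #{spots with P(centroid) ≥ τ} / #spots`,  default `τ = 0.2`,

   together with the histogram of per-spot boundary probabilities; and
4. a seeded two-sided **permutation test** on the difference of `f̂` between
   treatment groups (per-image fractions by default; pooled per-spot
   indicators optionally, for very small image counts).

Every stage can be validated against ground truth because the package ships
a synthetic scene generator: anisotropic tessellations emulating elongated
root cell files, pixel-integrated Gaussian emitters with Poisson/Gaussian
camera noise, and a controllable true boundary fraction `f_boundary`.

The tabular side implements the Pearson chi-square goodness-of-fit of
genotype counts against a 1:2:1 WT:het:hom segregation ratio (no continuity
correction), and the growth battery: seedlings averaged by plate
(pseudoreplicates), one-way ANOVA with Holm–Šidák pairwise comparisons,
two-way genotype × treatment ANOVA (Type II) with Šidák within-treatment
comparisons, and a linear-trend contrast for dose series.

## Worked example

```python
>>> import qdcoloc as q

# a 512x512 scene: 50 spots, 80% placed on cell walls
>>> scene = q.make_scene(seed=42)
>>> scene.true_boundary_fraction
0.8

# boundary probability map (training-free ridge variant)
>>> pmap = q.ridge_probability_map(scene.boundary_channel)

# detect + localize spots, then score them against the map
>>> spots = q.refine_centroids(scene.qd_channel,
...                            q.detect_spots(scene.qd_channel, psf_sigma_px=1.5))
>>> len(spots)
50
>>> result = q.colocalize(spots, pmap)
>>> round(result.boundary_fraction, 3)
0.82
```

The estimated fraction (0.82) recovers the simulated ground truth (0.8):
41 of the 50 detected spots sit at map probability ≥ 0.2.

The segregation test reproduces the canonical worked example — selfing a
heterozygous insertion line, observing 8 WT : 2 het : 0 hom:

```python
>>> q.chisq_segregation(q.SegregationTable((8, 2, 0)))
ChiSquareResult(statistic=16.4, df=2, p_value=0.000274...)
```

i.e. a significant departure from 1:2:1 (χ² = 16.4, df = 2, p < 0.05).

A full simulated two-group experiment (conjugate alone vs +agonist) runs
from the shell:

```sh
qdcoloc run --out demo_run --seed 11
# QD-MEL+RAM vs QD-MEL [image]: diff=0.5544 p=0.1
# QD-MEL+RAM vs QD-MEL [spot]: diff=0.5543 p=0.0001
```

With only 3 images per group the image-level permutation p cannot fall
below 0.1 (20 possible splits); the pooled per-spot test resolves the
difference. `demo_run/report.json` carries per-image fractions and full
provenance (config hash, seeds).

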