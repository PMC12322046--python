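# spatcell

Spatial point-pattern statistics for multi-type segmented tissue images —
the kind produced by imaging mass cytometry or multiplexed immunofluorescence
after segmentation and cell-type annotation. Given per-ROI cell tables
(centroid x/y in µm, cell-type label, condition) and optional integer label
masks, `spatcell` answers, with explicit null models and multiplicity control:

* **Which cell-type pairs co-occur?** Quadrat correlation matrix (QCM):
  Pearson correlation of 100 µm-quadrat counts against a cell-label-shuffle
  null, BH-corrected — a fast screen that gates pairs into PCF analysis.
* **How strongly and at what distance do two types co-locate?** Cross-pair
  correlation function with exact rectangular edge correction,

      g(r) = [ Σ_a n_a(r) / W_a(r) ] / ( N_A · N_B / |Ω| )

  where n_a(r) counts B cells in the annulus [r, r + dr) around anchor a and
  W_a(r) is the annulus∩window area; g ≡ 1 under complete spatial randomness
  (CSR). Bootstrap CIs resample anchor contributions; the topographical
  correlation map (TCM) renders each anchor's local score
  Γ_a = observed/expected − 1 as a spatial field.
* **Do three types cluster jointly?** Neighbourhood correlation function
  (NCF): the minimum-enclosing-circle (MEC) radius R of every cross-type
  triplet, binned and normalised by a Monte-Carlo CSR reference p3(r),

      NCF(r) = #{triplets : R ∈ [r, r+dr)} / (N₁N₂N₃ · p3(r)),

  with label-shuffle bootstrap envelopes and condition-level pooling.
* **Which types are in physical contact more than chance?** Adjacency cell
  network (ACN) from label masks, then contacting-cell-network (CCN)
  permutation z-scores z_AB = (O_AB − μ)/σ for the count of A cells touching
  ≥1 B cell, BH FDR, N_A-weighted condition aggregation (weighted z +
  Stouffer p), and the final network filter g(20) > 1 ∧ z > 0 ∧ significant.

A synthetic-data module generates CSR nulls, exact-distance pair attraction,
tight three-type triplet clusters and Thomas processes — with matching label
masks — so every statistic ships with a ground-truth test bed.

## Worked example

Fifty A–B cell pairs planted exactly 25 µm apart in a 1 mm² window, anchors
kept ≥100 µm from the boundary and ≥56 µm from each other so each annulus
[20, 30) µm contains exactly one partner:

```python
import numpy as np
from spatcell import (SimSpec, Window, PairedAttraction, simulate,
                      cross_pcf, PCFParams)

spec = SimSpec(
    Window(1000, 1000),
    structure=PairedAttraction("A", "B", offset_distance=25.0,
                               n_pairs=50, margin=100.0, min_separation=56.0),
    seed=1,
)
pattern = simulate(spec)
res = cross_pcf(pattern, "A", "B", PCFParams(n_boot=200, seed=2))
print(f"g(20) = {res.at(20.0):.4f}")
print(f"analytic = {1e6 / (50 * np.pi * 500):.4f}")
print(f"g_max = {res.g_max:.4f} at r = {res.r_at_g_max:.0f} um")
```

prints

```
g(20) = 12.7324
analytic = 12.7324
g_max = 12.7324 at r = 20 um
```

Exactly one B per anchor annulus means every anchor contributes 1/(π(30²−20²))
to the local density, so g(20) = |Ω|/(N_B·π·500) = 12.7324 — the package
reproduces the closed form to machine precision, and the curve peaks at the
planted 20–30 µm annulus.

The full pipeline runs from a YAML config:

```bash
spatcell simulate --structure paired --offset 25 --out demo
spatcell pipeline --config config.yaml --seed 1 --out results/
```

executing QCM → cross-PCF (QCM-passing pairs) → NCF → ACN/CCN → network
assembly, writing tidy CSVs and a JSON manifest; a rerun with the same seed
is byte-identical.

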