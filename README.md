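# micropat

Spatial-patterning statistics for micropatterned stem-cell colonies.

When mouse embryonic stem cells are grown on adhesive micropatterns —
discs, ellipses, hollow ellipses or four-petalled "flower" arrangements of
~30,000–90,000 µm² — a brachyury-positive (T⁺) subpopulation that looks
randomly scattered in unconfined culture organises spatially: peripherally
on discs, at the major-axis tips of ellipses (on one or both sides), and
inverted towards the centre on hollow ellipses. `micropat` implements the
quantitative toolkit for measuring this behaviour from per-cell feature
tables, plus a seeded synthetic-experiment generator and a desk-scale
image-quantification front end (render → segment → extract) so the whole
pipeline can be exercised and validated end to end without any raw data.

It is aimed at quantitative biologists analysing confined-colony
experiments (per-cell centroid + intensity tables) and at anyone who needs
a reproducible, testable reference implementation of these statistics.

## The statistics

For a colony on a pattern with centre *c* and longest half-axis *a* (disc
radius or ellipse semi-major axis), each cell at position *x* has a
**travel distance** `d(x) = 100·‖x − c‖ / a` (percent). The per-colony
**patterning score** is

```
score = log₂( mean d over T⁺ cells / mean d over all cells )
```

so 0 means the T⁺ cells sit no further out than average (random
positioning), +1 means twice as far out (periphery/tips), and negative
scores mean central enrichment. Colonies are classified **none** (no T⁺
cells), **undefined** (indistinguishable from random — by the sign rule or
an optional one-sided permutation test), or, on ellipses, **one-/two-sided**
by whether both major-axis sides hold ≥25% of the T⁺ cells.

Around the score the package provides: rigid registration of colonies (and
flower petals) into a canonical frame; pooled **binned density maps**
(BDMs); **neighbourhood-density** counts within a radius (NR, default
75 µm) and sweeps over 25–250 µm split by T label; top-hat
**concentration-proxy maps**; flower inner/outer-tip ratios and MAD
statistics; two-component Gaussian-mixture **intensity gating**; surface
coverage; the %T⁺-versus-density OLS fit with a 95% CI band; and the
Pfaffl relative-expression ratio for qPCR.

## Worked example

```python
from micropat import (GeneratorConfig, simulate_experiment, register_colony,
                      patterning_score, classify_colony, gate_t)
import pandas as pd

config = GeneratorConfig(shape="ellipse_m", n_colonies=50, seed=7)
colonies = simulate_experiment(config)

pooled = pd.concat([c.cells for c in colonies], ignore_index=True)
labels = gate_t(pooled, seed=7)          # T+/T- from simulated intensities
offset, rows = 0, []
for colony in colonies:
    colony.cells["t_label"] = labels[offset:offset + colony.n_cells]
    offset += colony.n_cells
    reg = register_colony(colony)
    result = patterning_score(reg)
    category = classify_colony(result, reg, method="permutation", seed=1)
    rows.append((colony.colony_id, result.n_cells, result.n_t_pos,
                 result.score, category))
df = pd.DataFrame(rows, columns=["colony", "cells", "T+", "score", "category"])
print(df.head(5).to_string(index=False))
```

prints

```
colony  cells  T+    score  category
 c0000    256  75 0.225179 one_sided
 c0001    216  17 0.621353 two_sided
 c0002    232  29 0.625419 two_sided
 c0003    176  32 0.404235 one_sided
 c0004    264  60 0.324389 one_sided
```

Across the 50 colonies this run recovers a mean of 16.4% T⁺ cells per
colony (the generator is configured at 17.1 ± 7.5%), a median score of
0.39 (tip enrichment), and categories `one_sided 24 / two_sided 15 /
undefined 8 / none 3` — the positive scores say T⁺ cells sit far from the
colony centre, and the side split says most colonies polarise to one tip.

The same pipeline runs from a shell:

```sh
micropat simulate --seed 7 --out run --n-colonies 50
micropat analyze --config run_config.yaml
micropat bdm run/cells.tsv --shape ellipse_m --label-column t_label_true --out bdm.tsv
micropat report run
```

## Layout

- `src/micropat/geometry.py` — pattern shapes, containment, boundary/tip
  distances, travel distance
- `src/micropat/synthetic.py` — seeded generator of synthetic experiments
- `src/micropat/image_quant.py` — rendering, nuclei segmentation, feature
  extraction (TIFF in/out)
- `src/micropat/registration.py` — canonical-frame registration and BDMs
- `src/micropat/spatial_stats.py` — scores, classification, neighbour and
  flower statistics, gating, regression, Pfaffl ratio
- `src/micropat/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, TSV
  and BDM serialisation
- `docs/methods.md` — models, assumptions, parameter choices, limitations
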