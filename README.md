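# otoquant

Quantification pipeline for 4D live imaging of neuronal specification in
the zebrafish inner ear, with a calibrated synthetic embryo generator so
every stage can be exercised and validated without microscope data.

During otic vesicle development, neuronal progenitors are specified in a
ventro-antero-lateral *neurogenic domain*: a `neurog1`-driven fluorescent
reporter (DsRed-Express, arbitrary units) turns on in single cells, rises
roughly linearly, and cells delaminate toward the statoacoustic ganglion
once the signal reaches a critical level.  A pool of early-specified
*pioneer* cells migrates in from anterior territory and ingresses into
the forming domain before the anterior epithelium folds, and these
ingressed cells non-autonomously promote specification of resident
cells.  `otoquant` implements the quantitative analyses used to
characterise this system:

* **morphometry** — a rectangular cuboid spanning the vesicle split into
  8 equal-volume octants (anterior/posterior x medial/lateral x
  dorsal/ventral); per-octant cell counts, fractions, tissue volumes,
  nuclear densities (nuclei / 10^3 µm^3) and mitotic-event counts;
* **fluor_quant** — single-cell reporter scoring
  `F_cell = mean of three background-subtracted cytosolic readings`,
  strict positivity thresholds, and per-vesicle summaries: N⁺ (number of
  positive cells), F̄_cell (their mean), the global level Σ F_cell, and
  N⁺ʰⁱ (cells above 1.5 x the control F̄_cell);
* **cell_dynamics** — delamination detection on tracks, the
  level-versus-timer delamination statistic (per-cell values normalised
  by the group mean, dispersions compared with a permutation test),
  division classification (apical position, cleavage-plane orientation,
  symmetric/asymmetric daughter fate, timing relative to onset), and
  photoconverted-nucleus ingression counts;
* **stats_report** — one-sample/unpaired/paired t tests from first
  principles, paired ablation reports, fold changes with bootstrap CIs;
* **synthetic_data** — an agent-based generator of ground-truth tracks,
  event logs and rendered multi-channel TIFF stacks, with perturbation
  scenarios (unilateral laser ablation of the pioneer stream, FGF-receptor
  blockade which advances anterior folding and abolishes ingression, and
  aphidicolin/hydroxyurea proliferation block);
* **experiments** — the cohort protocols tying it all together;
* **io_cli** — CSV/YAML/JSON/TIFF round-trips, run manifests and the
  `otoquant` command line.

Real data enter as track/intensity tables (CSV) and multi-page TIFF
stacks using the same readers.

## Worked example

Simulate one wild-type embryo, run the octant morphometry at 19 hpf and
summarise specification at 18.5 hpf:

```python
import numpy as np
import otoquant as oq
from otoquant import experiments

out = experiments.morphometry_cohort(range(1, 12))
print({k: round(v, 2) for k, v in out.items()})
```

prints

```
{'neurogenic_fraction_percent': 16.34, 'neurogenic_density_per_1e3um3': 2.2,
 'other_density_per_1e3um3': 1.62, 'neurogenic_mitosis_percent': 43.32,
 'n_embryos': 11, 'n_mitoses': 247}
```

i.e. over this 11-embryo synthetic cohort ~16% of vesicle cells sit in
the neurogenic octant, its nuclear density (2.2 nuclei/10^3 µm^3) is
well above the mean of the other octants (1.62), and 43% of all
mitoses between 14 and 18.5 hpf happen in that single octant — the
hallmarks of the neurogenic domain.

The same experiments are scriptable from a shell:

```sh
otoquant simulate --scenario wildtype --seed 1 --out run1/
otoquant morpho   --run run1/ --t-hpf 19 --out run1/morpho/
otoquant quantify --run run1/ --t-hpf 18.5 --out run1/summary.json
otoquant all --scenario ablation --n-embryos 6 --seed 42 --out abl/
```

The last command simulates six embryo pairs (ablated side plus intact
contralateral side), summarises both vesicles of each embryo and writes a
paired report of the four specification metrics.

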