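# nct — nucleocytoplasmic transport and stochastic frequency matching

Activating a single ErbB (HER2-family) receptor heterodimer in clonal 3D
breast-epithelial outgrowths drives only ~35% of them into an invasive,
DCIS-escapee-like phenotype.  `nct` implements the computational machinery
for studying that incomplete penetrance:

- **Stochastic frequency matching** (`nct.freqmatch`) — a per-gene statistic
  linking transcript fluctuation frequency to phenotype penetrance.  With
  *n* = 20 sampled outgrowths and penetrance *p* = 0.35, a true effector
  should show ~*np* = 7 extreme-expression events; the exact inverse
  binomial CDF gives the scoring bands (IQR [6, 8] → high-priority, 90% CI
  [4, 11] → candidate).  Events are counted against per-gene empirical
  10th/90th percentiles of the untreated condition, after a variance-ratio
  heterogeneity screen against pool-and-split technical controls.
- **A karyopherin transport model** (`nct.transport`) — a three-compartment
  (cytoplasm / nuclear pore / nucleus) mass-action ODE model of the Ran
  cycle (RCC1, RanGAP, RanBP1, NTF2), classical import (importin-α/β, with
  CAS/CSE1L recycling and competition), and CRM1/RanBP3 export, predicting
  steady-state nuclear-to-cytoplasmic (N/C) ratios of NLS, 2xNLS and IBB
  cargo reporters under perturbed protein abundances.
- **A feedback toggle switch** (`nct.feedback`) — ErbB heterodimers treated
  as classical import cargo with two antagonistic proportional feedbacks
  (cytoplasmic ErbB → CSE1L up; nuclear ErbB → importin-α down), co-solved
  with the transport steady state.  The closed loop turns the graded C/N
  response to CSE1L abundance into a switch, quantified by the apparent
  Hill coefficient (max log-log slope).
- **Morphometry** (`nct.morphometry`) — outgrowth circularity
  (4π·area/perimeter²) with upper-35th-percentile size stratification,
  proximity-ligation spot calling (15×15 LoG, σ = 1 px, 5-photon threshold,
  100–400 µm² nuclear gate), and colocalized nuclear/cytoplasmic intensity
  ratios (top-hat background correction, quantile normalization, geometric
  mean).
- **Synthetic data** (`nct.synthetic`) — seeded generators for the cohort
  structure (20 outgrowths + 16 pool-and-split controls per condition,
  35% high-state frequency over a 10% background), labelled masks, photon
  images and paired-channel cells, each with serialized ground truth.

## Worked example

```python
import numpy as np
from nct import (binomial_band, default_config, build_network, add_cargo,
                 steady_state, sensitivity_scan, NLS_SV40, IBB_KPNA2)

# scoring bands for 20 outgrowths at 35% penetrance
band = binomial_band(20, 0.35)
print(band.expected, band.iqr, band.ci90)
# 7.0 (6, 8) (4, 11)
print(band.classify(7), band.classify(11), band.classify(12))
# high_priority candidate unmatched

# steady-state reporter accumulation in the base parameterization
cfg = default_config()
model = add_cargo(build_network(cfg), NLS_SV40)
res = steady_state(model, "NLS")
print(round(res.nc_ratio, 2), res.converged)
# 4.6 True

# N/C of IBB cargo rises with importin-beta abundance
folds = np.logspace(np.log10(0.25), np.log10(4), 5)
scan = sensitivity_scan(cfg, "ImpB", folds, [IBB_KPNA2])
print([round(v, 1) for _, v, _ in scan["IBB"]])
# [5.0, 9.5, 18.6, 35.6, 62.6]
```

The N/C ratio is total cargo (free plus carrier-bound) in the nucleus over
the same in the cytoplasm: 4.6 means the monopartite-NLS reporter
concentrates ~5-fold in the nucleus at steady state.  The rising IBB curve
reproduces the model's qualitative prediction that IBB-type cargo is
promoted by importin-β while classical cargo is instead promoted by
importin-α and antagonized by CAS/CSE1L.

The same functionality is exposed on the command line:

```sh
nct synth cohort --seed 1 --out cohort/
nct freqmatch --matrix cohort/expression.tsv --samples cohort/samples.tsv --out calls.csv
nct scan --species CAS --folds 0.25:4:9log --out cas_scan.csv
nct switch --kd 2.5,32,320 --gains 0:0,8:0.3 --folds 0.25:4:12log --out switch.csv
```

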