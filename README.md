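# vtatrace

Quantitative analysis of monosynaptic rabies-virus (RABV) input maps to
ventral tegmental area dopamine (VTA^DA) neurons.

One-step RABV tracing labels the presynaptic partners of a genetically
defined starter population. With an attenuated TVA receptor (TC66T) the
inputs *local* to the injection site — historically unquantifiable because
of leak-mediated background infection — can be counted alongside long-range
inputs. `vtatrace` implements the downstream quantitative analysis for such
experiments, for circuit neuroscientists working with per-cell count tables
and projection images:

* **Input accounting** over a 57-region catalog (22 long-range + 35 local):
  per-brain fraction matrices, the local/long-range split, the convergence
  index `CI = N_long-range inputs / N_starters`, per-10,000 normalization,
  starter-cell composition and center-of-mass ellipses, and unpaired
  t-tests with confidence intervals.
* **Co-label maps** from marker flags (GAD1/2, TH, Tph2): composition of
  local GABAergic input, dopamine-to-dopamine connectivity fractions outside
  the sphere of TVA spread with the total-DA-input estimate
  `share(VTA/RRF) × frac(TH+)`, and serotonergic inputs per region
  (fractions and per-10,000 counts, midline raphe nuclei unsplit).
* **Ensemble embedding** of z-scored fractional counts: 20 seeded UMAP
  embeddings, pairwise distances normalized to each embedding's maximum and
  averaged, hierarchical clustering with silhouette-based selection of the
  cluster count, and a nearest-neighbor mixing score (with permutation
  p-value) for judging whether two cohorts can be compared.
* **Innervation profiles**: band-averaged image intensity from the midline
  laterally through the VTA, resampled to 100 bins, max-normalized, and
  averaged images → brain → region → cluster.
* **A synthetic cohort generator** that emulates the study design (4-brain
  cohorts, 900–2,400 starters, ~23k inputs per brain split ~54/46
  long-range/local, planted projection archetypes, Poisson background
  controls, gradient images), so the whole pipeline is testable end to end
  without animal data.

## Worked example

```python
import vtatrace as vt
from vtatrace.synthetic import GeneratorConfig, generate_cohort
from vtatrace.quantify import fraction_matrix, local_long_split, convergence_index
from vtatrace.colabel import gaba_composition

cat = vt.load_default_catalog()
cohort = generate_cohort(GeneratorConfig(n_brains=4, seed=0), cat)

fm = fraction_matrix(cohort, cat)
split = local_long_split(fm, cat)
print("local share: %.3f +/- %.3f"
      % (split["local"].mean(), split.attrs["sem"]["local"]))
print("convergence index per brain:",
      [round(convergence_index(b, cat), 2) for b in cohort])
gaba = gaba_composition(cohort, cat)
print(gaba.sort_values("mean_percent", ascending=False).head(3).round(1))
```

prints

```
local share: 0.462 +/- 0.002
convergence index per brain: [7.92, 8.09, 7.89, 7.94]
        mean_percent  sem_percent
region
SNr             21.3          8.6
PBP             19.7          2.7
SNc             11.7          2.1
```

i.e. for this simulated 4-brain cohort, 46% of all RABV-labeled inputs are
local, each brain shows ~8 long-range inputs per starter cell, and the
substantia nigra pars reticulata is the largest single source of local
GABAergic input, followed by the VTA's parabrachial pigmented nucleus and
the substantia nigra pars compacta.

The same stages run from the shell:

```bash
vtatrace simulate --out cohort/ --seed 0
vtatrace validate cohort/
vtatrace run-all --cohort cohort/ --out results/ --seed 0
```

`run-all` writes tidy CSVs (`input_fractions.csv`, `gaba_composition.csv`,
`aggregated_distances.csv`, `cluster_assignment.csv`,
`innervation_profiles.csv`, …) plus a `report.yaml` that is byte-identical
across re-runs with the same configuration and seed.

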