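# mmcds

Monte Carlo simulation of somatic clonal evolution in a self-renewing
stem-cell pool, under the multistage model of carcinogenesis (**MMC**) and
its extension with aging-dependent differential selection (**MMC-DS**).

## The problem

Cancer incidence rises steeply late in life. The classical multistage
explanation is waiting time: cells must accumulate several driver
mutations, each conferring a fixed clonal fitness advantage *s*, before a
malignant clone emerges. An alternative is that the *fitness effect itself*
is age-dependent — driver mutations are neutral or purged by negative
selection in young tissue and become beneficial only as the tissue ages —
so the timing of clonal expansions is set by an evolved aging program
rather than by mutation supply alone. This package implements both
hypotheses in one agent-based engine so their clonal dynamics can be
simulated, swept over parameters, and compared statistically. It is aimed
at researchers in somatic evolution, clonal hematopoiesis and cancer-risk
modeling.

## The model

An explicit population of stem cells evolves in weekly updates over a
100-year lifespan (5,200 updates). The pool's carrying capacity K(t) grows
from 300 cells at birth to 10,000 by maturity (~19 y). Each week, each
cell:

1. **divides** if its time since last division exceeds a threshold drawn
   from Normal(μ(t), μ(t)/8), where μ(t) is the age-dependent mean division
   interval (~3 weeks at birth slowing to ~40 in adulthood, or a constant
   ~20 in the classical setting);
2. each daughter **mutates** with probability MR (the *phenotypic mutation
   rate*, default 10⁻³ per division), gaining one driver;
3. **competes**: survival is a binomial trial with probability
   min(1, (K/N)·f_i/f̄), where f_i = (1+s(t))^k is the somatic fitness of a
   cell with k drivers.

Under MMC, s is constant; under MMC-DS, s(t) rises from −F_max early in
life to +F_max late in life, crossing zero at a configurable switch age.
Runs report the weekly sizes of the nested clone classes carrying ≥1…≥4
drivers. Conditions (samples of 50 replicate runs) are compared with a
pointwise Kruskal–Wallis test over all 5,200 weeks, summarized by the
normalized area under the p-value curve (1 = indistinguishable clonal
behavior, → 0 = different throughout life).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
from mmcds import standard_mmc_config, standard_mmcds_config, run_replicates
from mmcds.stats import compare_replicate_sets, takeover_week
import numpy as np

mmc = run_replicates(standard_mmc_config(), n=10, base_seed=7)
ds = run_replicates(standard_mmcds_config(), n=10, base_seed=7)

for name, rs in [("MMC", mmc), ("MMC-DS", ds)]:
    weeks = [takeover_week(r, clone_class=1) for r in rs.runs]
    print(f"{name}: median week the 1-driver class exceeds half the pool:",
          int(np.median(weeks)))

cmp = compare_replicate_sets(mmc, ds, clone_class=1)
print("p-value AUC ratio (MMC vs MMC-DS, 1+ clones):", round(cmp.auc_ratio, 4))
```

Output:

```
MMC: median week the 1-driver class exceeds half the pool: 748
MMC-DS: median week the 1-driver class exceeds half the pool: 3550
p-value AUC ratio (MMC vs MMC-DS, 1+ clones): 0.1133
```

With identical mutation supply and equal late-life selection strength,
differential selection postpones the takeover of mutant clones from age
~14 to age ~68 — past the age-50 sign switch — and the two models' clonal
dynamics differ over most of the lifespan (area ratio ≪ 1; the residual
~0.11 is the early- and very-late-life stretch where both models hold the
same near-zero or near-saturated clone counts).

The same experiments are available from the shell:

```bash
mmcds sweep --scenario fig4C_aging_curve --seed 1 --out out/aging
mmcds compare --a out/aging/switch_10y --b out/aging/switch_70y --clone 1 \
      --out out/cmp.tsv
mmcds normalize --in incidence.tsv --out normalized.tsv
```

Scenario names: `fig3A_division_profile`, `fig3B_adult_rate`,
`fig3C_mutation_rate`, `fig4A_fitness_MMC`, `fig4A_MMC_DS_a`,
`fig4A_MMC_DS_b`, `fig4B_pool_size`, `fig4C_aging_curve`,
`fig5_early_life`.

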