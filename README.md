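# copdsim

A deterministic dynamic population model of the burden of chronic
obstructive pulmonary disease (COPD) in Canadian adults aged 40+, projected
from 2011 to 2035, with an evaluation of three hypothetical population-level
interventions. It is written for health-economics and epidemiological
modellers who want a transparent, tested, fully scriptable re-implementation
of a system-dynamics cost-of-illness projection.

## The model

The population is stratified into 24 subgroups by sex, ten-year age band
(40–49, 50–59, 60–69, 70+) and smoking status (current, previous, never).
Stocks evolve by explicit Euler difference equations (default Δt = 0.25 y):
entry of 40-year-olds, band-to-band aging at rate 1/10 y⁻¹, net migration,
background mortality μᵢⱼ, smoking initiation and cessation.

Disease states per subgroup are **no COPD**, **mild**, **moderate** and
**severe** (GOLD I / II / III+IV), crossed with a diagnosis cascade driven
by respiratory symptoms and spirometry (uptake u = 0.37, sensitivity
Se = 0.92, specificity Sp = 0.84):

* symptomatic mild → TP with u·Se, FN with u·(1−Se), UD with (1−u);
  asymptomatic mild → UD;
* symptomatic non-COPD → TN with u·Sp, FP with u·(1−Sp).

Moderate and severe patients are all diagnosed: UD/FN cases that progress
surface as TP. Stage progression runs at hazard 1/T, the reciprocal of the
published mean progression times (e.g. T = 22 y mild→moderate for male
current smokers). Subgroup mild prevalence is held constant at its published
value — mild incidence is whatever restores it each step — while moderate
and severe stocks are fully dynamic.

Each stage s generates exacerbations at rate λₛ per patient-year
(0.79/1.22/1.47), split minor/major (94/6, 93/7, 90/10 %); every COPD death
rides on a major episode with probability 0.046. Costs (2011 CAD) combine
stage maintenance (accrued by TP/FP/moderate/severe only — UD and FN
patients generate no maintenance costs) and per-episode costs (accrued by
everyone). QALY losses are areas between the age-specific EQ-5D reference
curve and stage/episode utilities, plus the full reference-utility stream
from each COPD death to the 2035 horizon. Costs and QALYs discount at 3 %
to 2011. Interventions are multiplicative rate reductions e ∈ {10, 25, 50 %}:
**I** on smoking initiation, **II** on progression hazards, **III** on
exacerbation rates; they are compared by net monetary benefit
NMB = 50 000 $/QALY · ΔQALY + Δcost.

The official demographic projections behind the original analysis are not
shipped; a synthetic demography is calibrated so the 40+ population grows
17M → 24M over 2011–2035, the 70+ group reaches 8M, and baseline COPD
prevalence is 3.45M (see `docs/methods.md`).

## Worked example

```python
import copdsim as cs

ps = cs.default_demography()            # calibrate to the printed anchors
base = cs.simulate(ps)                  # no-intervention projection
a = base.annual
print(f"COPD 2011 {a.copd_total.iloc[0]/1e6:.2f}M -> "
      f"2035 {a.copd_total.iloc[-1]/1e6:.2f}M")
print(f"cumulative cost ${base.total_cost_discounted/1e9:.1f}B discounted")

iii = cs.run_scenario(ps, cs.ScenarioSpec("III", 0.50))
inc = cs.compare_scenarios(base, iii, ps.economics, 0.50)
print(f"intervention III -50%: saves ${inc.delta_cost_saving/1e9:.1f}B, "
      f"NMB ${inc.monetary_benefit/1e9:.1f}B")
```

prints

```
COPD 2011 3.45M -> 2035 4.94M
cumulative cost $101.4B discounted
intervention III -50%: saves $34.4B, NMB $92.8B
```

i.e. prevalence grows by ~43 % with the aging population, the 25-year
discounted societal cost is about $101B, and halving exacerbation rates
saves about a third of it — the dominant intervention at every effect size,
even though it *increases* the number of people alive with COPD (deaths
fall from ~17.9K to ~9.2K per year by 2035).

The same results come from the numbered drivers
(`analysis/01_calibrate_demography.py` … `04_sensitivity.py`) or the CLI
(`copdsim run`, `copdsim tornado`, `copdsim validate`, `copdsim summary`),
which write annual ledgers, per-subgroup tables, the intervention summary
and the tornado ranking as CSV under `results/`.

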