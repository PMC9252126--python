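# streambem

Spatially explicit bioenergetics projection of stream-fish growth under
climate and prey-availability scenarios.

## The problem

How will a warming climate change the growth opportunity of a stream fish
across its river network? For ectotherms, water temperature sets both the
scope for feeding and the metabolic cost of living, so the answer is not a
simple "warmer is worse": in thermally buffered, warm-temperate streams
where temperatures sit below the species' optimum, warming can *lengthen*
the growing season and *increase* annual growth. `streambem` implements the
full modelling chain needed to ask this question reach by reach:

1. a daily **Wisconsin energy-balance model** of individual growth,
2. **thermal-regime construction** from monthly air-temperature
   climatologies (logistic air→water conversion, then an annual sine fit
   interpolated to 365 days),
3. a **parameter-ensemble validation** procedure that resamples uncertain
   physiological constants within ±5% bounds and retains only the sets that
   reproduce empirical growth within ±2.5%, and
4. **per-reach projection** of end-of-year mass and growing-season duration
   under historical and future scenarios, with ensemble means and CVs.

It is aimed at fisheries ecologists and climate-vulnerability analysts who
want the whole pipeline reproducible from a single seed, with every input
either supplied as CSV or generated by the built-in synthetic-world module.

## The model

Daily growth is the residual of the whole-fish energy budget (J/day):

```
G = C − (R + SDA + E + U)
```

with

```
C = CA · M^CB · f_C(T) · CP · M · ED_prey        (consumption)
R = RA · M^RB · e^(RQ·T) · RACT · M · OXY        (respiration)
E = FA · C      U = UA · C      SDA = SA · R     (wastes, digestion)
```

where `M` is mass (g), `CP ∈ [0,1]` is the realized fraction of maximum
consumption (a surrogate for prey availability), `RACT ≥ 1` an activity
multiplier, `ED_prey` the prey energy density (J/g) and `OXY` the
oxycalorific coefficient (13 560 J/g O₂). The consumption temperature
dependence `f_C` is the Thornton–Lessem curve

```
f_C(T) = V^X · e^(X·(1−V)),   V = (CTM − T)/(CTM − CTO)
X = Z²·(1+√(1+40/Y))²/400,    Z = ln(CQ)·(CTM−CTO),   Y = ln(CQ)·(CTM−CTO+2)
```

which equals 1 at the thermal preferendum `CTO` and 0 at the feeding
ceiling `CTM`. Mass is stepped daily by `G/ED_pred`; the **growing season**
is the longest run of consecutive days with `G > 0`, and simulated length
comes from the allometric relation `W = a·L^b` evaluated at the last
surplus day (mass declines after the season ends, length does not).

## Worked example

```python
from streambem import RunConfig, run_pipeline

res = run_pipeline(RunConfig(), seed=1)
print(f"validated {res.validated.n}/{res.ensemble.n} parameter sets")
print(res.summary[["scenario", "median_mass_g", "median_season_days"]]
      .to_string(index=False))
```

prints

```
validated 52/500 parameter sets
        scenario  median_mass_g  median_season_days
      historical      39.924711              267.50
           rcp45      70.291592              323.75
  rcp45_enhanced     117.364974              365.00
rcp45_suppressed      37.737745              274.00
           rcp85     100.885517              365.00
```

Reading this: of 500 resampled physiological parameter sets, 52 reproduced
the (synthetic) empirical end-of-growing-season length within ±2.5% and
were retained. Across the 100-reach synthetic network, median end-of-year
mass of an age-1 fish rises from ~40 g under historical climate to ~70 g
under moderate warming (+2.4 °C) and ~101 g under high warming (+4.4 °C),
with growing seasons lengthening from ~268 to ~324 and 365 days — warming
helps because water temperatures in this groundwater-buffered system stay
at or below the species' thermal optimum. Note the consumption scenarios:
suppressing realized consumption by 10% (CP 0.5 → 0.45) wipes out more
growth than moderate warming adds, and enhancing it by 10% adds more than
high-emissions warming does. Prey availability rivals climate itself.

The same run is available from the shell:

```sh
streambem project --seed 1 --out-dir out/
streambem summarize --results out/projections.csv
```

which writes `projections.csv`, `changes.csv`, `summary.csv`,
`reaches.geojson` and a `run_metadata.json` sidecar (config hash, seed,
version); identical seeds give byte-identical outputs. `streambem synth`,
`simulate`, `calibrate` and `diff` expose the individual stages.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch at the default study scale
(500-set ensemble, 100 reaches × 5 scenarios), prints the validation funnel
and per-scenario medians, and writes the JSON report.

## Layout

| module | contents |
| --- | --- |
| `streambem.params` | `PhysiologyParams`, `SimulationSettings`, parameter-file I/O |
| `streambem.bem` | temperature factors, daily budget, trajectory + vectorized batch simulation, season metrics |
| `streambem.thermal` | air→water sigmoid, annual sine fit, daily interpolation |
| `streambem.ensemble` | uniform resampling, growth validation, mean/CV summaries |
| `streambem.projection` | reach × scenario projection, scenario differencing, regional summaries |
| `streambem.synthetic` | reach-network generator, warming scenarios, validation fixture from a known truth |
| `streambem.config` / `io` / `cli` / `pipeline` | strict YAML config, CSV/GeoJSON I/O, CLI, end-to-end orchestration |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
numerical choices, and what the synthetic world does and does not emulate.
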