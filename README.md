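# phenosense

Spatially explicit estimation of **phenological temperature sensitivity** —
how strongly the timing of plant reproduction (day of year of budding,
flowering, fruiting) tracks year-to-year temperature, in days/°C, and how
that sensitivity varies *within* a species across its range.

The package is aimed at ecologists working with large opportunistic
observation sets (community-science records, herbarium specimens) and gridded
monthly climate. It implements the full analysis chain:

1. **Curation** of an observation table (six focal herbaceous species on two
   continents; four-stage phenophase classification with a "latest stage
   wins" rule; sequential exclusion of records with missing metadata,
   unannotatable phenophase, vegetative state, or out-of-range locations).
2. **Climate covariates** per record from a 0.5° monthly grid (CRU TS-style
   `tmp`/`tmn`/`pre` variables):
   - `t_std`, `p_std` — seasonal-window mean temperature/precipitation of the
     observation year (Jan–Mar for spring bloomers, Mar–May for summer
     bloomers), mean-centred within species;
   - `MAT` — 1901–2021 mean of annual mean monthly minimum temperature (°C);
   - `IVT` — interannual variability: the s.d. of those annual means (s.d. °C).
3. **The global interaction model**, fitted by OLS:

   ```
   DOY ~ (t_std × MAT × IVT × species)
       + (p_std × MAT × IVT × species)
       + (phenophase × MAT × IVT × species)
   ```

   (all marginal terms included; 120 coefficients for 6 species × 3
   reproductive phenophases), with AIC comparison against simpler candidate
   structures.
4. **Marginal inference** (an estimated-marginal-means engine for OLS):
   reference grids, equal-weight factor averaging, *exact* simple slopes
   ∂E[DOY]/∂t_std computed from the coefficient/term structure, delta-method
   standard errors, and Tukey-HSD-adjusted pairwise contrasts via the
   studentized range distribution.
5. **Sensitivity analyses**: the temperature-sensitivity surface over a
   MAT × IVT grid (0.2 °C × 0.05 s.d. fine grid, −5…15 °C × 0.4…1.2 s.d.;
   1 °C × 0.1 s.d. summary grid), projection of the slope onto each record's
   exact MAT/IVT for mapping, intraspecific and interspecific variation
   ranges, conditional MAT trends by IVT level, and precipitation
   sensitivity (days/mm).

A **synthetic-data generator** with a known bilinear truth surface
`b(MAT, IVT) = γ₀ + γM·MAT + γV·IVT + γMV·MAT·IVT` produces climate grids and
observation tables under the study conditions, so every stage is verifiable
offline, including end-to-end parameter recovery with honest confidence
intervals.

## Worked example

```python
import phenosense as ps

grid = ps.generate_climate_grid(seed=1)              # 0.5-deg monthly climate
obs = ps.generate_observations(grid, seed=2)          # 24,000 records
kept, report = ps.filter_observations(obs)
cov = ps.attach_covariates(kept, grid)                # t_std, p_std, MAT, IVT

model = ps.PhenologySensitivityModel().fit(cov)
print(f"n={model.n_obs_} df={model.df_resid_} adjR2={model.r_squared_adj_:.3f}")

b = model.baseline_sensitivity()
print(f"baseline sensitivity {b.slope:.2f} +/- {b.se:.2f} days/degC")
print(model.mat_trend_profile().round(3).to_string(index=False))

intra = model.intraspecific_range()
print(f"intraspecific range {intra['range']:.2f} days/degC "
      f"(extremes {intra['min_slope']:.2f} at {intra['min_at']}, "
      f"{intra['max_slope']:.2f} at {intra['max_at']})")
```

Output from this exact session:

```
n=24000 df=23880 adjR2=0.834
baseline sensitivity -2.50 +/- 0.17 days/degC
    ivt  trend    se      t     p    df
overall -0.072 0.028 -2.604 0.009 23880
    0.4 -0.003 0.029 -0.121 0.904 23880
    0.8 -0.071 0.028 -2.563 0.010 23880
    1.2 -0.139 0.031 -4.455 0.000 23880
intraspecific range 2.77 days/degC (extremes -3.97 at {'mat': 15.0, 'ivt': 1.2}, -1.20 at {'mat': -5.0, 'ivt': 1.2})
```

Reading: on this dataset phenology advances about 2.5 days per °C of
seasonal warming on average; the strength of that tracking grows with site
MAT (−0.07 days/°C per °C of MAT), but only where interannual variability is
high (significant at IVT = 1.2 s.d., absent at 0.4 s.d.), and the slope
spans ~2.8 days/°C across the climatic study area. Single-dataset estimates
scatter around the generator's truth surface within their standard errors.

## Command line

Every stage is also a subcommand driven by one YAML config:

```bash
phenosense validate --config config.yaml
phenosense run --config config.yaml --seed 1 --outdir runs/demo
phenosense simulate|prepare|fit|sensitivity|report --config config.yaml --outdir runs/demo
```

A minimal synthetic config:

```yaml
seed: 1
synthetic:
  n_per_species_continent: 500
```

(real data instead: `inputs: {observations: obs.csv, climate: cru.nc}`).
The run directory collects the exclusion report, AIC table, tidy coefficient
and surface CSVs, the per-record sensitivity map, range summaries and a
`manifest.json` of content hashes; rerunning with the same seed reproduces
the manifest bit-for-bit.

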