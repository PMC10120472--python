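# urbandiv — experienced income diversity of urban encounters

`urbandiv` measures how evenly people from different income groups share
time at urban places, and why that diversity changes when behavior changes.
It is aimed at computational social scientists and urban-mobility
researchers who work with stay/visit panels (who was where, when, for how
long) joined to a place directory and census income geography, and who want
the full analysis chain — preprocessing, diversity metrics, counterfactual
attribution, behavioral-model estimation, and area-level regression —
exercisable end to end on synthetic data with known ground truth.

## The statistic

Users are assigned to Q = 4 equal-count income quantiles by the median
household income of their home census block group (CBG). For a place α in a
2-month window, τ_qα is the share of total dwell time contributed by
quantile q, and the experienced income diversity of the place is the
evenness of that exposure vector:

    D_α = 1 − (2/3) · Σ_q |τ_qα − 1/4|

so D_α = 1 when all four quantiles contribute 25% of the time and D_α = 0
when a single quantile contributes everything. An individual's exposure is
the convolution τ_iq = Σ_α τ_iα τ_qα of their own time shares with the
places' vectors, and D_i applies the same evenness formula. Changes are
reported as ΔD(t) = 100% · (D̄(t) − D̄(2019, same month)) / D̄(2019, same
month), which doubles as deseasonalization.

The package contains six library modules (`synth`, `ingest`, `metrics`,
`counterfactual`, `behavior`, `heterogeneity`) plus `study`, which pins the
canonical synthetic study design, and numbered drivers under `analysis/`
that run the pipeline and write tables under `results/`. The synthetic city
is generated by a social exploration and preferential return (Social-EPR)
model: visits arrive as a Poisson process; with probability ρS^(−γ) a user
explores a new place (with probability σ_s one where their income group is
not the majority), otherwise returns to a known place proportionally to
past visits. Pandemic "scenarios" perturb activity rates per quantile,
travel-distance preference, σ_s, and subcategory preferences — the three
behavioral factors that the counterfactual decomposition later recovers.
See `docs/methods.md` for the model, estimators, and design choices.

## Worked example

```
cd analysis
python 01_simulate_city.py      # synthetic city + 16 monthly panels (cached in scratch/)
python 02_diversity_trends.py   # monthly D̄ and ΔD vs 2019
python 03_counterfactual_decomposition.py
python 04_behavioral_parameters.py
python 05_heterogeneity_regression.py
```

`02_diversity_trends.py` prints, for the bundled 800-user study:

```
  month  D_place  D_place_2019  delta_D_place_pct  D_indiv  D_indiv_2019  delta_D_indiv_pct
2020-03   0.2632        0.4225           -37.6947   0.4089        0.6081           -32.7537
2020-04   0.2097        0.4184           -49.8787   0.3227        0.6080           -46.9178
...
2020-10   0.3527        0.4241           -16.8425   0.5329        0.6254           -14.7857

largest drop: 2020-04 (D̄_i -46.9%, D̄_α -49.9%)
```

— diversity collapses at the April-2020 stringency peak and only partially
recovers as the ramp relaxes, even though the generator's mobility volumes
recover much faster. `03_counterfactual_decomposition.py` splits each
month's drop into the three factors by downsampling the matching 2019 panel
to pandemic dwell totals (globally, then per quantile × distance bin, 10
replicates each):

```
  month  D_2019  D_cf_i  se_cf_i  D_cf_ii  se_cf_ii  D_actual  share_i  share_ii  share_iii
2020-04  0.4184  0.4075   0.0007   0.3303    0.0005    0.2097   0.0521    0.3699     0.5779
...
mean factor shares over the ramp: i=0.05 ii=0.37 iii=0.58
```

— in this scenario most of the loss is attributable to microscopic
preference changes (factor iii), consistent with the configured ground
truth, where the social-exploration cut is the dominant perturbation.
`04_behavioral_parameters.py` recovers the behavioral parameters per period
(σ̂_s falls from ≈0.43 in 2019 to ≈0.31 at the peak, tracking the
configured reduction) and ranks subcategory popularity shifts (big-box and
grocery stores gain, restaurants and movie theaters lose).
`05_heterogeneity_regression.py` fits the CBG-level fixed-effects
regression and prints the stringency trade-off:

```
cbsa_id  pearson_r  p_value  ols_slope  ...  n_months  lag1_autocorr
    SYN    -0.9918      0.0     -0.567  ...         8         0.7606
```

— a strong negative correlation between monthly ΔD̄_i and the stringency
index.

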