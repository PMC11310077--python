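# paleodiv

A tested, reusable pipeline for Holocene pollen-diversity analysis: from
raw pollen count records and chronological controls, through joint
rarefaction / age-uncertainty resampling, to diversity metrics, regional
trend models, land-use regressions, site-level slopes and a
leave-one-environment-out sensitivity analysis. A first-class synthetic
data module generates complete "worlds" with known generative truth so
every stage can be validated against ground truth.

## Pipeline

| stage | module | what it does |
|---|---|---|
| simulate | `paleodiv.synthetic_data` | synthetic worlds: multi-record pollen counts, radiocarbon-style controls, calibration curves, harmonization table, rectangle region map, gridded land-use (ALCC) fractions, plus a retained truth object |
| io | `paleodiv.pollen_io` | CSV/JSON formats, taxonomic harmonization, region assignment, regional ALCC mean series |
| filter | `paleodiv.chronology` | radiocarbon calibration, monotone Monte-Carlo age-depth draws, record inclusion criteria (3+ in-window controls, gaps <= 3,000 yr, 5+ samples of 300+ grains) |
| resample | `paleodiv.resampling` | R joint resamples: every sample rarefied to 300 grains (multivariate hypergeometric) paired with one age draw per record; Holocene window 11,700-100 cal yr BP |
| diversity | `paleodiv.diversity` | interval-adjusted Bray-Curtis and Jaccard turnover, rarefied richness, Pielou evenness; multi-site heterogeneity in 500-yr bins with bootstrap record-count control |
| trends | `paleodiv.trends` | per-region penalized B-spline smooths + record random intercepts (REML), AIC comparison against a pooled single-smooth model, median/IQR summaries across resamples |
| landuse | `paleodiv.landuse` | mixed regressions of each metric on sqrt(regional ALCC) over 8,000-100 cal yr BP with lag-1 autocorrelation correction |
| slopes / sensitivity | `paleodiv.site_analysis` | per-record linear slopes over three fixed periods (log/logit transformed, per 1,000 yr); leave-one-depositional-environment-out reruns |

## CLI

All stages are driven by one YAML config and a master seed; every output
is a pure function of (config, seed) and reruns are byte-identical.

```sh
paleodiv all --config config.yml --seed 1 --outdir out
# or stage by stage:
paleodiv simulate --config config.yml --seed 1 --outdir out
paleodiv filter   --config config.yml --seed 1 --outdir out
paleodiv resample --config config.yml --seed 1 --outdir out
paleodiv diversity --config config.yml --seed 1 --outdir out
paleodiv trends   --config config.yml --seed 1 --outdir out
paleodiv landuse  --config config.yml --seed 1 --outdir out
paleodiv slopes   --config config.yml --seed 1 --outdir out
paleodiv sensitivity --config config.yml --seed 1 --outdir out
```

Example `config.yml`:

```yaml
world:
  n_regions: 3
  records_per_region: 20
resample:
  R: 100            # the full analysis uses 1,000
diversity:
  het_B: 100
  min_region_records: 20
trends:
  k: 50
  family: gaussian   # or scaled-t
  age_grid_step: 250
```

Each stage writes CSV/JSON artifacts plus a `params.json` with its
resolved parameters under `out/<stage>/`.

## Conventions

* Ages are calendar years before present (cal yr BP, present = 1950 CE);
  larger values are older. CE years convert via `BP = 1950 - CE`.
* Depths are centimetres, strictly increasing downcore; age draws always
  respect superposition.
* Rarefaction is to exactly 300 terrestrial pollen grains; spores and
  aquatics are removed during harmonization.
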