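# trapsurv

Multi-scale analysis of trap-based surveillance for bark- and
wood-boring beetle (BWBB) communities around entry points (ports,
airports, rail yards). Surveillance campaigns run grids of baited
funnel traps across landscapes that mix forest and urban cover;
`trapsurv` answers the two design questions such campaigns face —
*where to put traps* along the urbanization gradient and *how many
traps are enough* — from season-pooled capture tables.

The package provides:

* a trap-scale **urbanization index**: the Euclidean distance of a
  trap's (tree cover %, barrier-free angle %) from the full-natural
  state (100, 100), scaled to [0, 100];
* **incidence-based diversity estimation** per landscape: Chao2
  richness, sample completeness (q = 0), and sample coverage (q = 1)
  with rarefaction below and extrapolation beyond the observed number
  of traps;
* **beta-diversity turnover**: the replacement component
  2·min(b, c)/(a + b + c) averaged over trap pairs;
* **effort-reduction simulations**: random and urbanization-ordered
  trap removal with % species-loss curves, blocked scenario
  comparisons, and landscape-scale regressions;
* **catch GLMMs**: per-trap richness (Poisson) and abundance (negative
  binomial) against the urbanization index with landscape random
  intercepts, fitted by adaptive Gauss–Hermite maximum likelihood;
* a **synthetic-study generator** reproducing the statistical
  structure of a 13-landscape × 16-trap campaign, so the whole
  pipeline is testable without field data.

## Worked example

Generate a default synthetic campaign and run the analysis drivers:

```sh
python analysis/01_generate_study.py --seed 1
python analysis/02_diversity_estimation.py
python analysis/03_effort_reduction.py --seed 1
python analysis/04_catch_models.py
```

The first script writes `results/study/{traps,landscapes,captures}.csv`
and prints the design-balance correlations:

```
  13 landscapes x 16 traps; 2428 capture records, 15586 individuals
  trap tree cover vs barrier-free angle:   r = 0.867
  trap tree cover vs landscape tree cover: r = 0.810
```

i.e. traps in forested spots also face few artificial barriers, and
trap surroundings track their landscape. The diversity driver then
summarises each landscape (excerpt):

```
landscape_id   T  S_obs  chao2  completeness  coverage_observed  mean_turnover
         L01  16     40 45.859         0.872              0.943          0.572
         L10  16     34 47.500         0.716              0.902          0.583
means: completeness=0.84 coverage=0.945 turnover=0.57
coverage at  4 traps ~ tree cover: slope=+0.00173 F=12.06 R2=0.52 p=0.005
coverage at 32 traps ~ tree cover: slope=+0.00027 F=4.36  R2=0.28 p=0.061
```

Sixteen traps see ~84% of each landscape's estimated species pool, and
a new trap would mostly catch already-seen species (coverage 0.94).
Coverage at low trap numbers rises significantly with landscape tree
cover — urban-dominated landscapes need more traps — while the effect
fades once effort is extrapolated to 32 traps. The effort driver
quantifies the cost of thinning the grid:

```
mean % species lost (across landscapes):
4  least_urbanized_first    44.5
   most_urbanized_first     33.6
   random                   38.1
8  least_urbanized_first    21.2
   most_urbanized_first     16.0
   random                   18.4
k=8: blocked LRT chi2=13.22 (df=2) p=0.001
random loss at k=8 ~ landscape tree cover: slope=-0.071 F=6.05 R2=0.35 p=0.032
```

Halving effort costs ~18% of species under random removal, less
(16.0%) if the most urbanized traps are sacrificed first, more (21.2%)
if the least urbanized go first — keep the low-urbanization traps.
Loss falls with landscape tree cover: urban landscapes lose more. The
catch models give the trap-scale mechanism:

```
species_richness_native   slope=-0.00795 (se 0.00124) chi2= 38.19 p=6.4e-10
abundance_native          slope=-0.01458 (se 0.00285) chi2= 24.22 p=8.6e-07
```

Catches decline log-linearly with the urbanization index.

The same stages are available as a CLI (`trapsurv generate | index |
diversity | effort | models | run`) and as library calls
(`trapsurv.pipeline.run_pipeline`).

## Layout

```
src/trapsurv/        library: data_model, urbanization, diversity,
                     effort, catch_models, synthetic, pipeline, cli
analysis/            numbered analysis drivers (thin, print findings)
tests/               pytest suite incl. end-to-end acceptance checks
scripts/acceptance.py
docs/methods.md      model details, assumptions, calibration, limits
```
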