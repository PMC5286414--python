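# nichespace

Multidimensional community niche metrics with resampling-based confidence
intervals.

`nichespace` quantifies the structure of ecological communities in
n-dimensional niche space — stable isotope ratios, per-amino-acid
signatures, trophic position, diet fractions, traits — via generalized
Layman-style dispersion metrics, and attaches bootstrap or parametric
confidence intervals so communities can be compared statistically by
interval overlap.

## Metrics

For a community of S taxa with coordinate vectors in R^n:

| metric  | meaning |
|---------|---------|
| `R_<axis>` | per-axis range (max − min) |
| `CD`    | mean Euclidean distance of taxa to the centroid (species spread) |
| `NND`   | mean nearest-neighbor distance (density of species packing) |
| `SDNND` | sample SD (divisor S−1) of nearest-neighbor distances (evenness) |
| `CHV`   | convex hull area (n = 2) / volume (n > 2): total occupied niche space |

CHV requires strictly more taxa than axes (S > n) and full-dimensional
geometry; `compute_all_metrics` reports it as undefined (with a warning)
otherwise, while `convex_hull_volume` raises. Axes are used on their raw
scales by default; `standardize` (or `--standardize`) z-scores them first.

## Confidence intervals

Two schemes, both recomputing every metric per replicate (default 10,000
replicates, 95% equal-tailed percentile intervals):

* **non-parametric** — from individual-level data: each taxon's k
  individuals are redrawn with replacement (independently per taxon) and
  taxon means recomputed;
* **parametric** — from per-(taxon, axis) mean ± SD tables (the shape of
  mixing-model output): each value is redrawn from a normal distribution
  truncated to the axis' declared bounds (e.g. diet fractions in [0, 1]).

A single root seed is split into per-taxon substreams, so results are
bit-reproducible and adding a taxon does not perturb the other draws.
`compare_communities` flags metrics whose intervals do not overlap
(closed intervals; touching endpoints count as overlap).

## Derived axes from amino-acid data

`nichespace.aminoacids` provides trophic position from the δ15N offset
between Glutamic Acid and Phenylalanine, `TP = ((Glu − Phe) − β)/TDF + 1`
(defaults β = 3.4, TDF = 7.6, both configurable), sample-mean
normalization of per-amino-acid δ13C profiles, the δ-notation conversion,
and `build_derived_community` to assemble a trophic-position +
diet-fraction community ready for the metrics and resamplers.

## CLI

```sh
# point metrics from a community CSV (taxon,axis1,axis2,...)
nichespace metrics community.csv --out metrics.csv

# bootstrap CIs from an individuals CSV (repeated taxon rows)
nichespace bootstrap individuals.csv --scheme nonparametric \
    --replicates 10000 --level 0.95 --seed 1 --out cis_before.csv

# parametric CIs from an estimate CSV (taxon,axis,mean,sd) with bounds
nichespace bootstrap estimates.csv --scheme parametric \
    --axes-config axes.yaml --seed 1 --out cis_after.csv

# flag metrics whose intervals do not overlap
nichespace compare cis_before.csv cis_after.csv

# synthetic scenario fixtures (12 archetypes)
nichespace simulate --archetype invasion_dispersed_third --seed 1 \
    --k 10 --out-dir fixtures/
```

Axis bounds and units live in a YAML sidecar, not the data files:

```yaml
axes:
  - {name: TP, unit: TP}
  - {name: algae, unit: fraction, lower: 0, upper: 1}
```

Every command can emit a JSON run manifest (`--manifest`) with input
hashes, config echo, seed and tool version.

## Missing data policy

Missing cells are errors by default; `drop_incomplete=True` drops
offending rows with a logged report. Values are never imputed.
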