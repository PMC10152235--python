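# spatialih

Spatial immune-hotspot analysis of histology cell coordinates. Starting from
per-slide cell tables (x/y in micrometres plus a class label), the package:

1. **Rasterizes** cells onto a 50×50 µm lattice and computes a local
   Getis–Ord statistic per grid for the cancer and lymphocyte channels
   (4th-order queen neighborhoods, one-sided upper-tail p values).
2. **Labels compartments** at p < 0.05: cancer hotspots (CH), peritumoral
   immune hotspots (IH_peri, lymphocytes only), intratumoral immune hotspots
   (IH_intra, both channels), and derives three spatial scores
   (`s_intra_immune`, `s_intra_cancer`, `s_intra_tissue`).
3. **Segments individual immune hotspots** by 8-connectivity, excluding
   pathologist-annotated TLS/LAG polygons, and assigns those structures to
   compartments by majority area.
4. **Builds Delaunay interaction graphs** of the six immune subsets per
   hotspot (edges > 250 µm pruned) and computes pairwise link fractions,
   Shannon diversity, composition metrics, Wilcoxon/BH comparisons, median
   splits and univariate logistic regressions.
5. **Registers serial sections** by landmark least-squares affine fit with
   target-registration-error and density-concordance quality metrics.
6. **Runs survival statistics**: maximally selected log-rank cutpoints,
   Kaplan–Meier/log-rank, multivariate Cox (Efron ties), and repeated 1:1
   discovery/validation split testing.
7. **Generates synthetic slides and cohorts** (Poisson tumor nests,
   Thomas-cluster infiltrates, zoned TLS-like aggregates, and
   proportional-hazards survival outcomes with a known spatial-score
   coefficient) so the whole stack is testable without restricted data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property/simulation acceptance suite
(oracle equivalence of the Getis–Ord statistic, exhaustive neighborhood
enumeration, compartment recovery on ground-truth masks, flood-fill and
empty-circumcircle oracles, cutpoint/Cox parameter recovery, split-validation
calibration).

## CLI

```bash
spatialih simulate --config slide.yaml --out sim/ --seed 3
spatialih hotspots --cells sim/cells.csv --grid 50 --order 4 --alpha 0.05 --out hs/
spatialih components --cells sim/cells.csv --annotations ann.geojson --out comp/
spatialih interactions --cells ihc_cells.csv --max-edge 250 --out ia/
spatialih register --landmarks lm.csv --cells moving_cells.csv --diag 25000 --out reg/
spatialih survival --table surv.csv --score s_intra_immune --splits 100 --seed 7 --out sv/
spatialih run-all --cells sim/cells.csv --out run/
```

Cell tables are CSV with columns `cell_id,x_um,y_um,class`; valid classes are
`cancer`, `stromal`, `lymphocyte` (H&E) and `CD8`, `CD4_FOXP3neg`,
`CD4_FOXP3pos`, `CD20_CXCR5neg`, `CD20_CXCR5pos`, `CD79b`, `P40` (IHC).
Annotations are GeoJSON FeatureCollections with a `kind` property (`TLS` or
`LAG`). Every output directory receives the config plus its hash for
provenance.

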