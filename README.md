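# enamelfractal

Fractal dimensionality of occlusal enamel bands, and the phylogenetic
comparative statistics to go with it.

Hypsodont horses of the tribes **Hipparionini** and **Equini** solved
the same problem — tooth wear from abrasive grazing — with different
dental architecture: hipparionines with convoluted occlusal enamel
bands, equines with taller crowns and simpler bands. Enamel-band
complexity indices based on band length scale with body size; the
fractal dimension *D* of the band outline does not. This package is for
paleontologists and morphologists who want to:

- estimate *D* from binary trace images of occlusal enamel bands with
  the **box-counting method**: cover the one-pixel-wide band border with
  grids of boxes of edge *s* ∈ [2, 64] px, count occupied boxes *N*(*s*),
  and fit log *N*(*s*) = a − *D*·log *s*. A straight line has *D* ≈ 1, a
  plane-filling curve *D* → 2;
- **time-calibrate** a fossil supertree from first/last appearance data
  (FAD/LAD, Ma), resolving the zero-length branches of basic dating;
- fit **PGLS with maximum-likelihood Pagel's λ**,
  y = β₀ + β₁x + ε, cov(ε) = σ²·V(λ), where V holds shared root-to-tip
  branch lengths and λ scales its off-diagonal (λ = 0 collapses to a
  non-phylogenetic GLS; λ = 1 is Brownian motion), with
  likelihood-ratio confidence intervals for λ;
- compare tribes with **Welch's t-test** (reconstructable exactly from
  species-level n/mean/SD summaries) and compare regression slopes
  between clades;
- generate every input synthetically with known ground truth: L-system
  fractal curves of analytic dimension, Yule trees, and trait data drawn
  from the exact PGLS generating model.

The species summary table of the published equid study (35 species,
98 teeth) ships as a packaged fixture.

## Worked example

Tribe comparison from the packaged species summaries:

```sh
$ enamelfractal compare --summaries summaries.csv
{
  "t": -3.7912862669888816,
  "df": 52.91930442889481,
  "p": 0.00038598848252603576,
  "equini_mean": 1.3589880597014925,
  "hipparionini_mean": 1.4209387096774193
}
```

Equini teeth average *D* ≈ 1.359 and Hipparionini ≈ 1.421; the
difference is highly significant (Welch t = −3.79 on ≈ 52.9 df,
p < 0.001) — hipparionine enamel bands are reliably more complex.
(The summaries CSV here is `summaries_to_frame(table1_fixture())`
written to disk.)

Sanity-check the estimator on a curve whose dimension is known exactly:

```sh
$ enamelfractal simulate --kind koch --iterations 5 --raster-px 729 --out demo/
wrote demo/koch_i5_729px.png (analytic D = 1.2619)
$ enamelfractal trace-d --images demo/ --out demo/d.csv
wrote 1 D estimates to demo/d.csv
$ cat demo/d.csv
specimen_id,D,fit_r2,n_sizes
koch_i5_729px,1.2244619489039004,0.9984960518402597,9
```

The box-counting estimate 1.224 sits within 0.04 of the Koch curve's
analytic log 4/log 3 ≈ 1.262, with the log–log fit essentially linear
(R² ≈ 0.998).

From Python, the same machinery composes directly:

```python
from enamelfractal import (
    GeneratorSpec, generate_curve, estimate_D,
    simulate_tree, simulate_traits, phylo_covariance, profile_lambda,
)

trace, d_true = generate_curve(GeneratorSpec(kind="sierpinski",
                                             iterations=9, raster_px=729))
print(estimate_D(trace).D)          # ~1.57 vs analytic 1.585

tree = simulate_tree(64, seed=1)
data = simulate_traits(tree, lam=1.0, sigma2=0.05, seed=2)  # Brownian traits
fit = profile_lambda(data, phylo_covariance(tree))
print(fit.lambda_hat, fit.lambda_ci)  # lambda recovered near 1
```

A full study (images or a specimen table with D, a newick tree, a
FAD/LAD CSV) runs through `enamelfractal report --config run.yaml`, or
`run_pipeline(RunConfig(...))` from Python, producing specimen-D,
species-summary, tribe-comparison, regression and phylogenetic-signal
tables plus a provenance block.

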