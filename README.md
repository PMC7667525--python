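# gxmap

Spatially-adjusted association of regional gene expression with statistical
brain maps, for imaging-transcriptomics studies of neurodegeneration.

## The problem

Bulk transcriptomic atlases of the human cortex (donor-level microarray
bundles with samples located in MNI millimetre space) can be linked to
voxel-wise disease maps — e.g. grey-matter atrophy t-maps from voxel-based
morphometry contrasts of mutation carriers against non-carriers — to ask
which genes are expressed more (or less) in the regions a disease attacks.
The obstacle is spatial autocorrelation: both expression and atrophy are
smooth over the cortical sheet, so naive correlations between them are
grossly anti-conservative. `gxmap` implements the full pipeline with an
explicit spatial correction, plus a synthetic-data generator so that every
stage is testable without any external download.

## The method

For each donor *d*, atrophy map and probe, the Spearman correlation between
the sampled atrophy value *t* and expression *x* is approximated by a rank
regression,

&nbsp;&nbsp;&nbsp;&nbsp;rank(*t*) = β₀ + β₁ · rank(*x*) + Σⱼ γⱼ *E*ⱼ + ε,

where the *E*ⱼ are Moran eigenvector maps (MEM): leading eigenvectors of
the doubly-centered, symmetrised spatial weight matrix of the donor's
10-nearest-neighbour graph over geodesic inter-sample distances.  If
Moran's I flags the residuals as spatially autocorrelated (one-sided
randomisation test, p < 0.05), eigenvectors are added — first one, then in
steps of five, up to 150 — until the residuals pass or the cap is reached
(spatial eigenvector mapping, SEVM).  The per-donor two-sided p-values for
β₁ are combined with Stouffer's weighted-Z method using weights restricted
to ±1 (direction only, so large donors are not up-weighted):

&nbsp;&nbsp;&nbsp;&nbsp;*Z*meta = Σ_d *w*_d Φ⁻¹(1 − *p*_d/2) / √(Σ_d *w*_d²).

Meta p-values are corrected per map with Benjamini–Hochberg FDR; a gene is
called positive (negative) if any of its probes reaches q < 0.05 with
*Z*meta > 0 (< 0), and consensus lists intersect the per-map calls across
three maps.  Gene lists are then tested for overrepresentation of gene-set
collections (GMT) and derived cell-type marker sets (FPKM > 2.5, target /
mean non-target enrichment ≥ 3.0) with one-sided Fisher's exact tests
against the cortex-expressed background.

## Worked example

```python
import numpy as np
import pandas as pd
import gxmap as gx

# --- simulate four donors with two genes truly tied to atrophy -------------
genes = [f"G{i+1:05d}" for i in range(60)]
truth = gx.GroundTruth(effect_rho={"G00001": 0.6, "G00002": 0.6},
                       directions={"G00002": -1}, seed=0)
geoms = gx.generate_geometry(n_donors=4, n_samples=200, seed=7)

bundles, tables = [], {}
for geom in geoms:
    volume, t_at_samples = gx.atrophy_for_geometry(geom, map_id="C9orf72")
    bundle = gx.generate_expression(geom, n_genes=60, probes_per_gene=2,
                                    truth=truth, atrophy_t=t_at_samples, seed=11)
    bundles.append(bundle)
    tables[geom.donor_id] = pd.DataFrame({"C9orf72": t_at_samples},
                                         index=bundle.samples["sample_id"])

# --- spatially-adjusted association, combined across donors ----------------
result = gx.run_association(bundles, tables, k=10)
top = result.probe_results.sort_values("q").head(5)
print(top[["probe_id", "z_meta", "p_meta", "q", "direction"]].to_string(index=False))

probe_gene = dict(zip(bundles[0].probes["probe_id"], bundles[0].probes["gene_symbol"]))
lists = result.gene_lists(probe_gene)["C9orf72"]
print("positive:", sorted(lists.positive), " negative:", sorted(lists.negative))
print(result.eigenvector_summary.to_string(index=False))
```

Output:

```
 probe_id    z_meta   p_meta        q  direction
G00001_p1  3.846118 0.000120 0.005268          1
G00001_p2  4.085266 0.000044 0.005268          1
G00002_p2 -3.823240 0.000132 0.005268         -1
G00002_p1 -3.410543 0.000648 0.019450         -1
G00006_p1  2.704049 0.006850 0.164401          1
positive: ['G00001']  negative: ['G00002']
 min    q1  median   q3  max  map_id
15.0 18.75    20.0 20.0 20.0 C9orf72
```

Both probes of the two planted genes are recovered with the planted signs
(q < 0.05), no null gene is called, and every fit needed 15–20 spatial
eigenvectors to whiten its residuals — the smooth atrophy bump and the
spatially structured expression would otherwise have produced dozens of
spurious calls (see the type-I study in `gxmap.studies`).

A thin CLI mirrors the file-based workflow:
`gxmap sample-volume` (NIfTI lookup at sample coordinates),
`gxmap associate` (donor bundles + sampled t-values to probe-level
statistics) and `gxmap enrich` (gene list vs GMT collection).

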