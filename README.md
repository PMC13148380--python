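# stainstat

Quantitative analysis of brightfield immunohistochemistry (IHC) and bulk
expression data for studies of immune-cell spatial patterning in tissue —
e.g. macrophage (F4/80) staining in mouse liver damage models. The package
bundles four analysis arms behind one library, each drivable end to end
from synthetic data with known ground truth:

1. **Tile-based GLCM texture pipeline.** A brightfield image is converted
   to grayscale, divided by the mean of a 200×200 background patch, a
   1500×1500 ROI is tiled into an 8×8 grid (187.5-px nominal tiles),
   tiles dominated by empty/vein regions are removed (Gaussian blur, then
   >10 % of pixels above the ROI's 90th percentile), tiles are 3×3
   block-averaged, and a moving-window gray-level co-occurrence matrix
   (GLCM, `n_gray` = 4; 0°/45°/90°/135° shifts pooled) yields seven
   texture maps per tile — mean, variance, contrast, dissimilarity,
   homogeneity, angular second moment, entropy. Six summaries per map
   (mean, sd, q1, q3, kurtosis, skewness) give 42 features per tile,
   embedded by PCA with tile-thumbnail scatter plots.
2. **IHC scoring.** Per-cell intensity tables are stratified at marker
   cutoffs (F4/80: 0.05/0.4/0.6; CD3: 0.2/0.4/0.6) into
   neg/low/moderate/high; per region the package reports percent-positive
   and the H-score `1·%low + 2·%moderate + 3·%high ∈ [0, 300]`, optionally
   restricted to 500×500 vein patches (central vs portal), with one-way
   ANOVA across conditions.
3. **Signature activity score.** Per-sample signed sum of log2 expression,
   `score(s) = Σ_{g∈up} x_gs − Σ_{g∈down} x_gs` (lower = less pathway
   activity), with ortholog mapping of signatures between species,
   exclusion bookkeeping, and a full-vs-reduced sensitivity correlation.
4. **Interaction-gene clustering.** Median centering per gene,
   1 − Pearson correlation distance, average-linkage (UPGMA) hierarchical
   clustering with a fixed k-cluster cut (default 4), and per-cluster ×
   per-group expression summaries.

A `stainstat.synthetic` module generates brightfield images (dispersed or
Thomas-process clustered cells, bright veins), stratified cell tables, and
2×2 factorial expression matrices with planted signatures and interaction
patterns, always returning the generating truth so every stage is testable
without external data.

## Worked example

```python
import stainstat as ss

cfg = ss.synthetic.HistologySimConfig(
    seed=0, cell_count=1200, clustering_mode="clustered",
    cluster_count=8, cluster_sd_px=110.0, vein_count=2, vein_radius_px=120.0)
sample = ss.synthetic.simulate_histology(cfg)

feats, tiles, thumbs = ss.pipeline.image_features(
    sample.image, image_id="demo", return_tiles=True)
print(len(feats), "of", len(tiles.tiles))          # 23 of 64
pca = ss.embedding.fit_pca(
    feats.set_index("tile_id")[ss.pipeline.feature_columns()])
print(pca.explained_variance_ratio[:2].round(3))   # [0.864 0.113]
```

The tile filter keeps 23 of 64 tiles here — the clustered pattern leaves
many near-empty bright tiles, and both these and the two veins are removed
before texture analysis. PC1 carries 86 % of the feature variance on this
single image. Scoring the same simulated cells with the F4/80 cutoffs:

```python
labeled = ss.ihc.stratify_cells(sample.cells.drop(columns="stratum"),
                                ss.ihc.CUTOFF_PRESETS["f480"])
labeled["region_id"] = "demo"
print(ss.ihc.h_score(labeled)[["percent_positive", "h_score"]])
#    percent_positive     h_score
# 0             100.0  148.333333
```

and the activity score on a simulated knockout experiment separates
genotypes in the expected direction (lower score = less activity):

```python
s = ss.synthetic.simulate_expression(ss.synthetic.ExpressionSimConfig(seed=0))
roles = s.gene_roles
sig = ss.activity.SignatureGeneSet(
    up=set(roles.index[roles == "signature_up"]),
    down=set(roles.index[roles == "signature_down"]))
score, _ = ss.activity.activity_score(s.matrix, sig)
print(score.groupby(s.samples.set_index("sample")["group"]).mean().round(1))
# NTC_CCl4       208.3
# NTC_Veh        209.2
# sgBap1_CCl4   -185.9
# sgBap1_Veh    -187.7
```

A thin CLI mirrors the library:
`stainstat simulate|texture|pca|hscore|activity|cluster --help`.

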