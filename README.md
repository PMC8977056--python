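# ktrquant

Single-cell quantification of kinase activity from **kinase translocation
reporter (KTR)** time-lapse imaging. KTRs are engineered kinase substrates
that shuttle out of the nucleus when phosphorylated, so the
cytoplasmic-to-nuclear intensity ratio (**C/N ratio**) of the reporter reads
out kinase activity in each cell at each time point. `ktrquant` implements
the complete analysis chain for experiments of this kind — e.g. HeLa cells
co-expressing a nuclear marker, an Akt-KTR and an ERK-KTR, stimulated with
GPCR ligands (histamine, sphingosine-1-phosphate, α2-adrenergic agonists):

1. **Image preprocessing** — constant subtraction on the nuclear-marker
   channel (250 counts), rolling-ball background removal (radius 70 px) on
   the Akt channel, and a Gaussian-blur (σ = 2) + threshold (300–65535)
   cell mask from the ERK channel.
2. **Segmentation** — nuclei by a global 330-count threshold with
   intensity-guided declumping, gated to 8–20 px equivalent diameter;
   cells by expanding each nucleus up to 5 px inside the cell mask;
   cytoplasm as the cell-minus-nucleus ring.
3. **Tracking** — greedy nearest-centroid linking (≤ 3 px per frame);
   only tracks present as a single object in every frame are analysed.
4. **Trajectories** — QC gates (mean intensity ~260–~4000 counts, area
   ≥ 100 px, mean radius > 1), C/N = cytoplasmic mean / nuclear mean,
   linear interpolation onto a common time grid (wells are imaged with a
   0.5 min stagger), baseline normalization (subtract the mean of time
   points 5 and 6; stimulation occurs during time point 7 of a 3.5-min
   acquisition), and the response **AUC** — the plain sum of normalized
   C/N over time points 9–18, i.e. 7–38.5 min post-stimulation.
5. **Concentration–response** — per-replicate mean AUCs averaged into a
   grand mean per concentration and fitted with the four-parameter
   logistic `y = c + (d − c) / (1 + exp(b(ln x − ln e)))`, where `e` is
   the EC50; the negative control enters at a small pseudo-concentration.
6. **Clustering** — trajectories over the tp 9–18 window clustered by
   hierarchical clustering (Manhattan/Euclidean × Ward/Ward2) and k-means;
   every (method, k) combination on a 5 × 3 grid (15 combinations per
   kinase) is scored with six internal validation metrics — **BW ratio**
   (mean between-cluster distance over the size-weighted mean
   within-cluster distance), Dunn index, average silhouette width, Pearson
   gamma, Calinski–Harabasz, and connectivity (neighborhood size 25) —
   which are max-normalized and summed into a combined selection score.

A **synthetic-data module** generates both trajectory tables and renderable
three-channel 12-bit TIFF stacks with planted ground truth (baseline C/N
spread 0.20–0.75; flat, low, transient ~10-min-peak, sustained and
biphasic ~35-min-second-peak response archetypes; lognormal amplitude
heterogeneity), so every stage is verifiable by closed-loop recovery.

## Worked example

```python
import numpy as np
from ktrquant import synth, pipeline, doseresponse

# render 50 cells with a transient ERK/Akt response, no noise
cfg = synth.SynthConfig(n_cells=50, noise_sd=0.0, amplitude_cv=0.2, seed=3)
truth = synth.generate_trajectories(cfg, [synth.default_archetypes()["transient"]])
render = synth.render_timelapse(truth, seed=3)

# full extraction: preprocess -> segment -> track -> QC -> C/N
cn = pipeline.extract_trajectories(render.stack)
print(cn["cell_id"].nunique())          # 50   (all planted cells recovered)

traj, summary = pipeline.analyze_trajectories(cn)
print(summary[["auc_erk", "start_ratio_erk"]].head(3).round(3))
#    auc_erk  start_ratio_erk
# 0    3.149            0.562
# 1    2.517            0.683
# 2    4.859            0.373
```

The AUC column is each cell's summed normalized C/N over 7–38.5 min
post-stimulation (a transient response with peak amplitude ~0.5 gives an
AUC of roughly 2–4 depending on the cell's amplitude draw); `start_ratio`
is the pre-stimulation C/N used for basal-activity stratification
(pools 0.15–0.35 / 0.35–0.60 / 0.60–1.00).

The `analysis/` scripts run the same stages as a narrative study —
`01_simulate.py` (synthetic data), `02_extract.py` (image pipeline
closure), `03_dose_response.py` (EC50 recovery), `04_cluster_validation.py`
(the 15-combination validation grid) — writing their tables under
`results/`. A thin CLI wraps the same functions:

```bash
ktrquant synth --seed 1 --outdir out
ktrquant extract out/stack.tif --outdir out
ktrquant analyze out/cn_trajectories.csv --outdir out
ktrquant validate-clusters out/trajectories_normalized.csv --kinase erk
```

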