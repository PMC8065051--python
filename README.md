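# dktihist

Dual-modality analysis of brain tissue microstructure: diffusion kurtosis
tensor imaging (DKTI) metric maps from multi-shell diffusion MRI, a
histogram-of-oriented-gradients (HOG) heterogeneity statistic for stained
histology sections, and the cross-modality correlation between the two —
all exercisable end-to-end on synthetic data.

It is aimed at imaging scientists who want a tested, self-contained
reimplementation of this analysis chain: the kurtosis tensor fit and the
eight scalar metrics, regional (ROI/segmentation) statistics, the tiled
HOG orientation-heterogeneity metrics, and Pearson/Benjamini–Hochberg
correlation of regional values across modalities.

## The model

The diffusion-weighted signal along unit direction **n** at b-value *b*
(s/mm²) is represented as

```
ln S(b, n) = ln S0 − b·D_app(n) + (b²/6)·MD²·W_app(n)
```

with `D_app(n) = nᵢnⱼDᵢⱼ` the apparent diffusivity of the rank-2 diffusion
tensor **D** (mm²/s), `W_app(n) = nᵢnⱼnₖnₗWᵢⱼₖₗ` the projection of the
fully symmetric rank-4 kurtosis tensor **W** (dimensionless), and
`MD = tr(D)/3`. The apparent kurtosis is
`K_app(n) = (MD²/D_app(n)²)·W_app(n)`. The 22 unknowns (ln S0, 6 elements
of **D**, 15 elements of MD²·**W**) are estimated by linear least squares
on log-signals; the model is exactly log-linear, so noiseless signals are
recovered to numerical precision.

Eight scalar metrics are derived per voxel: D_mean, D_axial, D_radial, FA
from the eigenvalues of **D**; K_mean (spherical quadrature average of
K_app), K_axial, K_radial (great-circle average), and KFA =
‖W − W̄·I⁽⁴⁾‖_F / ‖W‖_F ∈ [0, 1], the kurtosis analogue of FA. Axial and
radial metrics can be referred either to the principal eigenvector of
**D** (default) or to a fixed anteroposterior axis.

For histology, ROI images are tiled into non-overlapping 100 µm squares;
per tile, image gradients are binned by unsigned orientation (8 bins) in
20×20-px cells, contrast-normalised over sliding 2×2-cell blocks (L1
norm) and concatenated into a feature vector. Its standard deviation and
excess kurtosis quantify orientation heterogeneity: coherent parallel
fibers concentrate gradient mass in few bins (high kurtosis), mixed
orientations spread it.

## Worked example

Simulate the four-tissue phantom (WM, GM, subcortical nuclei, CSF at
literature regional values), fit the maps, and summarise:

```sh
dktihist make-phantom --out phantom --shape 40 40 16 --snr 40 --seed 1
dktihist fit-maps --dwi phantom/phantom_dwi.nii.gz \
    --bval phantom/phantom.bval --bvec phantom/phantom.bvec \
    --out phantom/maps --no-smoothing
dktihist roi-stats --maps phantom/maps --labels phantom/phantom_labels.nii.gz \
    --names "0:wm:WM,1:gm:GM,2:scn:SCN,3:csf:CSF" --out phantom/roi.csv
```

which prints

```
phantom written to phantom (40x40x16, 91 measurements)
maps written to phantom/maps; 25600/25600 voxels valid (0.0% invalid)
ROI statistics for 4 ROIs written to phantom/roi.csv
```

`phantom/roi.csv` then contains, per ROI and metric, the mean/SD/SEM over
voxels; at SNR 40 the recovered regional medians sit within a few percent
of the ground truth (WM D_mean 0.60×10⁻³ mm²/s and K_mean 1.17, GM
0.80×10⁻³ / 0.82, CSF high-diffusion/low-kurtosis), reproducing the
qualitative regional ordering d(CSF)>d(GM)>d(WM) and k(WM)>k(GM)>k(CSF).

The full synthetic analysis — phantom, maps, per-ROI histology textures
with coherence tied to tissue type, and the cross-modality correlation
table — runs as

```sh
dktihist run-all --seed 1 --out results_run
```

```
pipeline complete: 72 ROI-metric rows, 8 correlations -> results_run
strongest pair: d_mean vs kurtosis (r=0.91, adj p=0.00896)
```

mirroring the positive diffusivity-vs-histological-kurtosis association
the method is designed to detect.

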