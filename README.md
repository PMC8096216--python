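# nucleoquant

Quantitative image analysis for classifying nucleolar (and other
membrane-less) condensates as **polymer–polymer phase separated (PPPS)** or
**liquid–liquid phase separated (LLPS)** from cropped 3D fluorescence
microscopy stacks. Written for cell biologists quantifying budding-yeast
nucleolar components (rDNA-binding proteins such as Cdc14 and Net1 vs
ribonucleoproteins such as Cbf5 and Nop56), but the measurements are generic.

The two regimes differ in measurable ways, and the package implements one
readout per distinction:

| readout | PPPS (compressible polymer) | LLPS (liquid droplet) |
|---|---|---|
| GLCM homogeneity of the sum projection, Σ p(i,j)/(1+\|i−j\|) | low (punctate) | high (smooth) |
| Pearson r of volume vs mean intensity above background across a population | strongly negative (fixed amount, variable volume) | ≈ 0 (fixed concentration) |
| compression = mean intensity above background / volume | rises with crosslinking | insensitive |
| heterogeneity = SD of min–max rescaled foreground | high | low |
| FRAP percent recovery | low (immobile scaffold) | high (mobile liquid) |
| two-channel Pearson + relative positional variance σ²/μ of A-voxel distances to B's centre | shell-like exclusion → low rpv | intermixed → rpv ≈ R/20 |

Every stage runs on a per-stack Otsu background threshold with strict
`intensity > t` foreground. A ground-truthed synthetic generator (uniform
droplets at fixed concentration; conserved-intensity Gaussian puncta whose
compaction tracks a crosslink-density parameter; shell/intermixed two-channel
geometries; exponential FRAP recovery under imaging bleach) makes the whole
pipeline testable without any microscope data. See `docs/methods.md` for the
full model descriptions, conventions and limitations.

## Worked example

Simulate three multi-puncta (PPPS-like) and three droplet (LLPS-like) crops,
then score their homogeneity:

```sh
nucleoquant simulate --regime ppps --n 3 --out sim_ppps --seed 1
nucleoquant simulate --regime llps --n 3 --out sim_llps --seed 1
# manifest.csv: columns id,group,path_channel1 pointing at the six TIFFs
nucleoquant homogeneity --manifest manifest.csv --out homog --seed 1
```

`homog/records.csv` then contains (values printed by the run above):

```
   id   group  threshold  n_pairs  homogeneity
ppps0  puncta 670.563885      121     0.545730
llps0 droplet 689.877106      119     0.637955
ppps1  puncta 606.992380      129     0.574160
llps1 droplet 621.583147      121     0.623967
ppps2  puncta 626.009539      131     0.552545
llps2 droplet 747.797395      118     0.632768
```

`threshold` is the Otsu background level of each sum projection, `n_pairs`
the number of valid horizontal pixel pairs entering the co-occurrence
matrix, and `homogeneity` the texture score in (0, 1]: every droplet scores
higher (≈ 0.62–0.64) than every punctate signal (≈ 0.55–0.57), the
direction that separates liquid-like from polymer-like components. At
population scale (100 images per regime) the gap is highly significant
(rank-sum p < 10⁻²⁰).

The same pattern holds for the other subcommands: `volint` (per-cell
morphometry plus the outlier-gated volume–intensity Pearson correlation per
group), `heterogeneity`, `coloc`, `rpv` (two-channel manifests with
`path_channel2`), and `frap` (manifests with `prebleach`, `laser`,
`timelapse` columns). Each run writes `records.csv`, `summary.json` and
`run.log` into `--out`, and reruns with the same config and seed are
byte-identical. The library mirrors the CLI one-to-one
(`nucleoquant.homogeneity_score`, `compute_signal_metrics`,
`volume_intensity_correlation`, `channel_correlation`,
`relative_positional_variance`, `normalize_with_correction`, ...).

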