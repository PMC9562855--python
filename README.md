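# spadinv

Hyperspectral inversion of relative leaf chlorophyll content (SPAD) for
canopies under pest stress — specifically jujube (*Ziziphus jujuba*)
orchards infested by leaf mites, where chlorophyll loss tracks infestation
severity.  The package covers the full workflow a UAV hyperspectral
campaign needs once images are on disk:

1. **Radiometric preprocessing** — empirical-line calibration from digital
   numbers (DN) to reflectance using gray reference plates,
   `rho_t = (DN_t - DN_1)/(DN_2 - DN_1) * (rho_2 - rho_1) + rho_1`;
   irradiance-consistency correction `L_jc = L_j * E_j / E_ref` across
   images; Savitzky–Golay spectral smoothing; minimal ENVI cube I/O.
2. **Feature analysis** — six vegetation indices (NDVI, RVI, PhRI, MCARI,
   TCARI, GI), first-derivative spectra, per-band Pearson correlation
   profiles against SPAD, and single-index linear SPAD models scored by
   R² and RMSE.
3. **Band selection** — the successive projections algorithm (SPA): greedy
   forward chains maximizing the orthogonal-projection residual norm,
   scored by multiple-linear-regression RMSE per subset size, with the
   classical F-ratio parsimony rule for the winning subset size.
4. **Regression** — extreme learning machine (ELM: random hidden layer in
   [-1, 1], least-squares readout) and its particle-swarm-optimized
   variant (PSO-ELM), where each particle encodes the hidden weights and
   thresholds as `theta = (w_11..w_nt, b_1..b_t)`, dimension `D = t(n+1)`,
   updated by `v <- omega v + c1 r1 (pbest - x) + c2 r2 (gbest - x)` with
   omega = 0.9 and c1 = c2 = 1.4.
5. **Mapping** — per-pixel SPAD prediction over reflectance cubes and
   SPAD-threshold classification into severity grades I–IV.

Because no field data accompany the study design, the package ships a
first-class synthetic generator (`spadinv.synthetic`) that emulates the
canopy spectra — green peak near 550 nm, red absorption valley near
670 nm, logistic red edge at 715 nm, NIR plateau — together with SPAD
values whose class means fall with severity and whose coefficient of
variation is ≈21%.  Every stage of the pipeline is exercisable and tested
against it.

## Worked example

```python
import numpy as np
import spadinv as sv

# 1. simulate a study-scale campaign: 1,200 canopy samples, four severities
samples = sv.generate_sample_set(sv.GeneratorConfig(n_samples=1200, seed=0))

# 2. vegetation-index screening
tab = sv.compute_vi_table(samples)
for name in sv.VI_NAMES:
    r = np.corrcoef(tab[name], samples.spad)[0, 1]
    print(f"  {name:6s} r = {r:+.3f}")

# 3. SPA band selection
res = sv.spa_select(samples.reflectance, samples.spad,
                    sv.SPAConfig(max_k=10), grid=samples.grid)

# 4. ELM vs PSO-ELM on an 800/400 split over the 5 best bands
bands = res.best_subsets[5]
mod, val = samples.split(seed=0)
Xm, Xv = mod.reflectance[:, bands], val.reflectance[:, bands]
elm = sv.elm_train(Xm, mod.spad, n_hidden=20, seed=0)
pso, trace = sv.pso_elm_train(Xm, mod.spad, n_hidden=20, swarm_size=30,
                              max_iter=100, seed=0)
table = sv.compare_models({"ELM": elm, "PSO-ELM": pso},
                          Xm, mod.spad, Xv, val.spad,
                          ids_mod=mod.sample_id, ids_val=val.sample_id)
print(table.round(3).to_string(index=False))
```

prints

```
  NDVI   r = +0.878
  RVI    r = +0.864
  PhRI   r = +0.824
  MCARI  r = +0.192
  TCARI  r = -0.275
  GI     r = -0.315
  model  r2_modeling  rmse_modeling  r2_validation  rmse_validation
    ELM        0.991          0.882          0.989            0.941
PSO-ELM        0.992          0.833          0.990            0.932
```

The index correlations carry the canonical sign pattern for chlorophyll
loss under mite stress — NDVI/RVI/PhRI/MCARI positive, TCARI/GI negative —
and the PSO-optimized ELM edges out the randomly initialized one on both
the modeling and the held-out validation split (RMSE in SPAD units).

A command-line interface mirrors the pipeline:

```sh
spadinv simulate samples --n 1200 --seed 0 --out samples.csv
spadinv spa --samples samples.csv --max-k 10 --out spa.json
spadinv train --samples samples.csv --bands spa.json --model pso-elm --out model.json
spadinv evaluate --model model.json --samples samples.csv --out table.csv
spadinv simulate scene --out scene.hdr && spadinv map --cube scene.hdr --model model.json --out map.csv
```

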