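# dentopo

Fully three-dimensional topographic quantification of tooth crowns from
paired triangle meshes of the **outer enamel surface (OES)** and the
**enamel–dentine junction (EDJ)**.

The occlusal shape of a tooth develops from the EDJ, which acts as a primer
that the growing enamel cap then modifies: enamel is not deposited evenly,
so the OES is not a parallel copy of the junction. Quantifying *how* the
enamel transforms the junction requires (1) topographic descriptors that
work in full 3D — keeping re-entrant surfaces, vertical walls and overhung
regions that 2.5-D GIS-style analyses discard — and (2) a geometric
correspondence that pairs every patch of enamel surface with the junction
beneath it. `dentopo` implements both, for dental morphologists working on
primate (or other mammalian) molars from µCT-derived surface meshes.

## What it computes

Given an OES/EDJ mesh pair (PLY/OFF/STL/OBJ) and the three dentine-horn
landmarks (protocone, paracone, metacone tips):

* **canonical alignment** — reference plane through the three tips mapped
  to xy, mesial axis ∥ x, cervix at z = 0, occlusal relief on +z;
* **re-tessellation** to ~22,000 near-uniform triangles whose unit area
  scales with tooth size;
* **per-polygon signifiers** — area υ, barycenter χ, elevation γ,
  orientation ψ (normal azimuth, 0–360°), inclination λ (180° horizontal →
  90° vertical → <90° re-entrant), mean curvature φ and its
  size-standardized form φ_std;
* **enamel thickness** δ — exact minimum Euclidean distance from each OES
  node to the nearest EDJ triangle, with the node→triangle and face→face
  correspondence matrix stored;
* **complexity** ψ^c — orientation binned at 45°, maximal edge-connected
  same-bin patches of ≥ 3 faces counted per bin and in total;
* **indices** — area-weighted δ mean/sd, standard thickness
  δ^st = Σδυ/A_EDJ, occlusal relief index
  Γ = Σ(υγ | λ>135°)/Σ(υγ | λ<135°), classic relief index (3D/2D area),
  relative crest area φ^p, maximum convexity index φ^mci, blunting index
  φ^bi = φ^p_EDJ/φ^p_OES, relative complexity ψ^c-e/d, plus binned
  inclination/orientation/curvature/thickness profiles;
* **covariation** — OES and EDJ signifiers paired through the
  correspondence matrix, Pearson r on 130 seeded subsamples of 1000 rows
  with two-sided significance at p < 0.01;
* **morphometric maps** — each signifier written back onto the surfaces as
  colored PLY.

Because no reference specimens ship with the package, a synthetic module
generates analytic primitives (sphere, cone, cylinder, concentric shells…)
with closed-form signifiers and four-cusp crown pairs with exactly known
enamel thickness; the entire pipeline is validated against these oracles.

## Worked example

Generate a synthetic molar with 0.6 mm of uniform enamel and analyze it:

```python
from dentopo import AnalysisConfig, analyze_pair
from dentopo.synthetic import SyntheticToothSpec, make_synthetic_tooth

oes, edj, lm, truth = make_synthetic_tooth(
    SyntheticToothSpec(target_faces=22000, seed=1))
res = analyze_pair(oes, edj, lm,
                   AnalysisConfig(retessellate=False, seed=1))
print(res.report_oes.to_dict())
print(res.report_pair.to_dict())
```

prints (abridged):

```
OES :  delta_mean 0.600  delta_sd 0.000  delta_st 0.697
       gamma 3.429  ri_classic 1.244  psi_c 41  phi_mci 0.277
EDJ :  gamma 2.444  ri_classic 1.270  psi_c 37  phi_p 0.067  phi_mci 0.294
PAIR:  phi_bi 160.0  psi_c_ratio 1.108  relief_accentuation 1.403
       scale_free_thickness 0.097
```

Reading these numbers: the recovered mean occlusal thickness equals the
0.6 mm the generator deposited (δ_sd ≈ 0 because it is uniform); δ^st
exceeds δ_mean because the OES is larger than the EDJ it wraps. Γ > 1 says
flat, elevated area dominates steep area on this crown, and relief
accentuation of 1.40 with Γ^OES > Γ^EDJ says the enamel blanket flattens
the junction's relief. The extreme φ^bi is the designed limit of the
blunting index on *uniform* enamel: a constant-thickness offset blunts
essentially every junction crest below the crest threshold, so the OES
crest area nearly vanishes; real (uneven) enamel yields moderate values.
The subsampled correlations report r(λ^OES, λ^EDJ) ≈ 1.0 — parallel
surfaces — and r(λ^OES, δ) ≈ −0.51, both significant in 130/130
subsamples.

The same analysis runs from the shell:

```sh
dentopo synth -o pair --faces 22000 --thickness 0.6
dentopo analyze pair/oes.ply pair/edj.ply pair/landmarks.json -o out
dentopo maps pair/oes.ply pair/edj.ply pair/landmarks.json -o maps
```

`out/` then contains the signifier tables, correspondence matrix, patch
tables, profiles, indices and correlations as CSV/JSON, each stamped with
the config hash.

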