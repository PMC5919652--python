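# fastdki

Fast diffusion-kurtosis (1-9-9) estimation, stroke lesion volumetry and
Cavalieri stereology on a synthetic rat-brain stroke phantom.

## The problem

In experimental stroke, the lesion outlined on **mean kurtosis** maps is
consistently larger than the lesion on **mean diffusivity (MD)** maps; the
surplus ring is a candidate marker of metabolically challenged tissue
around the infarct core.  Quantifying this mismatch requires three
measurement chains that this package implements end to end:

1. **Fast DKI fitting.**  Diffusion kurtosis imaging models the log-signal
   with the two-term cumulant expansion
   `log S(b, n̂) = −b nᵢnⱼDᵢⱼ + (b²/6) D̄² nᵢnⱼnₖnₗWᵢⱼₖₗ`,
   with the diffusion tensor `D` (μm²/ms), the fully symmetric rank-4
   kurtosis tensor `W`, and `D̄ = Tr(D)/3`.  The mean of the kurtosis tensor
   (MKT) is the spherical average of the apparent kurtosis `W(n̂)`, equal to
   `(1/5)(W_xxxx + W_yyyy + W_zzzz + 2W_xxyy + 2W_xxzz + 2W_yyzz)`.
   The 1-9-9 protocol — one b = 0 image plus nine directions (three axes,
   six bisectors, weighted 1/15 and 2/15) at each of two shells b₁ < b₂ —
   collapses the directional model into two scalar log-sum equations
   `A_s = −b_s D̄ + (b_s²/6) D̄² W̄` and admits the closed forms

       D̄ = (b₁²A₂ − b₂²A₁) / (b₁b₂² − b₁²b₂)
       W̄ = 6 b₁b₂ (A₁b₂ − A₂b₁)(b₁ − b₂) / (A₁b₂² − A₂b₁²)²

   which invert noiseless signals exactly, for anisotropic tensors too.
2. **Lesion volumetry.**  Voxelwise MD/MKT maps, threshold segmentation
   against the contralateral hemisphere (MD lesions are hypointense, MKT
   lesions hyperintense), and volume = voxel count × voxel volume.
3. **Cavalieri stereology** for the histology arm: 40 μm sections, a 1/15
   systematic sample, per-section areas by grid point counting or the 2D
   nucleator, and `V = t · (1/SSF) · Σ aᵢ`.

No imaging data ships with the package: the `phantom` module generates a
two-hemisphere brain (1.433 cm³) holding a 0.232 cm³ MD-hypointense lesion
core nested inside a 0.304 cm³ MKT-hyperintense lesion — a designed 31%
volume excess — imaged with the 19-volume protocol
(b = 0, 1, 2.5 ms/μm², 0.25 × 0.25 × 0.5 mm voxels) under Rician noise.
Every stage is therefore testable against known ground truth.

## Worked example

```python
import fastdki as fd

spec = fd.default_spec()                      # the study phantom, SNR 50
truth = fd.generate_phantom(spec)
series = fd.simulate_acquisition(truth, snr=50, seed=1)
md_map, mkt_map = fd.fit_maps(series, truth.masks["brain"])
les_md = fd.segment_lesion(md_map, truth.masks["brain"],
                           truth.masks["left"], "md_low", k=2.0)
les_mkt = fd.segment_lesion(mkt_map, truth.masks["brain"],
                            truth.masks["left"], "mkt_high", k=2.0)
v_md = fd.volume_from_mask(les_md, spec.voxel_size_mm)
v_mkt = fd.volume_from_mask(les_mkt, spec.voxel_size_mm)
print(f"MD {v_md:.4f} cm^3, MKT {v_mkt:.4f} cm^3, "
      f"excess {fd.mismatch_percent(v_mkt, v_md):.1f}%")
```

prints

```
MD 0.2300 cm^3, MKT 0.2978 cm^3, excess 29.5%
```

i.e. the MD lesion volume is recovered near its 0.2323 cm³ ground truth,
the MKT lesion near its 0.3054 cm³ truth, and the volume excess lands near
the designed 31%.  The numbered drivers under `analysis/` run the full
study: `01` builds the phantom, `02` fits and profiles the maps, `03`
repeats the MRI volumetry over 50 noise seeds (excess 29.1 ± 0.6%), `04`
runs the Cavalieri/histology arm (mean over start offsets within 0.1% of
truth), and `05` compares the three arms over a 7-subject cohort with
paired t-tests and absolute-agreement ICC.  Tables land in `results/`,
bulky NIfTI output in `scratch/`.

A thin CLI mirrors the pipeline for on-disk data
(`fastdki fit|segment|volumes|mismatch|stats`); schemes round-trip through
FSL-style `bvals`/`bvecs` and a JSON descriptor.

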