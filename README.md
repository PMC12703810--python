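# mrfkit

Quantitative T1/T2 mapping by MR fingerprinting (MRF), end to end and fully
synthetic: simulate an inversion-prepared FISP echo train, build and
SVD-compress a (T1, T2, B1) dictionary, match image series per pixel with
B1-informed inner products and low-T1 masking, and run the phantom/in-vivo
validation statistics (test-retest variation, longitudinal CV, deviation
from NMR reference, Bland-Altman, region summaries, age trends) — all
driven by a digital phantom generator, so no scanner data is required.

## Modules

| Module | Purpose |
| --- | --- |
| `mrfkit.sequence` | Acquisition schedules; EPG signal simulation; isochromat reference simulator |
| `mrfkit.dictionary` | (T1, T2, B1) grid construction, atom simulation, SVD temporal compression, HDF5 persistence |
| `mrfkit.matching` | Per-pixel exhaustive inner-product matching, B1 snapping, T1 < 400 ms masking |
| `mrfkit.phantom` | Synthetic vial phantom, brain-like volumes, smooth B1 fields, noisy test-retest acquisitions |
| `mrfkit.relaxometry` | Gold-standard inversion-recovery T1 and spin-echo T2 fits |
| `mrfkit.qa` | ROI extraction and all validation statistics |
| `mrfkit.io`, `mrfkit.pipeline`, `mrfkit.cli` | NIfTI/HDF5/CSV I/O, pipeline orchestration, CLI |

Key defaults follow the published acquisition and dictionary: 1500 time
points, TE 2 ms, TI 21 ms, TR in [12.1, 15.0] ms, flips in [0, 74°]; T1 grid
10–4500 ms and T2 grid 2–3000 ms with increasing step sizes; relative B1
0.6–1.4 (step 0.01); 50 SVD components; voxels 1 × 1 × 5 mm. The exact
vendor flip/TR pattern is not public — a documented stand-in is generated,
and any measured schedule can be loaded from CSV (`index,tr_ms,fa_deg`).

## CLI

```sh
# synthetic phantom + one acquisition
mrfkit simulate --shape 112 112 7 --noise-sd 0.01 --seed 7 --out sim/

# dictionary on the default grid (thinned to B1=1.0), SVD rank 50
mrfkit build-dict --b1-subset 1.0 --rank 50 --out dict.h5

# B1-informed matching with T1 < 400 ms masking
mrfkit match --series sim/series.nii.gz --b1 sim/b1.nii.gz \
             --dict dict.h5 --t1-mask 400 --out maps/

# QA statistics from a long-format measurement table
mrfkit qa-report --measurements measurements.csv --reference ref.json --out report/

# everything in one go (YAML config optional)
mrfkit run-all --out run/ --seed 7 --noise-sd 0.005
```

`run-all` writes NIfTI truth/B1/series volumes, the HDF5 dictionary,
parameter maps (`t1/t2/m0/score` float32 with NaN at masked voxels plus a
`mask` volume), the measurement table, QA report (CSV + JSON) and a
`manifest.json` with config hash, seeds and SHA-256 checksums of every
output.

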