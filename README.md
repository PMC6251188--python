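# fibwave

Wavefront-dynamics analysis for optically mapped fibrillation, plus a
synthetic excitable-media generator for ground-truth validation.

Given a gridded voltage movie (`T x H x W` frames with a valid-tissue mask,
frame interval in ms, pixel pitch in mm), the pipeline:

1. **conditions** the signal — mask-aware 9x9 spatial boxcar, dominant-
   frequency (DF) estimation, zero-phase equiripple FIR band-pass
   (2 Hz to 125 % of the mean DF), baseline-drift removal, min-max
   normalization;
2. computes **instantaneous phase** — sliding-window extrema with
   small-amplitude pair rejection, cubic-spline envelope normalization,
   Hilbert transform, and circular (complex-exponential) 9x9 spatial
   smoothing;
3. detects and tracks **phase singularities** by the topological-charge
   (winding-number) rule with a candidate/actual neighbour consensus,
   greedy nearest-neighbour tracking, probe-pixel rotation counting
   (a singularity lasting more than one rotation is a *rotor*), and
   trajectory / initiation / annihilation density maps;
4. extracts **isophase wavefronts** at phase -pi/2 and classifies every
   wavefront component as *propagated*, *new during existing activity*, or
   *new after electrical quiescence*, building new-wavefront (NWF) density
   maps and preferential initiation sites with per-site cycle lengths;
5. infers the **sustaining mechanism** (rotor-driven vs NWF-driven vs
   mixed) from the per-frame rotor / singularity / active-pixel series,
   with map correlation and Mood's median test for comparisons.

The `fibwave.synthetic` module generates analytic spiral/plane-wave phase
films, quiescence-guaranteed focal-source movies, two-variable
reaction-diffusion simulations, and a two-layer sheet pair coupled at
discrete connection sites (with stochastic anisotropic fibrosis and
recovery-shortening islands) that reproduces transmural breakthrough with
exact ground truth.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria (oracle
equivalence, core localization, rotor classification, NWF recovery,
mechanism labelling, two-layer breakthrough); the rest are per-module unit
and property tests.

## CLI

```bash
fibwave run movie.npz --out results/            # full pipeline
fibwave phase movie.tif --dt 1 --pitch 0.44 --out results/
fibwave ps movie.h5 --out results/              # singularity tracks + maps
fibwave nwf movie.h5 --out results/             # new-wavefront events + sites
fibwave maps movie.h5 --out results/            # DF / PS / NWF maps
fibwave simulate --regime spiral --seed 1 --out sim/
```

Movies are accepted as multi-page TIFF (supply `--dt`/`--pitch`), an HDF5
container (datasets `frames`, `mask`; attrs `dt_ms`, `pitch_mm`), or an
`.npz` archive with the same names. Products are CSV tables (tracks,
events), text-grid density maps, and a JSON manifest; configuration is a
YAML/JSON mirror of `fibwave.RunConfig`, whose defaults reproduce the
published parameter set (9x9 bins, 2 Hz low edge, 1.25 x DF high edge,
0.9 x CL extrema window, 15 % amplitude rejection, 3.0 rad charge
tolerance, isophase -pi/2 with 0.5 rad band).

## Library example

```python
import fibwave
from fibwave.synthetic import focal_movie

movie, truth = focal_movie(origin=(20, 20), cycle_ms=80, cv_mm_per_ms=1.0,
                           apd_ms=30, duration_ms=1000, grid=(40, 40))
result = fibwave.analyze(movie, fibwave.RunConfig(), precondition=False)
print(result.label)                      # "nwf_sustained"
print(result.sites[0].cycle_lengths)     # ~[80.0, 80.0, ...]
```
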