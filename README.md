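# emcspi

Simulation and reconstruction toolkit for **single-particle X-ray
imaging** (SPI).  In an SPI experiment, single biomolecules are injected
into an X-ray free-electron-laser beam and each pulse produces one
diffraction snapshot of one particle in an unknown, uniformly random
orientation.  The frames are extremely sparse — often fewer than a
hundred photons — so no frame can be oriented on its own.  This package
reconstructs the 3D diffraction volume from such data with the
**expand–maximize–compress (EMC)** algorithm, and ships the surrounding
workflow: a photon-level simulator, the sparse data format, quasi-uniform
rotation sampling, convergence diagnostics and an experiment-sizing
planner.

## The algorithm

Each pixel `t` of each frame `d` is an independent Poisson sample: for a
particle at orientation `r` the probability of observing counts `K_dt`
given the model tomogram `W_rt` (a curved Ewald-sphere slice of the 3D
volume `W`) is

    R_dr = prod_t  (W_rt)^K_dt  exp(-W_rt) / K_dt!

and, since the particle must have *some* orientation,
`P_dr = w_r R_dr / sum_r' w_r' R_dr'`.  One EMC iteration **expands** the
current volume into tomograms `W_rt` by trilinear slicing, computes
`P_dr` (**E-step**), replaces each tomogram by the probability-weighted
mean of the data, `W'_rt = sum_d P_dr K_dt / sum_d P_dr` (**M-step**),
and **compresses** the tomograms back into the 3D grid with the adjoint
trilinear scatter.  Optional per-frame scale factors absorb
pulse-to-pulse fluence variation, and a deterministic-annealing exponent
(`P_dr ∝ R_dr^β`, β raised from ≪1 toward 1 on a schedule) prevents the
hard-assignment local maxima that bright data produce.  Rotations are
sampled quasi-uniformly by refining the 600-cell: exactly
`M_rot = 10(5n³+n)` samples at level `n`.

See `docs/methods.md` for conventions, update rules and design choices.

## Worked example

Plan an experiment for a particle with dimensionless radius
`R̄ = R_p/a = 5`, speckle sampling σ = 5, 100 photons per frame and a
modest signal-to-noise parameter S = 10:

```
$ emcspi plan -S 10 -N 100 --sigma 5 --rbar 5
S          = 10
N          = 100
sigma      = 5
R_bar      = 5
n_level    = 5
M_rot      = 6300
M_data     = 6300
M_sp_MB    = 4.807
M_W_MB     = 0.9537
M_prob_GB  = 0.2957
```

Reading: level-5 rotation sampling gives 6300 orientation samples;
S² = 100 photons per orientation then requires
`M_data = S²·M_rot/N = 6300` frames; the sparse data occupy ~4.8 MB, the
dense model ~0.95 MB and the frame×orientation probability matrix
~0.3 GB.

Simulate and reconstruct a phantom end to end (`config.ini` holding a
32-pixel detector at 200 mm, λ = 6.2 Å, 500 frames of ~100 photons):

```
$ emcspi sim-setup
wrote 500 frames (50107 photons) to photons.emc; true model side 49
$ emcspi emc 10
...
iter   9  beta=1  rms=6.9438e-04  MI=2.1374  LL=-1.927006e+02  (0.5s)
iter  10  beta=1  rms=6.5309e-04  MI=2.2795  LL=-1.924801e+02  (0.5s)
finished at iteration 10 (beta=1, M_rot=420)
```

The r.m.s. model change falls as the run converges while the mutual
information between frames and orientations (bounded by
`ln M_rot = ln 420 ≈ 6.04` nats) and the average log-likelihood rise.
Per-iteration volumes land in `output/intensities_NNN.bin`;
`emcspi plot output/EMC.log` renders the four diagnostic panels, and
`emcspi emc 5 --resume` (or `-R` to refine the rotation sampling one
level) continues a previous run.

As a library:

```python
import emcspi as E

cfg  = E.parse_config(open("config.ini").read())
det  = E.make_detector(cfg)
geom = E.compute_geometry(cfg, R_p=18.9)   # -> a, L, R_bar, sigma
ps   = E.read_photons(cfg.in_photons_file)
state = E.run_emc(cfg, det, ps, iterations=30)
```

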