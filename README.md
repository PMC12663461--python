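# asymdiv

Quantification of asymmetric endosome segregation during asymmetric cell
division, from multi-channel fluorescence movies and fixed-cell z-stacks.

During the division of a neural progenitor, endosomes carrying
internalized Notch ligand first converge toward the central zone of the
cell and then move in a polarized fashion toward the posterior pole, so
that one daughter inherits more ligand than the other.  `asymdiv`
implements the full measurement chain needed to quantify this behaviour:

- **Spot detection and tracking** of endosomes and centrosomes
  (scale-normalized Laplacian-of-Gaussian detection with sub-pixel
  refinement; deterministic greedy nearest-neighbour linking with gap
  closing).
- **Registration**: the centrosome pair defines the anterior–posterior
  (A-P) axis per frame — the anterior centrosome gets normalized
  coordinate *s* = 0, the posterior one *s* = 1 — and T = 0 is the first
  sustained appearance of the cleavage furrow.
- **Kinematics**: kymographs of endosome occupancy probability along the
  axis, telophase position distributions, speeds in µm/min, and the
  headline statistic, the **asymmetry index**

  ```
  X = (Σ Ints_post − Σ Ints_ant) / (Σ Ints_post + Σ Ints_ant)
  ```

  of background-subtracted daughter-cell intensities.  X = 0 is perfect
  symmetry, X = ±1 absolute asymmetry; |X| ≥ 0.2 (one daughter holding at
  least 50 % more signal) is classified asymmetric (posterior or anterior).
- **Colocalization**: thresholded Manders coefficients M1/M2 with blank-
  region or Costes automatic thresholds and a Costes block-randomization
  significance test, within geometry-defined regions such as the
  inter-nuclear central zone.
- **Composition**: segmentation of endosomes in fixed anaphase cells,
  zone assignment (central / anterior / posterior surround), per-marker
  presence calls, DAPI-normalized cargo intensity and cargo area
  fractions, and division-orientation classes.
- **Statistics**: chi-square tests on category tables, two-tailed
  unpaired t-tests, simple linear regression (R², F, Sy.x), cohort
  summaries, and a deterministic report writer.
- **A synthetic-data generator** that simulates dividing cells (membrane,
  centrosome and endosome channels; biased-random-walk endosomes; PSF
  blur; Poisson + Gaussian noise) and fixed composition scenes, with full
  ground truth for every stage.

## Worked example

Simulate one dividing cell with a 90 % posterior step bias and push it
through the full analysis:

```python
from asymdiv.synthetic import DivisionSceneConfig, simulate_division_movie
from asymdiv.io_core import Annotation, RegionBox
from asymdiv.registration import register_movie
from asymdiv.kinematics import compute_asymmetry, average_velocity, telophase_position
from asymdiv.tracking import detect_movie_spots, link_tracks

config = DivisionSceneConfig(seed=7, p_bias=0.9)
movie, truth = simulate_division_movie(config)

ann = Annotation(anterior_direction=(0.0, 1.0),
                 blank_region=RegionBox((0, 0), (16, 16)))
reg = register_movie(movie, ann)                      # axis + anaphase onset
spots = detect_movie_spots(movie, "endosome", 0.25, 5.0, 0.3)
tracks = link_tracks(spots, max_disp_um=1.0, max_gap_frames=1)

res = compute_asymmetry(movie, reg, "endosome", movie.n_frames - 1,
                        ann.blank_region)
v = average_velocity(tracks, reg, window_minutes=(0.0, 4.0))
print(f"t0 = {reg.t0}")
print(f"X = {res.index:.3f} -> {res.label} (truth X = {truth.asymmetry_index:.3f})")
print(f"mean speed = {v.speed_um_min:.2f} um/min")
print(f"telophase mean s = {telophase_position(tracks, reg, 4.0):.3f}")
```

prints

```
t0 = 20
X = 0.297 -> posterior (truth X = 0.333)
mean speed = 1.22 um/min
telophase mean s = 0.738
```

Anaphase onset is recovered at the simulated frame (20); the cell is
classified posterior-asymmetric, in agreement with the ground truth; the
mean post-anaphase endosome speed (1.22 µm/min) reflects the configured
1.2 µm/min drift; and the mean normalized endosome position at telophase
(0.738) lies well toward the posterior centrosome (*s* = 1).

The same flows are available from the shell:

```bash
asymdiv simulate-division scene.yaml cell.ome.tif --seed 7
asymdiv track cell.ome.tif --sidecar cell.yaml --channel endosome -o tracks.csv
asymdiv asymmetry cell.ome.tif --sidecar cell.yaml -o results/
asymdiv coloc fixed.ome.tif --ch Par3 --ch Dld --threshold costes --n-iter 200
asymdiv compose fixed.ome.tif --reference Dld --markers Par3,Dlic1
```

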