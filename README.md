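# enclavekit

Label-free lineage tracking and genealogical-enclave analytics for growing
bacterial monolayer colonies.

When a surface-attached rod-shaped bacterium (e.g. *E. coli*) grows into a
monolayer colony, the descendants of the founder cell's two daughters — its
two *progeny chains* — do not intermix freely.  They demix into two
contiguous *genealogical enclaves* separated by an active interface, a
spatial organization invisible to standard imaging and only recoverable by
following every cell and division through the time-lapse.  `enclavekit`
provides the full computational stack for studying this process:

* **tracking** — a label-free lineage tracker for integer-labeled
  segmentation masks.  Cells are linked frame to frame by a centroid cutoff
  d_c ≈ 0.75 µm (mutual-uniqueness rule), divisions are detected by matching
  a mother's two *dummy centroids* (the predicted daughter centroids at
  ±l_c/4 along its axis) to newborn cells, and fast-moving boundary cells
  are rescued by pole displacement.  Chains 1 and 2 are rooted at the two
  cells of frame 0 and inherited at every division.
* **geometry** — enclave polygons, centroid separation Δc, interface length
  via L_interface = (Ps₁ + Ps₂ − L_colony)/2, per-cell contact graphs with
  inter-/intra-chain contact fractions, moving-box Shannon entropy
  SE(B) = −p_r ln p_r − p_g ln p_g with a label-permutation null, interface
  curvature κ, and invasion-front regions with mean invasion widths.
* **nematics** — structure-tensor orientation fields, the scalar nematic
  order parameter S_R = √(⟨cos 2Φ⟩² + ⟨sin 2Φ⟩²) on a moving grid,
  winding-number detection of ±1/2 topological defects, location classes
  (interface / boundary / bulk), and frame-to-frame defect linking.
* **lattice** — a coarse-grained square-lattice colony model: log-normal
  division clocks (25 °C: 48 ± 13 min; 37 °C: 21 ± 6 min; both CV ≈ 0.27),
  Moore-neighborhood daughter placement, and a shoving rule that translates
  runs of cells outward with probability ∝ 1/run-length, plus on-lattice
  demixing metrics.
* **synthetic** — a ground-truthed generator: off-lattice spherocylinder
  colonies with exponential elongation and stochastic division rendered to
  16-bit labeled masks, analytic director fields with planted defects, and
  two-color point patterns.  Every downstream module is testable without
  external microscopy data.

## Worked example

The `demo` subcommand grows a synthetic colony, tracks it, and runs the
enclave and lattice analytics:

```sh
enclavekit demo --n 48 --seed 1 --null-iters 2000 --out demo_out
```

prints

```
81 frames, 48 cells -> demo_out/colony
94 tracks, 46 divisions, 0 unresolved -> demo_out/tracking
analyzed 81 frames -> demo_out/enclaves
ensemble mean SE 0.2680, contacts 0.1930 -> demo_out/lattice
demo complete -> demo_out
```

Reading the outputs: the tracker resolved every cell in all 81 frames (no
unresolved cells) and found all 46 division events.  In
`demo_out/enclaves/enclaves.csv` the final frame shows the two enclaves
holding 104.0 and 91.6 µm² — each roughly half the colony — with centroids
6.6 µm apart and 53% / 47% of the colony outline exposed to the exterior,
the equitable partition characteristic of genealogical demixing.
`entropy_null.yaml` reports the arrangement entropy of the final frame,
SE = 0.230, far below the mean of 0.526 (± 0.039) obtained when the same
positions are relabeled at random 2000 times (observed value at the 0th
percentile of the null): the colony is much more demixed than chance.  The
inter-enclave contact fraction falls from 0.40 mid-movie to 0.19 in the
final frame as the enclaves consolidate.  The lattice ensemble (20 seeds,
n = 128) shows the same ordering of entropy and contacts.

Individual stages are available as `generate-colony`, `track`,
`analyze-enclaves`, `analyze-defects` and `simulate-lattice`; every run
writes a `manifest.yaml` echoing all parameters and seeds so outputs are
bit-reproducible.

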