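# priorphase

Markerless respiratory **phase recognition** for rotational lung
radiotherapy, from **prior 4D-CBCT re-projections**.

During stereotactic lung treatment the tumor moves with breathing. Instead
of implanting fiducial markers or strapping on external surrogates, the
respiratory phase of every in-treatment kV projection can be recognized by
comparing it against template radiographs re-projected from the
phase-resolved cone-beam CT (4D-CBCT) that is acquired anyway at patient
setup. `priorphase` implements that pipeline end to end for researchers in
image-guided radiotherapy, together with the synthetic ground truth needed
to evaluate it without clinical data:

* a breathing **4D digital thorax phantom** (body, lungs, diaphragm dome,
  mobile tumor) with ground-truth phase labels,
* an exact **cone-beam forward projector** (Siddon-style voxel walk,
  compiled hot path): `P_i = P_o exp(-sum_j a_ij f_j)`,
* **FDK filtered backprojection**, including phase-sorted 4D
  reconstruction with Parker short-scan weighting,
* the **template bank** (10 phases x 1-degree gantry angles, tumor ROI) and
  **normalized cross-correlation** matching

      Cor = sum_mn (A_mn - A_av)(B_mn - B_av)
            / sqrt( sum_mn (A_mn - A_av)^2 * sum_mn (B_mn - B_av)^2 ),

* the match criteria: **two-phase** (cyclic phase distance <= 2; phases 10
  and 1 are both peak exhale) and **relative phase** (an out-of-order phase
  counts as a match if |CC_ref - CC_obt| <= 0.01),
* the **Amsterdam Shroud** diaphragm-surrogate baseline, and
* an evaluation driver + CLI that scores template matching against the
  shroud baseline on ground truth.

## Worked example

```python
import priorphase as pp

cfg = pp.ExperimentConfig(noise_photons=1e5, seed=1)   # 210-frame arc, Poisson noise
report, art = pp.run_experiment(cfg)
print(report.pipr_match_rate, report.as_match_rate, report.n_visible_frames)
```

prints

```
100.0 100.0 69
```

meaning: of the 69 frames in the tumor-visible angular window (-135 to
-67 degrees), 100% were phase-matched by template recognition and 100% by
the Amsterdam-Shroud baseline on this clean, regularly-breathing phantom.
The separation between the methods appears when conditions worsen — e.g.
at 1e4 photons the shroud's all-frame rate drops (94.3% at seed 1) while
template matching, which tracks the tumor itself rather than the diaphragm,
stays at 100%; a coarser detector degrades the shroud much further.

The `examples/` directory walks through each capability (phantom and
trace, DRR projection, FDK reconstruction, shroud extraction, end-to-end
recognition); each script prints the numbers it computes and what they
mean. The same pipeline is scriptable from the shell:

```bash
priorphase run-all --seed 1 --outdir out/            # full pipeline + report
priorphase simulate --outdir out/ && priorphase reconstruct --outdir out/
priorphase templates --outdir out/ && priorphase track --outdir out/
priorphase evaluate --outdir out/
```

Volumes are written as MetaImage (`.mha`), projection stacks and templates
as float32 TIFF with CSV/JSON sidecars, traces and match tables as CSV,
configuration as YAML or JSON.

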