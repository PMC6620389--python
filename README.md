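# wormneurite

Morphometry of aging *C. elegans* ALM/PLM touch receptor neurons from
traced neuron trees (SWC) and confocal stacks (multi-page TIFF).

Aging touch receptor neurons accumulate structural abnormalities: new
processes sprouting from the soma (soma outgrowths) or from the sensory
dendrite (neurite outgrowths), focal enlargements of the process
(beads/blebs), sharp bends (kinks) of the dendrite, and shrinking soma
volume.  `wormneurite` turns a traced tree into per-neuron numbers for all
of these, and provides the cohort-level statistics used to compare ages and
genotypes — including a spatial test of whether neurite outgrowths occur
preferentially at sharp bends.  It is written for labs that trace neurons
with APP2/Vaa3D (or any SWC-producing tracer) and want reproducible,
threshold-documented quantification instead of manual scoring.

## What it computes

- **Compartment classification.**  Each node of the tree gets one of seven
  labels (`mainbranch`, `soma`, `somaoutgrowth`, `neuriteoutgrowth`,
  `pvm`, `vnc_connection`, `blob_artifact`).  The main branch is the
  longest root-to-endpoint path by arclength; the ALM soma is the
  connected blob of nodes with radius above a threshold (default 2 µm);
  PLM side branches carrying a soma-sized node are recognized as the
  crossing PVM neuron, together with side branches attaching within ±4 µm.
- **Sharp bends.**  For each main-branch node, total-least-squares lines
  are fitted to the neighbors within 2 µm of arclength up- and downstream;
  the turning angle α between the outward directions is computed as
  atan2(‖u×v‖, u·v) (straight run → 180°).  Nodes with α < 155° are
  candidates, selected sharpest-first with 4 µm non-maximum suppression.
  Bend density = count / dendrite length; a 135°–165° threshold sweep is
  built in.
- **Beads/blebs.**  The local thickness (mean radius in an 8 µm window) is
  subtracted from the node radii; residual maxima more than 2 SD above the
  process are counted, with the same suppression.
- **Soma volume.**  Seeded confidence-connected region growing (region
  mean µ ± 2.5 σ band, 4 iterations, 26-connectivity) from the traced
  soma node, cleaned by morphological closing/opening; volume =
  voxel count × dx·dy·dz.
- **Bend–outgrowth association.**  Events are located by arclength from
  the distal tip.  Per neuron, the fraction of outgrowths within r = 1 µm
  of a bend is paired with the empty-space function F(r) of the bend
  pattern (the fraction of dendrite within r of a bend — exactly the
  expected fraction under independent placement), and a Wilcoxon
  signed-rank test is applied across neurons.  Two-sample
  Kolmogorov–Smirnov comparisons and bootstrap 95% CIs of means round out
  the group statistics.

A synthetic-data module generates neurons with planted bends, branches,
beads and somas (and renders them into noisy voxel stacks), so the entire
pipeline is testable end to end with known ground truth.  See
`docs/methods.md` for the algorithms, defaults and caveats.

## Worked example

Generate a synthetic PLM cohort in which 80% of outgrowths are planted
within 0.5 µm of a bend, then quantify it:

```bash
wormneurite simulate fixtures/ --n 6 --seed 4 --coupling 0.8
wormneurite quantify fixtures/ -o out/ --seed 4
```

`out/summary.csv` holds one row per neuron (excerpt):

```
    neuron_id  main_length_um  neurite_outgrowth_count  bend_count  bend_density_per_um
SIM_A_8_PLM00         300.080                        5          19                0.063
SIM_A_8_PLM01         300.208                        3          15                0.050
SIM_A_8_PLM02         300.452                        3          13                0.043
SIM_A_8_PLM03         300.665                        4          12                0.040
SIM_A_8_PLM04         300.597                        6          11                0.037
SIM_A_8_PLM05         299.922                        3          15                0.050
```

The detected bend counts are the planted Poisson draws (density
0.04 µm⁻¹ × 300 µm ≈ 12 per neuron), recovered with no false positives.
`out/stats.json` holds the cohort statistics for the group parsed from the
file names (`SIM_8`):

```json
"bend_density_per_um": {"mean": 0.0472, "ci95": [0.0410, 0.0544]},
"association": {
  "r_um": 1.0, "n_neurons": 6,
  "mean_observed_fraction": 0.744, "mean_expected_fraction": 0.094,
  "statistic": 21.0, "p_value": 0.0156
}
```

74% of outgrowths lie within 1 µm of a bend where 9% would be expected
under independent placement; with only 6 neurons the one-sided signed-rank
p-value is 0.0156 (its minimum possible value at n = 6, i.e. every neuron
shows the effect).  Every output row records the config hash and software
version; re-running with the same seed reproduces the files byte for byte.

CLI verbs: `quantify` (batch directories of SWC/TIFF), `simulate`
(synthetic fixtures with ground-truth sidecars), `associate` (spatial test
from an event-position CSV), `sweep` (bend-threshold sweep).  The same
functionality is available as a library (`wormneurite.process_cohort`,
`wormneurite.detect_bends`, ...).

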