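# osteokin

Marker-based skeletal kinematics and oral-cavity volumetry for
suction-feeding biomechanics: from 3D marker trajectories to rigid-body
poses, joint-coordinate-system (JCS) Euler rotations, dynamic endocast
volumes, per-bone relative contributions to volume change (RCVC), muscle
strain, prey kinematics, and strike-level summaries.  A synthetic
articulated-skull generator with exact ground truth validates the whole
chain end to end.

Units are cm / ms / degrees throughout.  The world frame is right-handed:
+x rostral, +y dorsal, +z toward the animal's right.

## Modules

| module | what it does |
| --- | --- |
| `osteokin.synthetic_rig` | forward-kinematics strike generator: articulated skull (neurocranium on a body plane, hinged lower jaw, bilateral ceratohyals with coupled depression + long-axis rotation, clavicles, cranial rib), raised-cosine motion channels, tongue/prey soft points, Gaussian marker noise, full `GroundTruth` |
| `osteokin.rigid_body` | points-CSV I/O, weighted least-squares rigid fits (proper rotations only), per-frame pose series with validity flags, zero-phase Butterworth filtering, sliding-window polynomial refinement, marker & JCS precision reports |
| `osteokin.jcs_kinematics` | six-DOF decomposition between paired anatomical coordinate systems (fixed zyx order, right-hand rule), zero-offsetting, bone-fixed virtual points, muscle strain (% of L_i), tongue inter-marker distances, prey displacement/velocity/acceleration |
| `osteokin.endocast` | alpha-shape volume of bone-attached locator clouds (alpha = circumradius threshold in cm; doubled unilateral volume), boundary-mesh OBJ export |
| `osteokin.rcvc` | rolling freeze-and-recompute relative contribution to volume change, bilateral freeze units, sum-of-absolute-values normalization |
| `osteokin.strike_summary` | gape series, strike event detection (onset / peak gape / jaw close / channel peaks), trial alignment and mean ± s.e.m. averaging, Table-style summaries, body-length OLS regression |

## CLI

```sh
osteokin simulate  --out sim/ --noise 0.029 --seed 1      # synthetic strike
osteokin animate   --points sim/points.csv --filter-hz 35 --out poses/
osteokin precision --points sim/points.csv
osteokin kinematics --poses poses/ --zero-at 50 --out kin/
osteokin volumes   --poses poses/ --out volumes.csv
osteokin rcvc      --poses poses/ --window-frames 20 --out rcvc.csv
osteokin summarize --poses poses/ --events-threshold 0.05 --out events.csv
```

Pass `default` (the default) for `--bodies` / `--jcs` / `--endocast` to use
the built-in synthetic rig's definitions, or a JSON file:

* bodies: `{"jaw": {"markers": [...], "reference": [[x,y,z], ...]}}`
* jcs: `{"jaw": {"proximal": ..., "distal": ..., "acs_proximal": [16 floats,
  row-major], "acs_distal": [...]}}`
* endocast: `{"alpha": 2.0, "bilateral_factor": 2.0,
  "locators": [["body", [x,y,z]], ...]}`

## File dialects

* **Points CSV** — header of `name_X,name_Y,name_Z` triples, one row per
  frame; blank/NaN cells mark untracked marker-frames.
* **Transforms CSV** — 16 columns per body, row-major, in the row-vector
  ("animation package") convention: `world_row = [local, 1] @ M`,
  translation in the fourth row.  `read_transforms_csv(..., row_vector=False)`
  reads column-vector tables.

## Conventions worth knowing

* Rotations decompose in fixed z-then-y-then-x order; near gimbal lock
  (|cos ry| < 1e-6) the frame is flagged, rx pinned to 0 by convention.
* The endocast `alpha` is a circumradius threshold in cm; `alpha = inf`
  reproduces the convex hull.  Disconnected alpha-complex components all
  count toward the volume unless `largest_component_only` is set.
* RCVC freezes each unit's pose relative to the neurocranium at the
  start-of-window value; windows roll by one frame, values are stamped at
  the window centre, and truncated end windows are dropped.
* Frames with fewer than 3 visible markers are flagged invalid, never
  interpolated.

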