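# fracsim

Coupled bone fracture-healing and long-term remodelling simulator on
idealized plated and unplated long-bone geometries.

A biphasic (poroelastic) finite-element core computes daily loading fields
(octahedral deviatoric strain, interstitial fluid velocity, stress, strain
energy density) on a labelled callus mesh. These drive:

* **MSC infiltration** — diffusion with a saturating boundary-concentration
  ramp on the periosteal/marrow/soft-tissue interfaces;
* **mechano-regulated healing** — a biophysical stimulus
  `S = eps_dev/a + v/b` selects fuzzy tissue memberships (fibrous,
  cartilage, immature bone, woven/mature bone, resorption) that feed cell
  differentiation and tissue-production ODEs, rule-of-mixtures stiffness and
  a trailing 10-day modulus average;
* **bone remodelling** — after bony union bridges the callus focus, a
  site-specific strain-energy-density rule with a lazy zone, a cubic
  density-modulus law, surface-area-density-scaled rates, and Miner's-rule
  fatigue damage with damage-driven resorption;
* **a global adaptive time step** — the minimum of the healing, SED and
  damage controls.

Geometries are 2D (axisymmetric for unplated/calibration, plane-strain
cross-section with a bonded titanium plate strip for plated) and built
programmatically; no external data is required.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes closed-form oracles (Terzaghi consolidation, diffusion
series, boundary-ramp exponential), hypothesis property tests
(conservation, boundedness, fuzzy-membership partition of unity, density
bounds) and an acceptance suite (`tests/test_acceptance.py`) with
qualitative full-year scenario runs on coarse meshes.

## CLI

```bash
fracsim run --condition LC_A --gap 3 --unplated --out out/
fracsim run --condition LC_H --plated --damage --out out_plated/
fracsim sweep --conditions LC_A,LC_C,LC_E --gaps 3,8 --out sweep/
fracsim fixtures calibration_osteotomy --out fixtures/
```

`run` writes `series.csv` (per-increment time series of mean callus-focus
modulus, union/transition flags), `dt_log.csv`, `manifest.json` (resolved
parameter echo + config hash) and `final_state.vtk` (legacy-VTK snapshot of
all per-element state). Configurations are YAML trees mirroring
`SimulationConfig`; every unset key falls back to the built-in defaults
(see `fracsim/healing.py`, `fracsim/remodelling.py` for the annotated
parameter sets).

## Layout

| module | role |
| --- | --- |
| `fracsim.geometry` | labelled structured quad meshes, region/adjacency queries, spanning-path test |
| `fracsim.materials` | poroelastic material table (tissues + titanium) |
| `fracsim.poroelastic` | u-p consolidation FE solver for one daily loading event |
| `fracsim.diffusion` | MSC diffusion + boundary ramp |
| `fracsim.healing` | stimulus, fuzzy membership, cell/tissue ODEs, mixture modulus, smoothing |
| `fracsim.remodelling` | SED references, cubic law, surface-area density, fatigue damage |
| `fracsim.driver` | load schedules, coupled increment loop, union/transition, adaptive dt |
| `fracsim.config` / `fracsim.cli` / `fracsim.vtkio` | config parsing, outputs, CLI |
| `fracsim.fixtures` | calibration osteotomy, single-element rig, consolidation column, toy callus |
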