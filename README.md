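# stentsim

Rapid virtual deployment of balloon-expandable coronary stents on 2-simplex
surface meshes.

A triangulated vessel lumen is converted to its polygonal dual (a 2-simplex
mesh, in which every interior vertex has exactly three neighbours), a
crimped stent mesh is generated by projecting the artery mesh inward along
the centerline, and the stent is expanded by damped explicit vertex
dynamics.  The outward expansion force is derived from the device's beam
rigidity, nominal balloon pressure and target diameter; after stent-wall
contact, an inward resistance force based on a sixth-order
reduced-polynomial hyperelastic wall model opposes further expansion.
Lumen outcomes are quantified as frame-wise mean lumen diameter (MLD)
profiles with Bland-Altman and max|e| / RMSE / MARE agreement statistics.

All geometry is in millimetres; the mechanical unit system is mm-N-MPa
(balloon pressures entered in atm are converted with 1 atm = 0.101325 MPa).

## Layout

| module | contents |
| --- | --- |
| `stentsim.simplex` | triangulations, dual 2-simplex construction, normals, circumscribed elements, simplex angle |
| `stentsim.stent` | device spec (radial rigidity, radial force, inflection scale) and the expansion force; crimped-stent mesh generation |
| `stentsim.artery` | hyperelastic wall stress, contact detection, wall-resistance force |
| `stentsim.dynamics` | centered-difference vertex dynamics, convergence detection, force histories |
| `stentsim.metrics` | MLD profiles by plane slicing, cross-section diameters, Bland-Altman, error statistics |
| `stentsim.fixtures` | synthetic straight / stenotic / curved tubes with analytic ground truth |
| `stentsim.io`, `stentsim.config`, `stentsim.cli`, `stentsim.pipeline` | STL/PLY/OBJ + CSV I/O, YAML config, CLI, end-to-end workflow |

## CLI

Generate a synthetic stenotic vessel, deploy a stent in it, and compare
profiles:

```sh
stentsim synth --kind stenotic --length 40 --diameter 3 --severity 0.4 --out fixture/
stentsim simulate --artery fixture/surface.stl --centerline fixture/centerline.csv \
    --stent-diameter 2.9 --out run/
stentsim metrics --test run/mld_post.csv --reference run/mld_pre.csv
stentsim convert --surface fixture/surface.stl --out fixture/simplex.ply
```

`simulate` writes `history.csv` (per-step internal/external force totals and
contact counts), `mld_pre.csv` / `mld_post.csv`, deployed meshes (STL +
polygonal PLY with a JSON adjacency sidecar) and `report.json` (derived
device quantities, convergence, phase timings).  Exit codes: 0 converged,
2 configuration error, 3 not converged.

Device and material parameters come from a YAML config (see
`stentsim.config.DEFAULT_CONFIG` for keys and defaults: stent geometry and
modulus, balloon pressure, wall coefficients C10..C60, dynamics weights).

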