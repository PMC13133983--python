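# mtseam

Seam-aware metadata processing for microtubule cryo-EM reconstruction.

Microtubules are pseudo-helical polymers: N protofilaments (typically
11–16) of αβ-tubulin dimers wind around a hollow cylinder with S helical
starts, but one lattice contact — the **seam** — breaks the helical
symmetry, and in undecorated microtubules the α/β **register** of each
particle is ambiguous by one 41 Å tubulin monomer. General single-particle
engines handle the refinements; everything lattice-specific in between
lives here:

- **Lattice geometry** (`mtseam.lattice`) — architectures `N-S`, the
  theoretical helical parameters rise = S·a/N and twist = −360/N for a
  monomer repeat a = 41 Å (for 14-3: rise 8.79 Å, twist −25.7°), ZYZ
  Euler conventions, and the helical operator.
- **Filament trace repair** (`mtseam.trace`) — splits mistraced filaments
  at in-plane-angle jumps, re-fits centerlines (linear with quadratic
  fallback), reassigns picks to the nearest centerline, merges collinear
  fragments, and extrapolates picks into tracing gaps at the 82 Å segment
  spacing.
- **Synthetic references** (`mtseam.references`) — helically replicates a
  single-protofilament density into one reference volume per candidate
  architecture (radius scaled by N), for supervised classification.
- **Class smoothing** (`mtseam.classes`) — modal smoothing of per-particle
  3D-class labels along each filament and regrouping of extended
  off-class stretches into their own filaments.
- **Angle unification** (`mtseam.angles`) — per-filament quadratic ψ
  tracks through modal inliers, and φ snapping onto the N-line
  protofilament family with supertwist slope fitting.
- **Symmetry expansion & register** (`mtseam.expand`) — N-fold
  pseudo-helical expansion, the 41 Å monomer register shift (and its
  volume-space counterpart in `mtseam.references`), and un-expansion that
  retains only the seam-position copy.
- **Seam finding** (`mtseam.seam`) — per-layer register changepoint
  scores averaged into a per-microtubule consensus seam position.
- **Synthetic data** (`mtseam.simulate`) — planted-truth generators for
  picks, angle tracks, register layers and toy densities; they power the
  test suite and the end-to-end pipeline.

Tables are RELION-style STAR files, volumes MRC maps (both via gemmi).

## Worked example

Theoretical helical parameters for a 13-protofilament, 3-start lattice:

```sh
$ mtseam calc-helix 13 3
{"architecture": "13-3", "rise_A": 9.461538461538462, "twist_deg": -27.692307692307693, "rise_A_display": 9.46, "twist_deg_display": -27.7}
```

Full synthetic end-to-end run (simulated picks with 15% dropout and 10%
identity swaps → trace repair → class smoothing → ψ/φ unification →
14-fold expansion → register merge → seam finding → un-expansion), with
per-stage STAR tables, JSON summaries and planted-truth sidecars written
to the run directory:

```sh
$ mtseam run --out-dir run1 --seed 1
{"stages": ["simulate", "trace_extend", "smooth_classes", "unify_psi", "unify_phi", "expand", "register_merge", "seam_find", "unexpand"], "records": {"simulate": 267, "trace_extend": 322, "smooth_classes": 322, "unify_psi": 322, "unify_phi": 322, "expand": 4508, "register_merge": 4508, "seam_find": null, "unexpand": 322}, "seam_recovery": 1.0}
```

`seam_recovery: 1.0` means the consensus seam matched the planted seam
for every simulated microtubule. The same stages are exposed as
individual subcommands (`trace-extend`, `make-refs`, `smooth-classes`,
`unify-psi`, `unify-phi`, `expand`, `register-merge`, `seam-find`,
`unexpand`, `simulate`); `mtseam --help` lists them. Exit codes: 0 ok,
2 validation error, 3 missing input.

Library use mirrors the CLI:

```python
from mtseam import HelicalArchitecture, derive_symmetry, symmetry_expand

sym = derive_symmetry(HelicalArchitecture(14, 3, 41.0))
expanded = symmetry_expand(table, sym, n_pf=14)   # 14 copies per particle
```

## Reproduction

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite (≈45 s on one CPU) includes `tests/test_acceptance.py`
with one test per acceptance criterion: the 14-3 helical parameters, one
reference volume per candidate architecture, the planted-truth property
suites (trace recovery, class smoothing accuracy, angle unification,
expansion/register round-trips, seam recovery, replication geometry,
STAR/MRC round-trips) and the deterministic end-to-end pipeline run.
`scripts/acceptance.py` recomputes the headline helical parameters at
runtime and writes them as JSON.

Design and numerical choices are documented in `docs/methods.md`.
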