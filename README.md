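# excitedstate

Inference of protein excited-state conformational ensembles from
small-angle X-ray scattering (SAXS), Markov-state-model (MSM) kinetics,
and accessible-volume (AV) FRET prediction.

The package implements a hybrid simulation/experiment pipeline:

1. **SAXS forward model** — Debye-equation scattering prediction with
   tabulated atomic form factors (implicit hydrogens folded in), Guinier
   Rg extraction, and χ² against experiment with closed-form scale/offset
   fitting (`excitedstate.saxs_forward`).
2. **Maximum-entropy ensemble reweighting** — minimize
   G(w) = χ² + θ·Σ w ln(w/w⁰) over the weight simplex by simulated
   annealing, with a θ-selection scan, run-to-run stability check, and
   state-ablation re-refinement (`excitedstate.eros_refine`).
3. **MSM kinetics** — tICA, k-centers clustering, transition-matrix
   estimation, population propagation, and combination of two slowly
   interconverting isomeric regimes through an experimental rate constant
   with an RMSD-based state-pairing rule (`excitedstate.msm_kinetics`).
4. **Structure utilities** — PDB I/O, in-silico point mutation by
   side-chain truncation, Rg, Kabsch RMSD, contact maps
   (`excitedstate.core_structures`).
5. **AV-FRET** — grid/Dijkstra accessible-volume dye clouds and
   shot-noise-limited single-molecule efficiency histograms
   (`excitedstate.fret_av`).
6. **Ensemble analysis** — weighted contact densities, difference maps,
   and feature-based state classification (`excitedstate.ensemble_analysis`).
7. **Synthetic data** — deterministic toy ensembles, noisy synthetic
   experiments, and two-regime kinetic models with known ground truth, so
   the whole pipeline is testable offline (`excitedstate.synthetic_data`).

## Tests

```sh
python -m pytest -q tests/
```

The acceptance tests for the native-structure observables (criterion 1)
require the public reference structure as a plain-text PDB file at
`data/3CHY.pdb` (RCSB entry 3CHY). If the file is absent those three
tests fail with an explanatory message; everything else runs on
synthetic data generated at test time. To supply it:

```sh
curl -o data/3CHY.pdb https://files.rcsb.org/download/3CHY.pdb
```

## CLI

```sh
excited-state run --config cfg.toml          # full 3-step inference
excited-state refine --profiles DIR --exp FILE --theta 6 --seed 1 --out r.json
excited-state propagate --matrix T.txt --pop p0.txt --duration 5e-3 --out p.txt
excited-state contacts --pdbs DIR --weights w.txt --out density.txt
excited-state fret --pdb file.pdb --donor 7 --acceptor 63 --r0 42 --out hist.tsv
excited-state make-fixtures --seed 1 --out fixtures/
```

The pipeline config is a TOML file with keys matching
`excitedstate.pipeline.PipelineConfig` (paths to per-state profiles, the
two experimental profiles and the transition matrix; `theta_unfolded`,
`theta_excited`, `duration`, `seed`, `out_dir`). Exit codes: 0 success,
2 configuration error, 3 numerical failure.

## File formats

SAXS profiles are 3-column whitespace text (q [Å⁻¹], I, σ) with `#`
comments; transition matrices are dense text with an `n=... lag=...`
header line; contact/density maps are whitespace matrices with a one-line
header; discrete trajectories are one integer state per line.
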