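# File formats

## Curve CSV
Header `time_s,intensity_norm` (normalized) or `time_s,intensity[,background]`
(raw detector units). One row per scan; the time axis is stored explicitly in
seconds (scan-end timestamps, including the bleach-pulse gap) rather than
being inferred from the scan index.

## Sidecar JSON
Every artifact written by the CLI gets `<name>.<ext>.json` holding the
resolved configuration (geometry, protocol, bleach, grid, noise sections),
the seed, and run metadata — enough to regenerate the artifact exactly.

## Synthetic experiment directory
`cell000.csv … cellNNN.csv` raw traces plus `manifest.json` with the
construct label, ground-truth mobility parameters, noise model, root seed
and the derived per-cell seeds.

## Library cache (HDF5)
Datasets `curves` (nodes × scans), `time`, `node_params` (nodes × 5:
D, f1, T1, f2, T2); attributes `meta_json` (build configuration) and
`n_done` (for resumable builds). A `.csv` suffix selects a plain-text
fallback: a wide CSV plus a `.json` sidecar with nodes and metadata.

## Fit report JSON
`best` (parameter dict), `sse`, `fit_window` ([start, stop) scan indices),
`summary` (free/short/long percentages, residence times, identifiability
flags), `ranked` (top-k nodes with sse), `library_meta`.

## Configuration TOML
Optional tables `[geometry] [protocol] [bleach] [params] [grid] [noise]`;
keys mirror the dataclass fields and unknown keys are rejected.
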