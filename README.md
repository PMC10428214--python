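# trajnet

Dynamical interaction analysis of molecular trajectories: hydrogen-bond
occupancy fingerprints, residue-network community decomposition with RGB
co-membership projection, motion statistics (RMSD / RMSF / cross-correlation
maps), and binding/alchemical free-energy estimation — together with
synthetic ground-truth generators so the whole pipeline is testable without
external data.

## What is in the box

| module | contents |
| --- | --- |
| `trajnet.structures_io` | PDB / multi-model PDB reading and writing, atom selection (including the CB / CA-for-glycine network-node rule) |
| `trajnet.synthetic` | bead polymers with planted community structure, two-state Markov hydrogen-bond triplets, mode-driven correlated displacements, Crooks-consistent Gaussian work samples |
| `trajnet.hbonds` | geometric hydrogen-bond detection (3.2 Å / 20° defaults), whole-trajectory and per-chunk occupancies, residue contact barcodes, occupancy-difference fingerprints with 20-point / 3σ / 2σ-stability selection |
| `trajnet.network` | residue contact networks (6.7 Å default cutoff, ligand node), shortest-path edge betweenness, divisive community detection to a target community count Ω |
| `trajnet.rgb` | co-membership accumulation against three reference nodes, normalised to a 0–256 scale, exported as a color table plus a viewer coloring script |
| `trajnet.motion` | Kabsch superposition, RMSD series, (block-averaged) RMSF, dynamic cross-correlation matrices |
| `trajnet.free_energy` | Ki → ΔG conversion (1 M standard state), double thermodynamic cycle ΔΔG with closure, Zwanzig / BAR / MBAR estimators, window stitching |
| `trajnet.cli` | the `trajnet` command-line tool and an end-to-end demo |

## CLI

```bash
trajnet simulate --kind community --seed 1 --n-frames 10 --out traj.pdb --truth-out truth.tsv
trajnet hbonds traj.pdb --distance 3.2 --angle 20 --chunks 5
trajnet fingerprint ref.pdb alt.pdb --min-diff 20
trajnet network traj.pdb --cutoff 6.7
trajnet communities traj.pdb --omega 6
trajnet rgb traj.pdb --red I94 --green S64 --blue N142
trajnet rmsd traj.pdb ; trajnet rmsf traj.pdb ; trajnet dccm traj.pdb
trajnet fep samples.tsv --method bar
trajnet cycle            # bundled Ki table + alchemical edges
trajnet demo --seed 1 --out demo_output
```

Most analysis subcommands accept `--config pipeline.yaml`, a YAML file with
one section per stage (`hbonds:`, `network:`, `communities:`, `rgb:`,
`fingerprint:`); explicit flags override config values, which override the
built-in defaults. `trajnet demo` runs every stage on generated data and
writes all TSV outputs plus a provenance log; the same seed reproduces the
outputs bit for bit.

## Notes

- Trajectories are exchanged as multi-model PDB; binary formats are out of
  scope.
- All generators are deterministic given their seed.
- Temperatures default to 300 K; the gas constant is
  1.98720425×10⁻³ kcal mol⁻¹ K⁻¹.
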