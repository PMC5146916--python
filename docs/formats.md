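# File formats

All outputs are plain text, all quantities in reduced LJ units unless noted.

## XYZ structures and trajectories

Standard XYZ: bead count, comment line, then `LABEL x y z` per bead with
labels P/S/B (polymer) and C (membrane).  Trajectory frames append the same
block with `step=<int> time=<LJ time>` on the comment line.

## Topology table (`*_topology.tsv`)

Tab-separated, one row per bead:

    index  kind  group  bonded  anchor

`bonded` is a comma-separated list of bonded partner indices (`-` if none);
`anchor` is `x,y,0` for tethered membrane beads, `-` otherwise.

## Ensemble table (`*_ensemble.tsv`)

One row per trajectory:

| column      | meaning                                             |
|-------------|-----------------------------------------------------|
| `seed`      | trajectory index (seed derived from master seed)    |
| `status`    | `translocated`, `failed_slide` or `timeout`         |
| `tau_steps` | translocation time in steps (-1 if not translocated)|
| `tau_lj`    | translocation time in LJ time units (NaN if absent) |

## Waiting-time table (`*_waiting.tsv`)

Column `bead` (0..N-1) plus one column `traj_<seed>` per successful
trajectory holding the time that bead spent inside the pore slab
|z| < sigma_B, in LJ time units.

## Scaling table (input to `poretrans analyze`)

Tab-separated with columns `f`, `tau` and optionally `tau_err`; the analyze
command fits tau ~ f^-gamma by weighted least squares.

## Configs and manifests (YAML)

`RunConfig.dump` writes the full protocol block plus a units stanza; the
run manifest embeds the same resolved configuration, the code version and,
for `build`, the lattice metadata (bond length, origin convention, box,
carve counts), so a run is re-executable from its manifest alone.
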