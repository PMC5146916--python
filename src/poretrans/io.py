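"""Plain-text structure, trajectory and table output.

Formats are documented in docs/formats.md: XYZ for structures and
trajectories (labels P/S/B/C, coordinates in LJ units), TSV for ensemble and
analysis tables, YAML for configs and run manifests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import KIND_LABELS, MembraneLattice, Topology


def write_xyz(path, positions, kinds, comment: str = "", append: bool = False):
    """One XYZ frame: count, comment, then `label x y z` per bead."""
    pos = np.asarray(positions)
    labels = [KIND_LABELS[k] for k in kinds]
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{len(pos)}\n{comment}\n")
        for lab, (x, y, z) in zip(labels, pos):
            fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path):
    """Read back a single-frame XYZ file -> (labels, positions)."""
    lines = Path(path).read_text().splitlines()
    count = int(lines[0])
    labels, rows = [], []
    for line in lines[2:2 + count]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:4]])
    return labels, np.array(rows)


class TrajectoryWriter:
    """Appends XYZ frames with the step index and LJ time on the comment line.

    Intended as an observer for :meth:`Simulation.run`; off by default for
    ensembles.
    """

    def __init__(self, path, stride: int = 1000):
        self.path = Path(path)
        self.stride = stride
        self.path.write_text("")

    def __call__(self, sim) -> None:
        write_xyz(self.path, sim.state.pos, sim.system.kinds,
                  comment=f"step={sim.state.step} time={sim.state.time:.6f}",
                  append=True)


def write_topology_table(path, topology: Topology,
                         membrane: MembraneLattice | None = None) -> None:
    """Plain-text topology table: index, kind, group, bonded partners, anchor."""
    partners = {}
    for i, j in topology.bonds:
        partners.setdefault(int(i), []).append(int(j))
        partners.setdefault(int(j), []).append(int(i))
    rows = []
    for i in range(topology.n_total):
        kind = KIND_LABELS[topology.kinds[i]]
        group = "polymer" if topology.groups[i] == 0 else "membrane"
        bonded = ",".join(str(p) for p in sorted(partners.get(i, []))) or "-"
        if group == "membrane" and membrane is not None \
                and not topology.immobile_membrane:
            ax, ay = membrane.xy[i - topology.n_polymer]
            anchor = f"{ax:.6f},{ay:.6f},0"
        else:
            anchor = "-"
        rows.append(f"{i}\t{kind}\t{group}\t{bonded}\t{anchor}")
    header = "# index\tkind\tgroup\tbonded\tanchor"
    Path(path).write_text("\n".join([header, *rows]) + "\n")


def write_ensemble_tsv(path, ensemble) -> None:
    """One row per trajectory: seed, status, tau_steps, tau_lj."""
    ensemble.to_frame().to_csv(path, sep="\t", index=False)


def read_ensemble_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_waiting_times_tsv(path, ensemble) -> None:
    """Per-bead pore waiting times, one column per successful trajectory."""
    cols = {f"traj_{r.seed}": r.waiting_times for r in ensemble.records
            if r.status == "translocated" and r.waiting_times is not None}
    df = pd.DataFrame(cols)
    df.insert(0, "bead", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def write_reff_tsv(path, record, stride: int, dt: float) -> None:
    """Effective-pore-radius time series of one kinetic-membrane trajectory."""
    if record.reff is None:
        raise ValueError("record carries no effective-pore-radius series")
    t = (np.arange(1, len(record.reff) + 1)) * stride * dt
    pd.DataFrame({"time_lj": t, "R_eff": record.reff}).to_csv(
        path, sep="\t", index=False)


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))
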