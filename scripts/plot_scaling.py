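#!/usr/bin/env python
"""Plot a tau(f) scaling table (TSV with columns f, tau[, tau_err]) on
log-log axes with the fitted power law, in the layout of the force-sweep
figures.

Usage:  python scripts/plot_scaling.py table.tsv [-o out.png] [--window LO HI]
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from poretrans.analysis import fit_power_law  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("table")
    ap.add_argument("-o", "--out", default=None)
    ap.add_argument("--window", type=float, nargs=2, default=None)
    args = ap.parse_args()

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(args.table, sep="\t")
    err = df["tau_err"] if "tau_err" in df else None
    fit = fit_power_law(df["f"], df["tau"], err,
                        window=tuple(args.window) if args.window else None)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.errorbar(df["f"], df["tau"], yerr=err, fmt="o", ms=5, capsize=3,
                label="simulation")
    grid = np.geomspace(df["f"].min(), df["f"].max(), 50)
    ax.plot(grid, fit.amplitude * grid**(-fit.exponent), "--",
            label=rf"$\tau \propto f^{{-{fit.exponent:.2f}}}$")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"pulling force $f$")
    ax.set_ylabel(r"$\tau$  [LJ time]")
    ax.legend(frameon=False)
    fig.tight_layout()
    out = args.out or Path(args.table).with_suffix(".png")
    fig.savefig(out, dpi=150)
    print(f"wrote {out}  (gamma = {fit.exponent:.3f} +/- {fit.stderr:.3f})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
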