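#!/usr/bin/env python
"""Extract the 112-feature design matrices (body and world frame).

One 7-s window per labeled event, 14 features x 8 channels per window.
Matrices go to scratch/ (415 rows x 116 columns each); the console prints
the shapes and the class balance.
"""

from pathlib import Path

import pandas as pd

from cowmotion.features import build_design_matrix
from cowmotion.io_dataset import load_database

DB_ROOT = Path("scratch/synthetic_db")
OUT = Path("scratch")


def main():
    db = load_database(DB_ROOT)
    if not db:
        raise SystemExit(f"no database under {DB_ROOT}; run 01_simulate_database.py")
    for frame in ("body", "world"):
        X, y, meta = build_design_matrix(db, frame=frame, mode="first")
        table = pd.concat([meta, X], axis=1)
        table.insert(0, "label", y)
        out = OUT / f"features_{frame}.csv"
        table.to_csv(out, index=False)
        print(f"{frame}: {X.shape[0]} windows x {X.shape[1]} features "
              f"({int(y.sum())} mounts) -> {out}")


if __name__ == "__main__":
    main()
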