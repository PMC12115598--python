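#!/usr/bin/env python
"""Statistical comparison of the body- and world-frame F1 distributions.

Reads the 100-iteration CV metric tables written by 03_train_evaluate.py,
runs the assumption checks (Shapiro-Wilk, Levene) and the location test
(t-test or Mann-Whitney with rank-biserial effect size), and writes the
comparison JSON to results/.
"""

import json
from pathlib import Path

import pandas as pd

from cowmotion.stats_compare import compare_frames, comparison_to_dict, describe

RESULTS = Path("results")


def main():
    try:
        body = pd.read_csv(RESULTS / "cv_metrics_body.csv")["f1"].to_numpy()
        world = pd.read_csv(RESULTS / "cv_metrics_world.csv")["f1"].to_numpy()
    except FileNotFoundError:
        raise SystemExit("CV metrics missing; run 03_train_evaluate.py first")

    for name, g in (("body", body), ("world", world)):
        mean, median, std = describe(g)
        print(f"{name}: mean {mean:.3f}, median {median:.3f}, std {std:.3f} "
              f"(n={len(g)})")

    cmp = compare_frames(body, world)
    print(f"decision path: {'; '.join(cmp.decision_log)}")
    print(f"{cmp.test_name}: statistic {cmp.statistic:.4g}, p {cmp.p_value:.4g}")
    if cmp.rank_biserial is not None:
        print(f"rank-biserial effect size: {cmp.rank_biserial:.3f}")

    out = RESULTS / "frame_comparison.json"
    out.write_text(json.dumps(comparison_to_dict(cmp), indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
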