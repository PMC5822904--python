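#!/usr/bin/env python
"""RNA-seq cross-validation and expression-group classification.

Takes the tier-2 screen survivors from step 02, applies the RNA-seq support
filter (a gene must be significantly more abundant in an inflorescence
stage, the stamen, or the pistil than in every vegetative tissue), and
classifies the supported genes into the six expression subgroups. Also
writes the stamen-focal RES table for the supported genes. Outputs under
results/groups/.
"""

import argparse
from pathlib import Path

import pandas as pd

from estdigex.est_model_io import Tissue, read_expression_table, write_records
from estdigex.group_classifier import assignment_frame, classify_all
from estdigex.pipeline import rnaseq_support_filter
from estdigex.rnaseq_profiles import res


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--screen-dir", type=Path, default=Path("results/screen"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/groups"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    screen = pd.read_csv(args.screen_dir / "screen_tier2.tsv", sep="\t")
    survivors = screen.gene_id[screen.passes].tolist()
    profiles = read_expression_table(args.in_dir / "expression.tsv")

    retained, disregarded = rnaseq_support_filter(survivors, profiles)
    support = pd.DataFrame(
        [
            {"gene_id": c.gene_id, "retained": c.retained, "reasons": ";".join(c.reasons)}
            for c in retained + disregarded
        ]
    )
    write_records(args.out_dir / "rnaseq_support.tsv", support)

    by_id = {p.gene_id: p for p in profiles}
    supported = [by_id[c.gene_id] for c in retained if c.gene_id in by_id]
    assignments, counts = classify_all(supported)
    write_records(
        args.out_dir / "groups.tsv", assignment_frame(assignments, supported), counts
    )

    res_rows = []
    for p in supported:
        r = res(p, Tissue.STAMEN, set(Tissue) - {Tissue.STAMEN})
        res_rows.append({"gene_id": p.gene_id, "res_stamen": r.res, "defined": r.defined})
    write_records(args.out_dir / "res_stamen.tsv", pd.DataFrame(res_rows))

    print(
        f"support filter: {len(retained)} retained, {len(disregarded)} disregarded; "
        f"group counts: {counts}"
    )


if __name__ == "__main__":
    main()
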