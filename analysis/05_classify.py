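#!/usr/bin/env python
"""Leave-one-out nearest-centroid classification with each signature.

Evaluates every discovered signature on the discovery and validation
cohorts (LOO within each set, gastric positive).  Writes per-sample
predictions and a metrics table.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from methylmss import loo_predict, precision_recall
from methylmss.io import read_annotation, read_cohort, read_signatures
from methylmss.preprocess import normalize_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ann = read_annotation(args.out / "data" / "annotation.tsv")
    signatures = read_signatures(args.out / "signatures.json")
    metrics = {}
    for name in ("discovery", "validation"):
        cohort = read_cohort(args.out / "data" / name)
        norm = normalize_cohort(cohort, ann)
        for term, sig in signatures.items():
            pred = loo_predict(norm, cohort.class_label, sig)
            pm = precision_recall(pred["predicted"], pred["truth"])
            pred.to_csv(args.out / f"predictions_{name}_{term.replace(':', '')}.tsv", sep="\t")
            metrics[f"{name}/{term}"] = {
                "tp": pm.tp, "fp": pm.fp, "fn": pm.fn, "tn": pm.tn,
                "precision": pm.precision, "recall": pm.recall, "n": pm.n,
            }
            print(f"{name:10s} {term}: precision {pm.precision:6.1%}  recall {pm.recall:6.1%}  (n={pm.n})")
    (args.out / "classification_metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")


if __name__ == "__main__":
    main()
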