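#!/usr/bin/env python
"""Normalize both cohorts: 27k filter, M values, per-cohort z-scoring.

Reads the cohorts written by 01_simulate.py and writes z-scored M-value
matrices under <out>/normalized/.
"""

import argparse
from pathlib import Path

from methylmss import normalize_cohort
from methylmss.io import read_annotation, read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ann = read_annotation(args.out / "data" / "annotation.tsv")
    norm_dir = args.out / "normalized"
    norm_dir.mkdir(parents=True, exist_ok=True)
    for name in ("discovery", "validation"):
        cohort = read_cohort(args.out / "data" / name)
        norm = normalize_cohort(cohort, ann)
        norm.values.to_csv(norm_dir / f"{name}.tsv", sep="\t")
        print(f"{name}: {cohort.beta.shape[0]} probes -> {norm.values.shape[0]} after 27k filter; "
              f"steps: {' -> '.join(norm.provenance)}")
    print(f"wrote {norm_dir}/")


if __name__ == "__main__":
    main()
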