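#!/usr/bin/env python
"""Simulate the discovery and validation methylation cohorts.

Writes beta matrices, sample labels, probe annotation, the GO map and the
planted-probe truth list under <out>/data/.  The two cohorts share the
probe universe and truth; the validation cohort has independent samples,
noise and batch offsets.
"""

import argparse
from pathlib import Path

import yaml

from methylmss import CohortSpec, generate_cohort
from methylmss.io import write_annotation, write_cohort, write_go_map
from methylmss.synthetic_cohort import DEFAULT_GO_TERMS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--spec", type=Path, default=None, help="YAML file overriding CohortSpec fields")
    args = ap.parse_args()

    overrides = yaml.safe_load(args.spec.read_text()) if args.spec else {}
    if "signal_terms" in overrides:
        overrides["signal_terms"] = tuple(overrides["signal_terms"])
    spec = CohortSpec(**{"seed": args.seed, **overrides})
    discovery, ann, truth = generate_cohort(spec)
    validation, _, _ = generate_cohort(spec, cohort_seed=args.seed + 10_000)

    data = args.out / "data"
    write_cohort(discovery, data / "discovery")
    write_cohort(validation, data / "validation")
    write_annotation(ann, data / "annotation.tsv")
    write_go_map(ann, data / "go_map.tsv", labels=DEFAULT_GO_TERMS)
    (data / "planted_probes.txt").write_text("\n".join(sorted(truth)) + "\n")

    n_gc = (discovery.class_label == "GC").sum()
    n_ec = (discovery.class_label == "EC").sum()
    print(f"discovery: {discovery.beta.shape[0]} probes x {discovery.beta.shape[1]} samples "
          f"(EC={n_ec}, GC={n_gc}, {discovery.cohort_id.nunique()} cohorts)")
    print(f"validation: {validation.beta.shape[1]} samples, same probe universe")
    print(f"planted probes with true class effect: {len(truth)} "
          f"(effect size {spec.effect_size} on the beta scale)")
    print(f"wrote {data}/")


if __name__ == "__main__":
    main()
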