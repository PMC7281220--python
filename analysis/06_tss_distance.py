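#!/usr/bin/env python
"""Probe-to-TSS distances for every discovered signature.

Reports each signature probe's distance to its TSS midpoint and the
per-signature mean distance in base pairs.
"""

import argparse
from pathlib import Path

from methylmss import signature_mean_tss_distance, tss_distance_report
from methylmss.io import read_annotation, read_signatures


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ann = read_annotation(args.out / "data" / "annotation.tsv")
    signatures = read_signatures(args.out / "signatures.json")
    for term, sig in signatures.items():
        report = tss_distance_report(ann, sig.probe_ids)
        report.to_csv(args.out / f"tss_distances_{term.replace(':', '')}.tsv", sep="\t")
        mean_d = signature_mean_tss_distance(sig, ann)
        print(f"{term}: mean probe-to-TSS distance {mean_d:.1f} bp "
              f"(range {report['distance'].min()}-{report['distance'].max()} bp)")


if __name__ == "__main__":
    main()
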