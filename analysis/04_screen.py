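#!/usr/bin/env python
"""Run the MSS screen on the discovery cohort and extract signatures.

Desk-scale parameters: 200 RPS candidates reduced to the 50 most
dissimilar, 100 RGSs per GO term, top 50 gilded, 30-probe signatures.
Writes signatures JSON and the per-RGS enrichment scoreboard.
"""

import argparse
from pathlib import Path

from methylmss import ScreenConfig, discover_signatures
from methylmss.io import read_annotation, read_cohort, write_signatures
from methylmss.mss_screen import SCALED_OVERRIDES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.out / "data" / "discovery")
    ann = read_annotation(args.out / "data" / "annotation.tsv")
    truth = set((args.out / "data" / "planted_probes.txt").read_text().split())

    cfg = ScreenConfig().scaled(**SCALED_OVERRIDES)
    res = discover_signatures(cohort, ann, cfg, seed=args.seed)
    write_signatures(res.signatures, args.out / "signatures.json")
    res.scoreboard.to_csv(args.out / "scoreboard.tsv", sep="\t", index=False)

    print(f"pool {len(res.pool)} probes; {len(res.subpools)} GO subpools >= {cfg.min_subpool} members; "
          f"{len(res.rps_list)} RPSs retained; {res.n_fisher_tests} Fisher tests")
    for term, sig in res.signatures.items():
        planted = len(set(sig.probe_ids) & truth)
        print(f"  {term}: 30-probe signature, {planted}/30 planted")


if __name__ == "__main__":
    main()
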