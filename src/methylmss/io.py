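"""Plain-text serialization of the pipeline's objects.

Everything is TSV or JSON: beta matrices as probes x samples TSV with a
header row of sample ids, sample labels as a 4-column TSV, annotations
as TSV with GO terms comma-joined, GO maps as one probe/term pair per
row, and signatures as JSON keyed by GO term.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .mss_screen import Signature
from .synthetic_cohort import MethylationCohort, ProbeAnnotation


def write_cohort(cohort: MethylationCohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.beta.to_csv(out / "beta.tsv", sep="\t")
    labels = cohort.samples.reset_index()
    labels.columns = ["sample_id", "class", "subtype", "cohort"]
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)


def read_cohort(in_dir) -> MethylationCohort:
    d = Path(in_dir)
    beta = pd.read_csv(d / "beta.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(d / "labels.tsv", sep="\t", dtype={"subtype": object}).set_index("sample_id")
    samples = labels.rename(columns={"class": "class_label", "subtype": "gc_subtype", "cohort": "cohort_id"})
    samples["gc_subtype"] = samples["gc_subtype"].where(samples["gc_subtype"].notna(), None)
    cohort = MethylationCohort(beta=beta, samples=samples)
    cohort.validate()
    return cohort


def write_annotation(ann: ProbeAnnotation, path) -> None:
    table = ann.table.copy()
    table["go_terms"] = [",".join(sorted(ts)) for ts in table["go_terms"]]
    table.to_csv(path, sep="\t")


def read_annotation(path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table["go_terms"] = [
        frozenset(str(ts).split(",")) if isinstance(ts, str) and ts else frozenset() for ts in table["go_terms"]
    ]
    table["on_27k"] = table["on_27k"].astype(bool)
    ann = ProbeAnnotation(table)
    ann.validate()
    return ann


def write_go_map(ann: ProbeAnnotation, path, labels: dict | None = None) -> None:
    """One (probe_id, go_accession, go_label) row per membership pair."""
    labels = labels or {}
    rows = [
        {"probe_id": pid, "go_accession": term, "go_label": labels.get(term, term)}
        for pid, terms in ann.go_map().items()
        for term in sorted(terms)
    ]
    pd.DataFrame(rows, columns=["probe_id", "go_accession", "go_label"]).to_csv(path, sep="\t", index=False)


def write_signatures(signatures: dict, path) -> None:
    payload = {
        term: {"probes": list(sig.probe_ids), "frequencies": dict(sig.frequencies)}
        for term, sig in signatures.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_signatures(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {
        term: Signature(go_term=term, probe_ids=tuple(rec["probes"]), frequencies=rec.get("frequencies", {}))
        for term, rec in payload.items()
    }
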