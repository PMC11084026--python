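#!/usr/bin/env python
"""Assemble the run report (BIC table, MPCMP, class curves, outcome
frequencies, association tables) into results/analysis/report.md."""

import argparse
import dataclasses
import json

from akitraj.pipeline import PipelineConfig, report

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", default="results/analysis")
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

# the numbered scripts run the stages piecemeal; synthesize the manifest
# the report reads if the orchestrated pipeline did not write one
manifest_path = f"{args.outdir}/manifest.json"
try:
    open(manifest_path)
except FileNotFoundError:
    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    consort = json.load(open(f"{args.outdir}/consort.json"))
    with open(manifest_path, "w") as fh:
        json.dump({"config": dataclasses.asdict(cfg),
                   "version": "0.1.0", "consort": consort["excluded"],
                   "counts": {"included": consort["included"]}}, fh)

text = report(args.outdir)
print(f"wrote {args.outdir}/report.md ({len(text.splitlines())} lines)")
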