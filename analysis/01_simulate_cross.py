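#!/usr/bin/env python
"""Simulate the synthetic F1 cross at the default study conditions.

Generates the draft genome (5 scaffolds, ~37% repeats, 5% gene models),
the near-homozygous maternal parent (0.03% heterozygosity) and
heterozygous paternal parent (0.37%), 51 F1 progeny, the NsiI+MseI
ddRAD digest with 200-500 bp size selection, and pooled barcoded 100 bp
reads with parents at twice the progeny depth.  Artifacts go to
scratch/run/ (raw run outputs stay out of results/).
"""

import json
from pathlib import Path

from radmap import pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main():
    cfg = pipeline.load_config(overrides={"workdir": str(SCRATCH / "run"), "seed": 1})
    info = pipeline.run_stage("simulate", cfg)
    workdir = Path(cfg["workdir"])
    manifest = json.loads((workdir / "manifest.simulate.json").read_text())
    print(f"wrote {info['n_reads']} reads and truth tables to {workdir}")
    print(f"outputs: {', '.join(manifest['outputs'])}")


if __name__ == "__main__":
    main()
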