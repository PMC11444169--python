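#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds a SNP panel with block LD, a set of genetically correlated metabolite
GWAS (selection strength alpha varying across metabolites and classes),
cross-species concentration matrices whose Brownian rates are coupled to
alpha, and MR instrument tables whose causal-effect scales decrease with
alpha.  Everything later steps consume is written under the output directory.
"""

import argparse
import json

from metabsel.pipeline import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results/study")
    args = ap.parse_args()
    cfg = RunConfig(out_dir=args.out, seed=args.seed)
    report = run_pipeline(cfg, stages=["simulate"])
    print(json.dumps(report["simulate"], indent=1))
    print(f"inputs written under {args.out}/ "
          "(panel/, sumstats/, concentrations/, mr_truth/, tree.nwk, classes.tsv)")


if __name__ == "__main__":
    main()
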