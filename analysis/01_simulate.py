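#!/usr/bin/env python
"""Generate the synthetic study system: toy genome-scale model (SBML + TSV),
four-day FPKM expression table, and per-day condition specifications.

Writes data/toy/; every later analysis step consumes these files.
"""

import argparse
from pathlib import Path

from ansaflux.synthetic import emit_fixtures

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "data" / "toy")
    args = parser.parse_args()
    paths = emit_fixtures(args.out, seed=args.seed)
    print(f"synthetic system written (seed {args.seed}):")
    for name, path in paths.items():
        print(f"  {name:11s} {path.relative_to(ROOT) if path.is_relative_to(ROOT) else path}")


if __name__ == "__main__":
    main()
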