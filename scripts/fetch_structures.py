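"""Download and cache the deposited antibody--pMHC structures (needs network).

Populates data/structures/ with 3CVH, 3GJF and 7TR4 in mmCIF format so that
the structural worked examples (tests/test_acceptance.py part A, and the
structural block of scripts/acceptance.py) can run offline afterwards.

Usage:  python scripts/fetch_structures.py [--dir data/structures]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tcrmkit.structure import fetch_structure  # noqa: E402

ACCESSIONS = ("3cvh", "3gjf", "7tr4")


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", default="data/structures", type=Path)
    args = ap.parse_args()
    for acc in ACCESSIONS:
        path = fetch_structure(acc, cache_dir=args.dir)
        print(f"{acc}: {path}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
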