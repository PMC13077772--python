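#!/usr/bin/env python
"""Fetch the structural benchmark inputs (requires network access).

The model-vs-crystal benchmark in tests/test_acceptance.py compares the
mart1-3 design model against the 2.2-A crystal structure of the same
binder/MART-1/HLA-A*02:01 complex (PDB entry 9O5S).  Neither file ships
with the package:

* the crystal structure is downloaded here from the RCSB;
* the design model is part of the design-campaign data deposit (Zenodo)
  and must be placed manually as ``data/benchmark/mart1_3_model.pdb``.

After fetching, edit ``data/benchmark/roles.json`` so the chain IDs of
each file map to roles MHC_HEAVY / B2M / PEPTIDE / BINDER, then rerun the
test suite: the benchmark test activates automatically once both files
exist.
"""

from __future__ import annotations

import json
import urllib.request
from pathlib import Path

BENCH = Path(__file__).resolve().parent.parent / "data" / "benchmark"
CRYSTAL_URL = "https://files.rcsb.org/download/9O5S.cif"

ROLES_TEMPLATE = {
    "model": {"A": "BINDER", "B": "MHC_HEAVY", "C": "B2M", "D": "PEPTIDE"},
    "crystal": {"A": "MHC_HEAVY", "B": "B2M", "C": "PEPTIDE", "D": "BINDER"},
}


def main() -> None:
    BENCH.mkdir(parents=True, exist_ok=True)
    crystal = BENCH / "9o5s.cif"
    if not crystal.exists():
        print(f"downloading {CRYSTAL_URL} ...")
        urllib.request.urlretrieve(CRYSTAL_URL, crystal)
        print(f"wrote {crystal}")
    roles = BENCH / "roles.json"
    if not roles.exists():
        roles.write_text(json.dumps(ROLES_TEMPLATE, indent=2) + "\n")
        print(f"wrote {roles} — edit the chain IDs to match the files")
    model = BENCH / "mart1_3_model.pdb"
    if not model.exists():
        print(
            f"missing {model}: copy the mart1-3 design model from the "
            "design-campaign data deposit into place manually"
        )


if __name__ == "__main__":
    main()
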