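"""One-time download of the four reference PDB entries used for
validation (2mxu, 2fkg, 1d2s, 3bep) into data/validation/.

Requires network access; run once, after which the reference-structure
tests and examples/05_reference_structures.py become runnable.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ENTRIES = ("2mxu", "2fkg", "1d2s", "3bep")
URL = "https://files.rcsb.org/download/{}.pdb"


def main() -> int:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "validation"
    out_dir.mkdir(parents=True, exist_ok=True)
    failures = 0
    for entry in ENTRIES:
        target = out_dir / f"{entry}.pdb"
        if target.exists():
            print(f"{target} already present")
            continue
        url = URL.format(entry.upper())
        try:
            print(f"fetching {url} ...")
            with urllib.request.urlopen(url, timeout=60) as response:
                target.write_bytes(response.read())
            print(f"  -> {target} ({target.stat().st_size} bytes)")
        except Exception as exc:
            print(f"  FAILED: {exc}", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
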