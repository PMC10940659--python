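"""Render the final tables and figures from the completed bundle.

Produces the subgroup summary table (AUROC and parity difference, mean and
spread per privacy level) and the AUROC-versus-epsilon curve with the
non-private result as a dashed reference line.
"""

from __future__ import annotations

import json
from pathlib import Path

from dpfair.pipeline import report


def main() -> None:
    bundle_path = Path("results/experiment/bundle.json")
    if not bundle_path.exists():
        raise SystemExit("run analysis/03_run_privacy_grid.py first")
    bundle = json.loads(bundle_path.read_text())
    paths = report(bundle, "results/report")
    print(f"summary table: {paths['table']}")
    print(f"figure:        {paths['figure']}")


if __name__ == "__main__":
    main()
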