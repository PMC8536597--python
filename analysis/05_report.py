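"""Summary tables of a finished analysis.

Emits, per model: the per-condition flux-distribution table, the Gibbs-
energy range table with the near/far classification, and the mean
flux-control-coefficient table. Requires 01-04 to have run.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from thermomca.pipeline import report

RESULTS = Path(__file__).resolve().parents[1] / "results"

for tag in ("toy", "full"):
    outdir = RESULTS / tag
    if not (outdir / "rates.tsv").exists():
        print(f"[{tag}] no artifacts found; run analysis/01-04 first")
        continue
    tables = report(outdir)
    print(f"[{tag}]")
    for name, path in tables.items():
        print(f"    {name}: {path}")
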