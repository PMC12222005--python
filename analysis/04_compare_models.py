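#!/usr/bin/env python
"""Cross-model comparison table (AIC differences vs the absolute-noise fit).

Collects the evaluation reports into one CSV shaped like the study's
comparison table: noise structure, AIC difference to the reference
(absolute normal environmental noise), non-positive prediction counts,
Bray-Curtis dissimilarity and CPI coverage.
"""

import json
from pathlib import Path

from atnfit import io as aio
from atnfit.evaluation import EvaluationReport

BASE = Path(__file__).resolve().parent.parent / "results"
REFERENCE = "env_normal_absolute"


def main() -> None:
    reports = {}
    for path in sorted((BASE / "reports").glob("*.json")):
        reports[path.stem] = EvaluationReport(**json.loads(path.read_text()))
    table = aio.compare_models(reports, REFERENCE)
    out = BASE / "comparison.csv"
    table.to_csv(out, index=False, float_format="%.6g")
    print(table.to_string(index=False))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
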