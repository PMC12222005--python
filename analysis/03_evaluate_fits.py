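#!/usr/bin/env python
"""Evaluate the calibrated models against the synthetic data.

For each fit, computes AIC, the Bray-Curtis dissimilarity between the
one-step-ahead predictive medians and the observations, the 90% CPI
coverage, and the non-positive prediction counts; writes one JSON
report per model under results/reports/.
"""

import json
from pathlib import Path

from atnfit import io as aio
from atnfit.calibration import FitResult, NonPositiveCounts
from atnfit.evaluation import evaluate
from atnfit.noise import NoiseSpec

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    web = aio.read_web_yaml(BASE / "data" / "web.yaml")
    data = aio.read_biomass_csv(BASE / "data" / "biomass.csv")
    data.catches = aio.read_catch_csv(BASE / "data" / "catch.csv", data)
    outdir = BASE / "reports"
    outdir.mkdir(parents=True, exist_ok=True)
    for path in sorted((BASE / "fits").glob("*.json")):
        doc = aio.read_fit_result(path, web)
        cfg = doc["config"]
        noise = NoiseSpec(cfg["layer"], cfg["family"], cfg["scaling"], doc["sigma"])
        res = FitResult(
            params=doc["params"], sigma=doc["sigma"], B_init=doc["B_init"],
            loss=doc["loss"], loglik=doc["loglik"],
            n_nonpositive=NonPositiveCounts(**doc["n_nonpositive"]),
            aic=doc["aic"], n_parameters=doc["n_parameters"],
        )
        rep = evaluate(res, data, web, noise)
        (outdir / path.name).write_text(json.dumps(rep.to_dict(), indent=1))
        print(
            f"{path.stem}: AIC {rep.aic:.1f}, BC {rep.bray_curtis_dissimilarity:.3f} "
            f"(similarity {rep.similarity:.1%}), 90% CPI coverage {rep.cpi_coverage:.1%}, "
            f"nonpositive {rep.n_nonpositive_all} ({rep.n_nonpositive_excl_detritus} excl. detritus)"
        )


if __name__ == "__main__":
    main()
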