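"""Behavioral analyses: similarity slope and social-context contrasts.

Fits the correlational mixed model (sharing ~ perceived similarity,
crossed intercepts for participant and article; with and without
interest/valence adjustment) and the experimental linear model (sharing ~
condition, all pairwise contrasts, BH-FDR) on the simulated behavioral
tables, and prints the standardized estimates.
"""

from pathlib import Path

import pandas as pd

from dyadisc.io import read_tsv
from dyadisc.pipeline import RunConfig, run_pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    config = RunConfig(
        outdir=str(OUTDIR), seed=2026, stages=("fit-study2", "fit-study3")
    )
    run_pipeline(config)

    s2 = read_tsv(OUTDIR / "study2_results.tsv")
    print("perceived-similarity slope (standardized):")
    print(
        s2[["model", "estimate", "se", "t", "df", "p_raw", "ci_low", "ci_high"]]
        .round(4)
        .to_string(index=False)
    )

    s3 = read_tsv(OUTDIR / "study3_results.tsv")
    print("\ncondition contrasts (BH-FDR within model):")
    with pd.option_context("display.width", 140):
        print(
            s3[["model", "contrast", "estimate", "estimate_raw", "t", "df", "p_adjusted"]]
            .round(4)
            .to_string(index=False)
        )


if __name__ == "__main__":
    main()
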