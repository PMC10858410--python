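"""Mixed-model inference on the cardiac metrics.

Fits, for every metric, the random-intercept model
``metric ~ incubation + (1 | clutch)`` and the Tukey-adjusted pairwise
incubation contrasts; writes results/lmm_estimates.csv and
results/tukey_contrasts.csv and prints the incubation slopes with their
marginal/conditional R2.
"""

import argparse
from pathlib import Path

from cardiothermal.io import read_table, write_table
from cardiothermal.pipeline import lmm_table, tukey_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    metrics = read_table(args.results / "metrics.csv")
    lmm = lmm_table(metrics)
    tukey = tukey_table(metrics)
    write_table(lmm, args.results / "lmm_estimates.csv", {"source": "metrics.csv"})
    write_table(tukey, args.results / "tukey_contrasts.csv", {"source": "metrics.csv"})

    slopes = lmm[lmm["term"] == "incubation"]
    print("incubation slopes (per degC of incubation temperature):")
    print(
        slopes[["metric", "estimate", "se", "p", "r2_marginal", "r2_conditional"]]
        .round(3)
        .to_string(index=False)
    )
    sig = tukey[tukey["p_tukey"] < 0.05]
    print(f"{len(sig)}/{len(tukey)} Tukey contrasts significant at 0.05")


if __name__ == "__main__":
    main()
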