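"""Construct the asset-PCA wealth index and SES ranking on the analysis sample.

Filters to households with positive tobacco spending, fits the first
principal component of the standardized asset indicators, appends wealth
score, quintile and fractional rank, and reports how well the asset index
recovers the generator's hidden wealth factor.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from tehb import (fit_wealth_index, fractional_rank, load_households,
                  prepare_analysis_sample, score_and_classify)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    raw = load_households(RESULTS / "households.csv")
    sample, dropped = prepare_analysis_sample(raw)
    print(f"analysis sample: {len(sample)} spender households "
          f"({dropped} with zero tobacco spending dropped)")

    indicators = sorted((c for c in sample.columns if c.startswith("asset_")),
                        key=lambda c: int(c.split("_")[1]))
    model = fit_wealth_index(sample, indicators)
    scored = score_and_classify(sample, model)
    scored["frac_rank"] = fractional_rank(scored["wealth_score"].to_numpy())

    scored.to_csv(RESULTS / "scored_sample.csv", index=False)
    model.to_file(RESULTS / "wealth_model.txt")

    print(f"PC1 variance explained: {model.variance_explained:.3f}")
    rho = spearmanr(scored["wealth_score"], scored["latent_wealth"]).statistic
    print(f"Spearman(wealth score, latent wealth): {rho:.3f} "
          "(the asset index tracks the hidden factor)")
    means = scored.groupby("wealth_quintile")["tehb"].mean()
    print("mean TEHB (%) by quintile, poorest to richest:",
          "  ".join(f"{v:.2f}" for v in means))


if __name__ == "__main__":
    main()
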