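#!/usr/bin/env python
"""Publication-bias battery on the working dataset.

Cumulative meta-analysis by publication year per response category, funnel
coordinates (points and pseudo-CI rails), the weighted (SE-moderator)
asymmetry test per category, and the pooled inverse-variance OLS regression
across all mean-based effects.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from seqherb.bias import OLS_INVERSE_VARIANCE, WEIGHTED_SEI, cumulative_meta, egger_test, funnel_coordinates
from seqherb.reml import ModelSpec

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    es = pd.read_csv(OUT / "effect_sizes.csv")
    g = es[es["metric"] == "hedges_g"]
    bias_dir = OUT / "bias"
    bias_dir.mkdir(parents=True, exist_ok=True)
    spec = ModelSpec.three_level()

    pooled = egger_test(g["yi"].to_numpy(), g["vi"].to_numpy(), variant=OLS_INVERSE_VARIANCE)
    print(
        f"pooled Egger regression (effect on 1/variance): slope = "
        f"{pooled.slope:.3f} ± {pooled.slope_se:.3f}, "
        f"F({pooled.df[0]},{pooled.df[1]}) = {pooled.statistic:.3f}, p = {pooled.p:.3f}"
    )
    for cat, sub in g.groupby("response_category"):
        res = egger_test(
            sub["yi"].to_numpy(), sub["vi"].to_numpy(), variant=WEIGHTED_SEI, frame=sub
        )
        print(f"  {cat:24s} k={len(sub):4d}  asymmetry z = {res.statistic:+.3f}, p = {res.p:.3f}")
        series = cumulative_meta(sub, spec)
        series.to_csv(bias_dir / f"cumulative_{cat}.tsv", sep="\t", index=False)
        points, rails = funnel_coordinates(sub["yi"].to_numpy(), sub["vi"].to_numpy())
        points.to_csv(bias_dir / f"funnel_points_{cat}.tsv", sep="\t", index=False)
        rails.to_csv(bias_dir / f"funnel_rails_{cat}.tsv", sep="\t", index=False)
        first, last = series.iloc[0], series.iloc[-1]
        print(
            f"    cumulative series: {len(series)} steps, "
            f"{first['year']:.0f} (g={first['estimate']:+.3f}) -> "
            f"{last['year']:.0f} (g={last['estimate']:+.3f})"
        )
    print(f"wrote cumulative/funnel tables under {bias_dir}")


if __name__ == "__main__":
    main()
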