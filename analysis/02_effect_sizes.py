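#!/usr/bin/env python
"""Compute effect sizes for the working dataset.

Turns raw per-arm summaries into Hedges' g (with the small-sample correction
J and the outcome sign convention applied) and binary counts into log odds
ratios, then reports how many records were usable and the distribution of
effect values per response category.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from seqherb.dataset_io import read_dataset
from seqherb.effect_sizes import compute_effect_sizes
from seqherb.pipeline import derive_moderator_columns

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = read_dataset(OUT / "simulated_dataset.csv", strict=False)
    es = derive_moderator_columns(compute_effect_sizes(ds.frame))
    es.to_csv(OUT / "effect_sizes.csv", index=False)
    print(f"effect sizes computed for {len(es)} of {len(ds)} records")
    for (cat, metric), part in es.groupby(["response_category", "metric"]):
        print(
            f"  {cat:24s} {metric:15s} k={len(part):4d} "
            f"mean={part['yi'].mean():+.3f} median v={part['vi'].median():.3f}"
        )
    print(f"wrote {OUT / 'effect_sizes.csv'}")


if __name__ == "__main__":
    main()
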