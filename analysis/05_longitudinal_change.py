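#!/usr/bin/env python
"""Longitudinal (one-year) T2 change per group and layer.

Within-knee paired t-tests of year-1 minus baseline per group/layer on the
simulated cohort, the superficial-minus-deep change contrast, and the
reproduction of the published healthy deep-layer change CI from its summary
statistics.  Change tests use the descriptive p < 0.05 convention.

Writes results/longitudinal_changes.csv.
"""

from pathlib import Path

import pandas as pd

from cartt2 import io as cio
from cartt2 import reference
from cartt2.stats import change_from_summary, layer_change_contrast, paired_change

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cm, cs = reference.T2_CHANGE[("healthy", "Avg", "deep")]
    ref = change_from_summary(cm, cs, 89)
    print(f"published healthy deep change {cm} +/- {cs} ms (n 89) -> "
          f"95% CI [{ref.ci95[0]:.2f}, {ref.ci95[1]:.2f}] ms, p {ref.p_value:.2g}")

    cohort = cio.load_cohort(ROOT / "data" / "cohort.csv")
    rows = []
    for group in ("riskROA", "earlyROA", "healthy"):
        for layer in ("deep", "superficial"):
            ch = paired_change(cohort, group, "Avg", layer)
            sig = "significant" if ch.p_value < 0.05 else "ns"
            print(f"{group:>8} {layer:<12} change {ch.mean_change_ms:+5.2f} "
                  f"+/- {ch.sd_change_ms:.2f} ms (n {ch.n}) p {ch.p_value:.3g} [{sig}]")
            rows.append({
                "group": group, "layer": layer,
                "mean_change_ms": ch.mean_change_ms, "sd_change_ms": ch.sd_change_ms,
                "ci_low": ch.ci95[0], "ci_high": ch.ci95[1],
                "p": ch.p_value, "n": ch.n,
            })
        c = layer_change_contrast(cohort, group)
        print(f"{group:>8} superficial-minus-deep contrast {c.mean_change_ms:+5.2f} ms "
              f"p {c.p_value:.3g}")
        rows.append({
            "group": group, "layer": "superficial_minus_deep",
            "mean_change_ms": c.mean_change_ms, "sd_change_ms": c.sd_change_ms,
            "ci_low": c.ci95[0], "ci_high": c.ci95[1], "p": c.p_value, "n": c.n,
        })
    pd.DataFrame(rows).to_csv(ROOT / "longitudinal_changes.csv", index=False)
    print(f"-> {ROOT / 'longitudinal_changes.csv'}")


if __name__ == "__main__":
    main()
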