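#!/usr/bin/env python
"""Summarize the textile-electrode resistance bench measurements.

Two conductive-lycra segments (posterior and anterior) were each measured six
times with a two-wire multimeter; the per-segment statistics below are the
bench report for the prototype sock.  The script reduces them to the overall
mean resistance, the worst-case spread across all measurements (absolute and
as a percentage of the mean), and the equivalent conductance — the figure of
merit showing the electrode path sits orders of magnitude above the EDA
sensor's microsiemens measurement range.
"""

import json
from pathlib import Path

from socksig.io import resistance_summary_from_stats, round_half_away

ROOT = Path(__file__).resolve().parents[1]

BENCH_STATS = {
    "posterior": {"mean": 32.65, "sd": 0.82, "min": 32.09, "max": 33.59},
    "anterior": {"mean": 32.06, "sd": 0.18, "min": 31.92, "max": 32.26},
}


def main() -> None:
    summary = resistance_summary_from_stats(BENCH_STATS)
    out = ROOT / "results" / "electrode_summary.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    print(
        f"overall mean {round_half_away(summary.overall_mean, 2):.2f} ohm | "
        f"max spread {summary.max_difference:.2f} ohm "
        f"({round_half_away(summary.max_difference_pct_of_mean, 2):.2f}% of mean) | "
        f"{round_half_away(summary.mean_conductance, 2):.2f} mS"
    )


if __name__ == "__main__":
    main()
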