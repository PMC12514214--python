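"""Generate microscope-like series for all three experimental scenarios.

Each scenario yields a (time, area) table at 2 frames per second with
seeded multiplicative noise, the way the flow-cell experiment records a
single particle. Series are written as CSV next to this script; the
printed summary shows the size range each condition produces.
"""

from pathlib import Path

from cmpkinetics import generate, scenario_defaults, write_kinetics_csv
from cmpkinetics.synthetic import SCENARIOS

out_dir = Path(__file__).parent
for tag in SCENARIOS:
    series = generate(scenario_defaults(tag))
    path = out_dir / f"{tag}_series.csv"
    write_kinetics_csv(series, path)
    print(
        f"{tag:22s}: {len(series):5d} frames over {series.times[-1]:6.0f} s, "
        f"area {series.areas.min():7.1f} .. {series.areas.max():7.1f} um^2 "
        f"-> {path.name}"
    )
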