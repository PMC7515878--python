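"""A kinetic aggregation trajectory from free monomers.

Simulates the continuous-time chain whose elementary move is a single
bond toggle with rate r = A / (1 + exp(beta dH - dS)), then tracks the
aggregation metrics along the trajectory.  Time is in units of inverse
collision rate (A = 1).
"""

from pathlib import Path

from fibrilnet import metric_series, simulate
from fibrilnet.io import load_params

params = load_params(Path(__file__).parent / "params" / "illustrative_1ribbon.yaml")

traj = simulate(30, params, seed=11, max_events=1200, frame_interval=300)
print(f"simulated {traj.num_events} events over t = {traj.duration:.1f} "
      "(inverse collision rate units)")

series = metric_series(traj, "1-ribbon", stride=200)
cols = ["time", "avg_component_size", "max_fibril_size",
        "fibril_component_count", "fibril_fraction"]
print(series[cols].to_string(index=False, float_format=lambda x: f"{x:8.2f}"))

# Average component size starts at 1 (free monomers) and grows as bonds
# form; the fibril columns report the induced fibrillar components under
# the 1-ribbon template: with chain-favoring coefficients a large part of
# the system ends up in ribbon segments (fibril_fraction -> ~0.8-1).
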