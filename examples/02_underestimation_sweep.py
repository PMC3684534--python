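"""Sweep the underestimation gain G for both rotation directions.

For each (direction, G) the pipeline corrupts the feedforward torque
commands with trunk kinematics divided by G, executes them under the true
rotation, and scores the final hand deviation against the veridical (G=1)
execution. Prints the result table and the headline asymmetry.
"""

import trunkreach as tr

table, results = tr.sweep(G_grid=(1.0, 1.1, 1.2, 1.3, 1.4, 1.5))

print("direction   G    underest.%   final error (cm)")
for _, row in table.iterrows():
    print(
        f"   {row['direction']:3s}   {row['G']:4.2f}   {row['percent']:8.1f}   "
        f"{row['final_error_m'] * 100:10.2f}"
    )

ccw = table[(table.direction == "ccw") & (table.G == 1.5)].iloc[0]
cw = table[(table.direction == "cw") & (table.G == 1.5)].iloc[0]
print(
    f"\nAt 33% underestimation the hand misses by {ccw.final_error_m * 100:.1f} cm "
    f"(CCW) vs {cw.final_error_m * 100:.1f} cm (CW): "
    f"{ccw.final_error_m / cw.final_error_m:.2f}x larger for CCW."
)
print(
    "Errors grow monotonically with the misperception, and misjudging a "
    "counter-clockwise rotation is always costlier for the right hand, "
    "because the Coriolis and centripetal command errors add instead of "
    "cancelling."
)
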