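"""Secondary-extinction robustness of plant-fungus networks.

Removes one guild in random order, tracks survival of the other guild
(a species survives while it retains at least one partner), fits
y = 1 - x^a to the mean curve and reports robustness R = a/(a+1),
the area below the curve (R -> 1 means highly tolerant).
"""

import phyllonet as pn

for structure in ("nested", "specialized"):
    m = pn.simulate_network(
        pn.NetworkSimParams(
            n_plants=8, n_fungi=8, structure=structure,
            noise=0.0, total_weight=2000, seed=1,
        )
    )
    curve = pn.simulate_extinctions(m, primary_axis="plants", n_rep=200, seed=2)
    fit = pn.fit_extinction_curve(curve)
    print(
        f"{structure:12s} a = {fit.a:6.2f}  R_fitted = {fit.R_fitted:.3f}  "
        f"R_empirical = {fit.R_empirical:.3f}"
    )
print(
    "Nested networks keep generalist partners available longer, so their "
    "survival curves are flatter and R is higher than in one-to-one "
    "specialist networks (where every removal kills exactly one partner)."
)
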