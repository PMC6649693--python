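"""Distinguish two-state from multi-site binding by peak-trajectory shape.

In pure two-state fast exchange every peak moves on a straight line between
its free and bound positions; a weak second site with its own shift
direction bends the path.  This example simulates both regimes and counts
the nonlinear calls.
"""

from titramap import BindingParams, SimConfig, classify_trajectory, extract_trajectories, generate_titration


def rate(kd2, seed):
    cfg = SimConfig(
        seed=seed, n_residues=200, patches=((1, 200, 0.25),),
        proline_fraction=0.0, noise_shift_sd=0.001,
        binding=BindingParams(kd1=5.0, kd2=kd2),
    )
    series, _ = generate_titration(cfg)
    labels = [
        classify_trajectory(t, noise_sd=0.001, dev_factor=3.0).label
        for t in extract_trajectories(series)
    ]
    kept = [l for l in labels if l in ("linear", "nonlinear")]
    return sum(l == "nonlinear" for l in kept) / len(kept)


print(f"two-site residues (Kd2 = 20 x Kd1) called nonlinear: {rate(100.0, 11):.1%}")
print(f"single-site residues called nonlinear (false rate):  {rate(None, 12):.1%}")
# The classifier fits a total-least-squares line through each trajectory in
# the (dH, 0.14*dN) plane; curvature beyond 3x the positional noise marks a
# residue whose shifts respond to more than one bound species.
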