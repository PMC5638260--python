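"""Exact coverage times from the kernel's eigendecomposition.

For 100 sites, compares the global time tau (mean steps to reach a
randomly chosen site from a random start) across exploration strategies:
long-range (alpha <= 1) vs nearly local (alpha = 10) at a small radius.
Also cross-checks one site's spectral reach time against direct
first-passage simulation.
"""

import encounternet as en

loc = en.generate_locations(100, seed=5)
distances = en.pairwise_distances(loc)

print("alpha    tau (steps to reach a random site)")
for alpha in (0.1, 0.5, 1.0, 3.0, 10.0):
    kernel = en.LevyKernel.from_distances(distances, alpha, radius=0.05)
    sol = en.solve(kernel)
    print(f"{alpha:5.1f}    {sol.tau_global:12.1f}")
# tau is flat for alpha <= 1 and explodes for the nearly-local strategy:
# long-range hops are what lets a walker cover the whole location set.

kernel = en.LevyKernel.from_distances(distances, 3.0, radius=0.05)
sol = en.solve(kernel)
mc_mean, mc_se = en.mc_first_passage_oracle(kernel, target=7, repeats=5000, seed=9)
print(f"\nsite 7 reach time: spectral {sol.tau_per_site[7]:.1f}, "
      f"Monte Carlo {mc_mean:.1f} +- {mc_se:.1f}")
# The two numbers agree within a few standard errors: the eigenmode sum is
# an exact closed form for what the simulation estimates.
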