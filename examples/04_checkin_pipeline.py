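"""Full empirical pipeline on a synthetic city's check-in stream.

Generates check-ins for 30 users over two months with planted heavy
tails (inter-event exponent gamma=2.5, displacement exponent delta=1.5)
and shared hotspot venues, then runs the analysis: power-law fits,
hourly co-coincidence detection at delta_r = 100 m, the frequency f(n)
of repeated meetings, and the largest component of the cumulative
encounter network.
"""

import numpy as np

import encounternet as en

cfg = en.SyntheticConfig(n_users=30, duration_h=24 * 60, gamma_true=2.5,
                         delta_true=1.5, p_hotspot=0.3, n_hotspots=10,
                         seed=11)
table = en.generate(cfg)
print(f"{len(table)} check-ins from {table.n_users} users")

gaps = en.interevent_times(table)
fit_g = en.fit_power_law_xmin(gaps)
print(f"inter-event times: gamma = {fit_g.exponent:.2f} "
      f"(planted 2.5), tau_min = {fit_g.x_min:.2f} h, "
      f"{fit_g.n_tail} tail samples")

r = en.displacements(table)
fit_d = en.fit_power_law_range(r, *cfg.r_range_km)
print(f"displacements:     delta = {fit_d.exponent:.2f} (planted 1.5) "
      f"on [{cfg.r_range_km[0]}, {cfg.r_range_km[1]}] km")

co = en.hourly_cocoincidences(table, delta_r=100.0)
f_n = en.coincidence_frequency(co)
print(f"pairs with >=1 co-coincident hour: {len(co.events)}; "
      f"f(n) head: {dict(list(f_n.items())[:5])}")

A = en.cumulative_network(co, c=1, t=np.iinfo(np.int64).max)
summary = en.largest_component_summary(A)
print(f"largest component (c=1): N={summary.size}, E={summary.edges}, "
      f"<k>={summary.mean_degree:.2f}, <C>={summary.mean_clustering:.3f}, "
      f"diameter={summary.diameter}, <d>={summary.mean_distance:.2f}")
# gamma is recovered almost exactly; delta comes out slightly low because
# 30% of moves snap to the nearest hotspot, perturbing the planted lengths
# (with p_hotspot=0 the fit lands within ~0.01 of 1.5).  The repeated
# hotspot visits knit all users into one clustered, small-diameter component.
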