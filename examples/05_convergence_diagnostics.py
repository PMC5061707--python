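"""Convergence diagnostics for the posterior chains.

Runs a moderate two-chain sampler on the bladder-cancer data and prints
the numbers behind the usual diagnostic panels: autocorrelation, running
(ergodic) means, the Brooks-Gelman-Rubin trajectory and box-plot stats.
"""

from llsurv import MCMCConfig, diagnostics_report, load_bladder_fixture, sample_posterior

sample = load_bladder_fixture()
cfg = MCMCConfig(n_iter=12_000, burn_in=2_000, thin=5, n_chains=2, seed=7)
chains = sample_posterior(sample, config=cfg)

for name in ("alpha", "lambda"):
    rep = diagnostics_report(chains, name)
    acf1 = rep["acf"].iloc[1]
    print(f"\n--- {name} ---")
    print(f"lag-1 autocorrelation: chain 1 {acf1['chain_0']:.3f}, "
          f"chain 2 {acf1['chain_1']:.3f}")
    rm = rep["running_mean"]
    print(f"ergodic mean settles at {rm['chain_0'].iloc[-1]:.4f} (chain 1), "
          f"{rm['chain_1'].iloc[-1]:.4f} (chain 2)")
    traj = rep["bgr_trajectory"]
    print(f"BGR interval ratio over windows: first {traj['ratio'].iloc[0]:.3f} "
          f"-> last {traj['ratio'].iloc[-1]:.3f}; final R-hat = {rep['rhat_final']:.4f}")
    box = rep["boxplot"]
    print(f"box stats (P2.5, Q1, mean, Q3, P97.5): "
          f"({box['p2_5']:.3f}, {box['q1']:.3f}, {box['mean']:.3f}, "
          f"{box['q3']:.3f}, {box['p97_5']:.3f})")

print("\nAn R-hat near 1 and a flat ergodic mean say the chains have mixed; "
      "values above ~1.1 would call for longer runs.")
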