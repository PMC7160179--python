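"""Simulate a phylogeny with one planted allometric shift and recover it.

Generates an 80-tip tree whose log call-frequency ~ log body-size relation
jumps to a higher optimum in a 20-species clade, runs two rjMCMC chains,
checks convergence, and prints the per-branch shift support plus the
estimated regimes.
"""
import oushift as ou

tree, table, config, params, delta = ou.simulate.planted_shift_dataset(
    n_tips=80, target_tips=20, seed=5)
true_branch = config.shifts[0].branch
print(f"planted shift on branch {true_branch} "
      f"({tree.below_mask()[true_branch].sum()} species), "
      f"optimum displaced by {delta:.2f} log Hz")

traces = ou.run_analysis(tree, table, "a", ou.Priors(kmax=50),
                         n_chains=2, generations=150_000, thinning=100,
                         seed=1)
report = ou.gelman_r(traces, tree)
print(f"convergence: max R = {report.max_r:.3f} "
      f"({'converged' if report.converged else 'NOT converged'})")

summary = ou.summarize_shifts(traces, tree)
print(f"posterior mean number of shifts: {summary.mean_k:.2f}")
print(f"supported shifts (pp >= 0.7, > 3 species): {summary.supported}")
print(f"pp on the true branch: {summary.branch_pp.get(true_branch, 0.0):.2f}")
print()
print("regimes (optimum theta in log Hz, slope beta per log mm):")
print(summary.to_frame().to_string(index=False))
print()
print("The root regime's theta/beta should sit near the truth (9.3, -0.45);")
print("a supported branch equal to the planted one is a correct detection.")
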