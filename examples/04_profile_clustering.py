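"""Cluster core-protein trajectories per hemisphere into model temporal profiles.

Each trajectory (three ordered weeks, differences from its first value) is
assigned to the most correlated of 16 integer-step model shapes; enrichment of
a profile is judged against the exact null of all 3! orderings of each
protein's values.
"""

import latproteo as lp

matrix, design, _ = lp.generate(lp.SimParams(n_proteins=1000, seed=1))
dm = lp.join_design(matrix, design)
lm = lp.log2_normalize(dm, lp.detection_sets(dm).core)

for side in ("L", "R"):
    ps = lp.run_profiles(lm, design, side, c=2, m=16, alpha=0.05)
    sig = ps.table[ps.table["significant"]].sort_values("p")
    print(f"side {side}: {len(ps.assignment)} proteins over {len(ps.models)} profiles, "
          f"{len(sig)} significant at alpha = 0.05")
    for _, row in sig.iterrows():
        print(f"  profile {row['profile_id']} shape ({row['shape']}): "
              f"n = {row['n']}, expected {row['expected']:.1f}, p = {row['p']:.2e}")
print("A significant profile holds more trajectories than the permutation null "
      "predicts; its shape describes the shared temporal pattern (e.g. 0,1,2 = "
      "steady rise across weeks).")
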