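"""Partner competition across sampled crowded environments.

Embeds a target complex in random environments of 20 complexes
(40 proteins), computes interaction-rank distributions for candidate
partners of the target receptor, and labels the three partner
populations: strong competitors, never-competing proteins, and
intermediate, variable-strength binders.
"""

from ccdock.pipeline import run_environment_study

study = run_environment_study(n_complexes=30, seed=0, n_sets=50,
                              promiscuous="C005_r", inert="C007_l")

print(f"environments: {len(study.environment_sizes)} sets of "
      f"{study.environment_sizes[0]} proteins")
print(f"native pair mean IR {study.mean_ir_native:.1f} "
      f"(sd {study.sd_ir_native:.1f})")

counts = {}
for s in study.signatures:
    counts[s.label] = counts.get(s.label, 0) + 1
print("population sizes:", dict(sorted(counts.items())))

by = {s.candidate: s for s in study.signatures}
for pid in ("C005_r", "C007_l"):
    s = by[pid]
    print(f"{pid}: mean IR {s.mean_ir:.1f}, sd {s.sd_ir:.1f} -> {s.label}")
print(f"partners competing at rank <= 10 (native excluded): "
      f"{study.false_positives}")
# the planted promiscuous protein always ranks top; the planted inert
# protein always ranks last; both have near-zero rank spread
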