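"""Evaluate marker-panel combination rules against routine cytology.

Runs the full pipeline on a synthetic study-calibrated cohort with the
reference cutoffs (HOXB7 ≤ 9.4, IGF2BP3 ≤ 11.46, NEK2 ≤ 9.27 cycles)
and prints a performance column per rule: dichotomized cytology (M only,
then suspicious-or-malignant), each single marker, 1/2/3-of-3 gene
votes, and cytology OR 2-of-3.  Sensitivity trades against specificity
as the vote threshold m rises; the OR-combination recovers cytology
misses at little specificity cost.
"""

from brushdx import RunConfig, run

report = run(RunConfig(seed=1, fixed_cutoffs={"HOXB7": 9.4, "IGF2BP3": 11.46, "NEK2": 9.27}))

print(f"{'rule':<22}{'sens%':>7}{'spec%':>7}{'PPV%':>7}{'NPV%':>7}{'acc%':>7}")
for name, entry in report["rules"].items():
    cells = [entry[k]["display"] for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy")]
    print(f"{name:<22}" + "".join(f"{c:>7}" for c in cells))
print(f"\nn = {report['n_patients']} patients "
      f"(prevalence {report['rules']['2_of_3']['prevalence']:.3f}); "
      "marker-positive = ΔCt at or below the cutoff.")
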