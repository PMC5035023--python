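"""Cohort QA aggregation: reproduce published-style acceptance tables.

Builds flag-level QA fixtures for two sub-cohorts (1,000 subjects with
the extensive QA profile; 2,000 under the reduced acceptance protocol),
applies the acceptance rules and prints the nested analysability tiers
and rejection-reason shares.
"""

from dixoncomp import generate_cohort_fixture, summarize_cohort
from dixoncomp import validation as V

rec1 = generate_cohort_fixture(V.table1_cohort_config(), 1000, seed=0)
rec2 = generate_cohort_fixture(V.table3_cohort_config(), 2000, seed=1)

for name, records in (("first 1,000", rec1), ("next 2,000", rec2),
                      ("combined 3,000", rec1 + rec2)):
    s = summarize_cohort(records)
    print(f"{name}: n={s.n}")
    print(f"  analysable fat            {s.analysable_fat:5d}  "
          f"{s.analysable_fat_pct:6.2f}%")
    print(f"  analysable fat + 1 thigh  {s.analysable_fat_one_thigh:5d}  "
          f"{s.analysable_fat_one_thigh_pct:6.2f}%")
    print(f"  analysable fat + 2 thighs {s.analysable_fat_both_thighs:5d}  "
          f"{s.analysable_fat_both_thighs_pct:6.2f}%")

s1 = summarize_cohort(rec1)
print("\nartifact prevalence, first 1,000:")
for flag, count in s1.flag_counts.items():
    print(f"  {flag:26s} {count:4d}  {s1.flag_percentages[flag]:6.2f}%")

rej = summarize_cohort(generate_cohort_fixture(
    V.rejection_reason_config(), 1000, seed=2))
print(f"\nrejected subjects: {rej.n_rejected}; primary reasons:")
for code, count in rej.rejection_reason_counts.items():
    print(f"  {code:18s} {count:3d}  "
          f"{rej.rejection_reason_percentages[code]:6.2f}%")
print("\nPercentages are rounded half-up to two decimals; tiers are")
print("nested (fat only >= fat+1 thigh >= fat+both thighs).")
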