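"""Generate a seeded case-control cohort and match controls hierarchically.

Builds a cohort of first-episode mania cases (BD) plus a healthy-control
pool, then selects matched controls by the study hierarchy: gender first,
then age within a 2-year window, then handedness.
"""

from morphosvm import CohortSpec, generate_cohort, match_controls
from morphosvm.cohort import subjects_to_frame

spec = CohortSpec(
    n_per_group={"BD": 23, "HC": 40},
    volume_shape=(8, 8, 8),  # small grid: demographics are the point here
    seed=7,
)
cohort = generate_cohort(spec)

cases = [s for s in cohort.subjects if s.group == "BD"]
pool = [s for s in cohort.subjects if s.group == "HC"]
controls = match_controls(cases, pool, max_controls=33)

df = subjects_to_frame(cases + controls)
print(df.groupby("group")[["age"]].agg(["mean", "std"]).round(2))
print()
for group, sub in df.groupby("group"):
    male = (sub.gender == "M").mean()
    right = (sub.handedness == "right").mean()
    print(f"{group}: {len(sub)} subjects, {male:.0%} male, {right:.0%} right-handed")

# The matched controls should mirror the cases' gender split and sit within
# the same age range — the hierarchical criteria enforce exactly that when
# the pool allows.
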