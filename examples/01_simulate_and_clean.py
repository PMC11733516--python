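"""Generate a synthetic survey cohort and run the exclusion pipeline.

Plants 20 speeders, 33 irrelevance-flagged records and 52 under-length
records in a 522-record cohort, then applies the three exclusion criteria
in order (completion time <= 5 min, manual irrelevance flag, fewer than 3
distinct words on any question) and prints the audit ledger.
"""

from qcla import PlantedCounts, SimulationSpec, generate_cohort, run_pipeline

spec = SimulationSpec(
    n_respondents=522,
    planted=PlantedCounts(time_fail=20, irrelevant=33, wordmin_fail=52),
    seed=42,
)
raw, truth = generate_cohort(spec)
dataset, ledger = run_pipeline(raw)

print(f"collected responses : {ledger.initial_n}")
print(f"excluded, time      : {ledger.excluded_time}")
print(f"excluded, irrelevant: {ledger.excluded_irrelevant}")
print(f"excluded, word min  : {ledger.excluded_wordmin}")
print(f"analyzed sample     : {ledger.final_n}")
print()
print("first respondent's aggregated answers:")
for q in range(1, 5):
    print(f"  Q{q}: {dataset.iloc[0][f'q{q}']}")
# Each excluded record carries exactly one disposition (first failing rule),
# so the four counts always sum to the number collected.
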