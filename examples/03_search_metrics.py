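"""Per-trial search measures and the exclusion cascade.

Runs the full trial pipeline (object assignment, accuracy correction,
RT decomposition into initiation / scanning / verification, counts) on
a synthetic experiment and prints the exclusion summary and
condition-wise means with within-subject standard errors.
"""

from vrsearch.pipeline import included, process_experiment
from vrsearch.search import exclusion_summary
from vrsearch.stats import within_subject_se
from vrsearch.synthgen import GeneratorConfig, generate_experiment

exp = generate_experiment(GeneratorConfig(n_participants=6), seed=5)
metrics, _ = process_experiment(exp, with_saccade_table=False)

print("exclusion cascade (percent of all trials):")
print(exclusion_summary(metrics).round(2).to_string(index=False))

inc = included(metrics)
print(f"\nincluded trials: {len(inc)} of {len(metrics)}")
for col in ("rt_ms", "initiation_ms", "scanning_ms", "verification_ms"):
    means = inc.groupby("condition", observed=True)[col].mean()
    wse = within_subject_se(inc, col)
    print(f"{col:16s} upright {means['upright']:7.0f} +/- {wse['upright']:5.0f}   "
          f"inverted {means['inverted']:7.0f} +/- {wse['inverted']:5.0f}  (ms, within-subject SE)")

gap = (inc["initiation_ms"] + inc["scanning_ms"] + inc["verification_ms"]
       - inc["rt_ms"]).abs().max()
print(f"\nphase additivity: max |initiation + scanning + verification - RT| "
      f"= {gap:.2e} ms")
print("Scanning and verification are longer in inverted scenes; initiation "
      "is unaffected — searching and recognizing suffer, launching does not.")
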