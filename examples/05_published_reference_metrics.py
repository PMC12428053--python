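"""Recompute the published diagnostic metrics from packaged category counts.

No imaging involved: the packaged four-category counts of the published
123-examination cohort are fed through the same metric calculator the
pipeline uses, reproducing every printed percentage to one decimal.
"""

from ctperf import diagnostic_metrics, load_reference_counts

tables, n = load_reference_counts()
print(f"published cohort: {n} examinations")
print("algorithm  compartment     sens   spec    ppv    npv (%)")
for (algorithm, compartment), table in sorted(tables.items()):
    m = diagnostic_metrics(table).as_percent_strings()
    print(f"{algorithm:10s} {compartment:12s} {m['sensitivity']:>6s} "
          f"{m['specificity']:>6s} {m['ppv']:>6s} {m['npv']:>6s}")

# e.g. threshold/hypoperfused prints 78.0 / 40.2 / 39.5 / 78.6 and
# isp/hypoperfused prints an undefined NPV ("/"): that algorithm never
# produced a negative prediction, so the 0/0 ratio has no value.
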