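"""Parse the packaged DOC cohort table and summarize the diagnosis groups.

The table holds 32 patients with disorders of consciousness: diagnosis
(MCS / UWS), aetiology, demographics and the six CRS-R sub-scores with
their total.  The summary reproduces the standard demographic breakdown
of a clinical cohort report."""

from dynconn import load_reference_cohort, summarize_group

table = load_reference_cohort()
print(f"cohort: {len(table)} patients")
for diag in ("MCS", "UWS"):
    s = summarize_group(table, diagnosis=diag)
    print(f"  {diag}: n={s.n}, {s.n_traumatic} traumatic, {s.n_male} male, "
          f"age {s.age_min}-{s.age_max} (mean {s.mean_age_rounded})")

# Every row's CRS-R total must equal the sum of its six sub-scores.
for rec in table:
    rec.validate_total()
print("all CRS-R totals validate against their sub-score sums")
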