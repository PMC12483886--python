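"""Quality control and normalization of a peak-area / SNR matrix pair.

A measurement is valid when its SNR strictly exceeds 10.  Samples need a
response rate >= 80% (over all compounds) to stay; compounds then need
>= 50% over the retained samples.  The retained table is half-minimum
imputed, log10-transformed, per-sample median-centered and per-compound
z-scaled with parameters learned on a reference (training) subset.
"""

from breathdx import SyntheticConfig, apply_qc, generate_cohort, normalize

peaks, snr, sheet, truth = generate_cohort(SyntheticConfig(seed=7))
report, valid = apply_qc(peaks, snr)

print(f"samples   {len(peaks.sample_ids)} -> {len(report.retained_samples)} "
      f"(dropped below 80% response)")
print(f"compounds {len(peaks.compound_ids)} -> {len(report.retained_compounds)} "
      f"(dropped below 50% response)")
print(f"median sample response rate: "
      f"{report.sample_response_rate.median():.3f}")

ref = report.retained_samples[:60]          # pretend these are training samples
norm = normalize(valid, reference_samples=ref)
col = norm.values.iloc[:, 0]
print(f"first compound on reference subset: mean {col.loc[ref].mean():+.2e}, "
      f"sd {col.loc[ref].std(ddof=1):.6f}")
# Mean 0 / sd 1 on the reference subset by construction; other samples are
# mapped with the same learned parameters, so nothing leaks backwards.
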