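"""Generate a synthetic two-cohort NIRS dataset and write it to CSV.

The generator emulates the study design: a laboratory colony sampled at
2, 5, 8, 12 and 15 days post-emergence and a field-derived cohort at
1, 7 and 14 days, scanned on a 350-2498 nm grid at 3 nm resolution.
"""

import nirage as ng

spectra, meta = ng.simulate(ng.default_config(seed=1))
ng.write_spectra(spectra, "spectra.csv", meta, "metadata.csv")

print(f"samples:  {spectra.n_samples} ({(meta.df.cohort == 'lab').sum()} lab, "
      f"{(meta.df.cohort == 'field').sum()} field)")
print(f"channels: {spectra.n_channels} "
      f"({spectra.wavelengths_nm[0]:.0f}-{spectra.wavelengths_nm[-1]:.0f} nm)")
print(meta.df.groupby(['cohort', 'age_days']).size())
print("Wrote spectra.csv / metadata.csv — absorbance spectra, one column "
      "per mosquito, plus per-sample age, cohort and group labels.")
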