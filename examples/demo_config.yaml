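# Demo: synthetic registry of 50,000 raw beneficiary records with the default
# contamination shares, classified with the 2018 minimum/maximum benefits and
# analysed over the three standard periods.
seed: 20050101
simulate:
  n_records: 50000
  seed: 20050101
thresholds:
  2018: {min_eur: 657.60, max_eur: 2617.53}
periods:
  - {label: P1, start_year: 2005, end_year: 2010}
  - {label: P2, start_year: 2011, end_year: 2014}
  - {label: P3, start_year: 2015, end_year: 2018}
graduation:
  knot_spacing: 2.0
  degree: 3
  penalty_order: 2
output_dir: pensiongap_out
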