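age_band,sex,education_band,daily_earnings
25-34,female,secondary,205.60
25-34,female,certificate,236.80
25-34,female,bachelor_or_higher,302.40
25-34,male,secondary,238.40
25-34,male,certificate,272.00
25-34,male,bachelor_or_higher,324.80
35-44,female,secondary,228.80
35-44,female,certificate,269.20
35-44,female,bachelor_or_higher,356.00
35-44,male,secondary,266.40
35-44,male,certificate,311.20
35-44,male,bachelor_or_higher,412.80
45-54,female,secondary,224.00
45-54,female,certificate,262.40
45-54,female,bachelor_or_higher,348.00
45-54,male,secondary,261.60
45-54,male,certificate,304.00
45-54,male,bachelor_or_higher,401.60
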