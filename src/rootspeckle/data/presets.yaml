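# Calibration presets for the synthetic growth model.
#
# mu / sigma_total are the target pooled mean and standard deviation of the
# normalized root elongation rate in nm s^-1 mm^-1; period_s is the dominant
# oscillation period; osc_fraction is the fraction of total variance carried
# by the oscillation (the rest is white noise).
presets:
  wet:
    label: wet
    mu: -0.10
    sigma_total: 3.41
    period_s: 10.0
    osc_fraction: 0.5
  dry:
    label: dry
    mu: -23.44
    sigma_total: 52.63
    period_s: 10.0
    osc_fraction: 0.5
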