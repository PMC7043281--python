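term
abnormal
low
below average
reactive
high
elevated
above average
positive
detected
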