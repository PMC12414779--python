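# Bone-marrow default simulation profile.
matrix = "BM"
dead_fraction = 0.08
background_dp_rate = 1.3e-4

[[populations]]
name = "lymphocyte"
fraction = 0.15
location = [2.60, 2.00, 0.50, 0.50, 0.40]
spread = [0.08, 0.10, 0.30, 0.30, 0.25]

[[populations]]
name = "monocyte"
fraction = 0.05
location = [2.90, 2.40, 0.80, 0.60, 0.40]
spread = [0.08, 0.12, 0.30, 0.30, 0.25]

[[populations]]
name = "granulocyte"
fraction = 0.38
location = [2.80, 2.90, 0.70, 0.50, 0.40]
spread = [0.10, 0.12, 0.30, 0.30, 0.25]

[[populations]]
name = "precursor"
fraction = 0.32
location = [2.70, 2.50, 0.60, 0.90, 0.40]
spread = [0.12, 0.15, 0.35, 0.35, 0.25]

[[populations]]
name = "debris"
fraction = 0.10
location = [1.50, 1.30, 0.30, 0.30, 0.40]
spread = [0.15, 0.15, 0.30, 0.30, 0.25]
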