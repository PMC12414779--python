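# Peripheral-blood default simulation profile (post-lysis suspension).
# Channel order: fsc, ssc, fl1_ige, fl2_cd117, fl3_7aad; location/spread in log10 units.
matrix = "PB"
dead_fraction = 0.03
background_dp_rate = 5e-5

[[populations]]
name = "lymphocyte"
fraction = 0.25
location = [2.60, 2.00, 0.50, 0.50, 0.40]
spread = [0.08, 0.10, 0.30, 0.30, 0.25]

[[populations]]
name = "monocyte"
fraction = 0.05
location = [2.90, 2.40, 0.80, 0.60, 0.40]
spread = [0.08, 0.12, 0.30, 0.30, 0.25]

[[populations]]
name = "granulocyte"
fraction = 0.60
location = [2.80, 2.90, 0.70, 0.50, 0.40]
spread = [0.10, 0.12, 0.30, 0.30, 0.25]

[[populations]]
name = "debris"
fraction = 0.10
location = [1.50, 1.30, 0.30, 0.30, 0.40]
spread = [0.15, 0.15, 0.30, 0.30, 0.25]
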