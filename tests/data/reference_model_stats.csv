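model,set,n,r2,f
general-noael,active_training,140,0.51,142
general-noael,passive_training,140,0.51,142
general-noael,calibration,140,0.56,174
general-noael,validation,141,0.55,172
general-loael,active_training,142,0.55,173
general-loael,passive_training,142,0.55,168
general-loael,calibration,137,0.51,138
general-loael,validation,137,0.53,149
kidney-noael,active_training,95,0.50,94
kidney-noael,passive_training,95,0.52,103
kidney-noael,calibration,45,0.62,70
kidney-noael,validation,45,0.59,62
kidney-loael,active_training,97,0.51,99
kidney-loael,passive_training,102,0.59,143
kidney-loael,calibration,46,0.67,88
kidney-loael,validation,38,0.69,80
brain-noael,active_training,23,0.55,26
brain-noael,passive_training,22,0.61,31
brain-noael,calibration,23,0.58,28
brain-noael,validation,22,0.53,23
brain-loael,active_training,22,0.54,23
brain-loael,passive_training,23,0.69,48
brain-loael,calibration,22,0.66,39
brain-loael,validation,23,0.69,46
liver-noael,active_training,97,0.76,297
liver-noael,passive_training,94,0.73,247
liver-noael,calibration,30,0.78,103
liver-noael,validation,31,0.55,35
liver-loael,active_training,96,0.78,326
liver-loael,passive_training,95,0.78,323
liver-loael,calibration,30,0.76,89
liver-loael,validation,31,0.61,46
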