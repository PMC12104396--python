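name,molecular_weight,cmax_ug_per_ml,fu_plasma,fu_incubation,cmax_source
Omeprazole,345.42,1.12,0.01,0.02,label
Lansoprazole,369.36,1.15,0.01,0.02,label
Pantoprazole,383.37,2.50,0.01,0.02,label
Rabeprazole,359.44,0.62,0.01,0.02,label
Ilaprazole,366.44,0.45,0.01,0.02,back_derived
Ticlopidine,263.78,0.0,0.01,0.02,positive_control
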