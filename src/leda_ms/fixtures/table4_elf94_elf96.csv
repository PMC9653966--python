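transition_label,isomer_id,ratio,sd
392/604,ELF94,0.01,0.01
392/604,ELF96,0.32,0.01
366/604,ELF94,0.18,0.01
366/604,ELF96,0.01,0.01
279/604,ELF94,0.08,0.01
279/604,ELF96,0.01,0.01
253/604,ELF94,0.01,0.01
253/604,ELF96,0.18,0.01
221/604,ELF94,1.10,0.06
221/604,ELF96,0.44,0.03
195/604,ELF94,0.04,0.01
195/604,ELF96,0.70,0.02
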