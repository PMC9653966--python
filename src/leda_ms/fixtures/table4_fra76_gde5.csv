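transition_label,isomer_id,ratio,sd
378/590,FRA76,0.01,0.01
378/590,GDE5,0.26,0.01
352/590,FRA76,0.20,0.01
352/590,GDE5,0.04,0.01
279/590,FRA76,0.11,0.01
279/590,GDE5,0.01,0.01
253/590,FRA76,0.01,0.01
253/590,GDE5,0.21,0.01
221/590,FRA76,1.30,0.02
221/590,GDE5,0.60,0.01
195/590,FRA76,0.09,0.01
195/590,GDE5,0.64,0.03
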