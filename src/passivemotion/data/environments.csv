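name,gravity_m_s2
Earth,9.81
Mars,3.71
Europa,1.315
Enceladus,0.113
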