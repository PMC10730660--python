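c.1400C>G
c.760C>T
c.51C>G
c.797C>T
c.338G>A
c.1195C>T
c.497+1G>T
c.865C>T
c.696C>T
c.844C>T
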