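# Animal hemoglobin-subunit symbols mapped onto the annotated human
# beta-family hemoglobin genes HBB/HBD.  The two human genes carry the same
# annotation, so the choice of canonical target does not affect any count.
alias	canonical
Hba1	HBB
Hbad	HBB
Hbbl	HBB
Hbm	HBD
Hbz1	HBD
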