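(Camelus_bactrianus,Sus_scrofa,((Moschiola_indica,(Tragulus_kanchil,Hyemoschus_aquaticus)),(Giraffa_camelopardalis,((Axis_axis,Moschus_chrysogaster),Bos_indicus))));
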