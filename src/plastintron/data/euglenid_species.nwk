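((((Egra,Elon)euglena,Maen)monomorphina_euglena,Evir)photo_core,Egym)root;
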