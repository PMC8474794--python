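symbol	category
Gpc1	core
Vcan	core
Prss23	affiliated
Tnc	core
Mmp3	affiliated
Adam12	affiliated
Col3a1	core
Adamts18	affiliated
Plod2	affiliated
Postn	core
Timp1	affiliated
Angpt2	affiliated
Col4a3	core
Col5a2	core
Sdc4	affiliated
Col18a1	core
Igf1	affiliated
Slit2	core
Adam10	affiliated
Egln1	affiliated
S100a4	affiliated
C1qc	affiliated
Mfap2	core
Tnfref21	affiliated
Clec11a	affiliated
Adamts12	affiliated
Fgf10	affiliated
Fn1	core
Ptn	affiliated
Leprel2	affiliated
Thbs1	core
Tnfrsf1b	affiliated
Mfap5	core
Col13a1	core
Il15ra	affiliated
Adam23	affiliated
Ctsc	affiliated
Mdk	affiliated
Wisp1	core
F10	affiliated
Serpina3g	affiliated
Sema6d	affiliated
Fgf21	affiliated
Wisp2	core
Gas6	core
Cxcl13	affiliated
Sfrp1	core
Podn	core
S100g	affiliated
Igfbp3	core
Ngfr	affiliated
Omd	core
Dhh	affiliated
Figf	affiliated
Bmp8a	affiliated
Plxnb2	affiliated
Spock2	core
Tgfbi	core
Col20a1	core
Fbn1	core
Tnfsf13b	affiliated
Htra3	affiliated
Vtn	core
Ltbp1	core
Col1a1	core
Col1a2	core
Mmp2	affiliated
Mmp9	affiliated
Timp2	affiliated
Lox	affiliated
Lamb1	core
Eln	core
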