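accession	tf_name	targets
M01014	Sox5	Smad5,Smad1,Smad7,Sox6,Sox5,Mir125b2,Mir34a,Mir224,Mir15a,Mir125b1,Lipe,Sry
M01014	SRY	Slc9a3r2,Wt1,Akr1b10,Zfp748,Hdac3,Smad3,Ar,Importin beta,Ep300,Kpnb1,Kpna,Znf208,Sry,Amh,Ptgds
M00699	IRF-8	Spi1,Irf1,Trim21,Cops2,Irf2,Il12b,Il1b,Cybb,B2 m,Cbl,Irf4,Nfatc1,Ttraf6,Stat1,Etv6,beta2-mg,Cdkn2b,Il-12 p40,H-2Dd,H-2Kb,H-2Ld
M01014	Sox13	Smad7,Fgf3
M01014	Sox4	Mir199a1,Mir27b,Mir199a2,Mir206,Mir29c,Mir107,Mir34a,Mir95,Mir17,Mir199b,Mirn292,Mirn101b,Cebpa,Sdcbp,Tcf4
M01014	Sox2	Pou5f1,Pou2f1,Pax6,Lbx1,Pdx1,Meis1,Asc,Golga6,Nkx2-3,Otp,Dlx5,Otx1,Dlx4,Isl1,Zfhx3,Fbxo15,Fgf4,Hrc,Nanog,Spp1,Zscan10
M01014	Sox9	Ep300,Nr5a1,Kpnb1,Crebbp,Smad3,Smad2,Amh,Mia,Med12,Maf,Importin beta,Calmodulin,Ppargc1a,Ncadherin,Col2a1
M01014	Sox15	Fhl3,Pou5f1
M00233	Mef-2	Smarca4,Hdac4,Hdac9,Hdac7,Hdac5,Nfat,Mapk14,Thra,Ep300,Ckm,Myog,Mef2 d,Jun,Slc2a4,Srf,Mck
M00062	IRF-1	Agtr2,C2ta,Nos2,H-2kb,Ptgs2,Tlr3,H2-Dd,IL-12,IL-7R,Stat1,Ciita,Nfkb1,Rela,Stat5,Tap1,Vcam1,Psmb9,Ifnb1,Stat3,Irf8,Crebbp,Smarca4,Cybb
M01014	Sox6	Cenpk,Sox5,Dazap2,Hdac1,Ctnnb1,Pdx1,Ctbp2,Mir29a,Mir221,Mir222,Mir29c,Mir126,Ccnd1,Fgf3,Hbb-y
M01014	Sox18	Mef2c,Vcam1
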