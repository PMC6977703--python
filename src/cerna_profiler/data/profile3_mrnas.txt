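AABR07005593.1
Ccdc184
Hist3h3
Mms22l
Slc17a7
AABR07013843.1
Ccdc33
Hrct1
Myb
Slc28a3
AABR07016578.1
Ccdc74a
Hs3st5
Mypn
Slc29a1
AABR07016845.1
Cd164l2
Hsd17b3
Nr2e3
Slc6a12
AABR07018064.1
Cep55
Il2rb
Otx1
Smoc2
AABR07027811.4
Cfap44
Ildr2
Oxtr
Spag8
AABR07048271.1
Cldn15
Itgb4
Pcbd1
Spata18
AC096809.1
Cpne4
Kcnh2
Pcdh12
Spats1
AC097129.1
Cxcr5
Kcnk12
Pla2g2c
Spred3
AC123253.2
Dlec1
Kcnk4
Plagl1
Sprn
Adamts18
Dlx2
Kcp
Plch1
Srrm4
Adgb
Dnai1
Kif2c
Plekha7
Synpo2l
Adra2a
E2f1
Klhdc7a
Prlhr
T2
Akr1b8
Etv5
Lhb
Prss56
Tcte1
Anxa8
Fam64a
LOC100361018
Ptger3
Tgm2
Apcdd1l
Fbxo47
LOC499781
Rab38
Tmem37
Arl5c
Ggnbp1
LOC502684
Reep6
Tox2
Armc3
Glis1
LOC684762
RGD1562029
Trpv2
Atp2a3
Gsto2
LOC686662
Rgs6
Tsnaxip1
Bard1
Hcrt
LOC688553
Rnf182
Tspo
Barhl1
Hes1
Lrfn1
Rspo3
Ttc16
Batf
Hes7
Lrp2
Rxfp2
Ttll6
Bdnf
Hist1h2ac
Lrrc36
Scd4
Vsx1
Bub1b
Hist1h2ac
Map3k19
Sec14l4
Vwa3b
Capsl
Hist1h2ao
Mfsd4
Sfrp2
Vwa5b1
Cbln2
Hist1h2bl
MGC116202
Shc3
Xkr7
Ccdc108
Hist1h2bo
Mmp14
Sidt1
Zic5
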