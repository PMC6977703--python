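NONRATT000216.2
NONRATT009993.2
NONRATT024024.2
NONRATT001131.2
NONRATT011596.2
NONRATT024046.2
NONRATT001180.2
NONRATT012417.2
NONRATT024214.2
NONRATT001358.2
NONRATT012674.2
NONRATT024557.2
NONRATT001421.2
NONRATT012936.2
NONRATT024630.2
NONRATT002729.2
NONRATT013263.2
NONRATT025429.2
NONRATT003319.2
NONRATT014106.2
NONRATT025956.2
NONRATT004126.2
NONRATT014204.2
NONRATT026386.2
NONRATT004376.2
NONRATT014224.2
NONRATT026498.2
NONRATT004419.2
NONRATT014766.2
NONRATT026518.2
NONRATT004747.2
NONRATT014929.2
NONRATT027617.2
NONRATT005391.2
NONRATT015102.2
NONRATT027997.2
NONRATT005891.2
NONRATT017193.2
NONRATT028621.2
NONRATT005964.2
NONRATT017209.2
NONRATT029228.2
NONRATT006053.2
NONRATT017794.2
NONRATT030267.2
NONRATT006238.2
NONRATT017951.2
ENSRNOT00000087777
NONRATT006431.2
NONRATT018250.2
MSTRG.15278.3
NONRATT007085.2
NONRATT018531.2
MSTRG.16299.3
NONRATT007290.2
NONRATT018736.2
MSTRG.17073.1
NONRATT007459.2
NONRATT019793.2
MSTRG.23728.9
NONRATT007516.2
NONRATT020448.2
MSTRG.23943.1
NONRATT007517.2
NONRATT020991.2
MSTRG.26499.20
NONRATT007641.2
NONRATT021380.2
MSTRG.38968.2
NONRATT007657.2
NONRATT021598.2
MSTRG.39805.1
NONRATT009240.2
NONRATT022815.2
MSTRG.40651.2
NONRATT009407.2
NONRATT023402.2
NONRATT009800.2
NONRATT023886.2
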