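pop_a,pop_b,weight
Kodi,Loli,0.01113
Kodi,Lamboya,0.02481
Lamboya,Loli,0.06764
Lamboya,Wanokaka,0.01297
Loli,Wanokaka,0.06614
Loli,Anakalang,0.0461
Wanokaka,Anakalang,0.0098
Wanokaka,Rindi,0.00572
Anakalang,Rindi,0.01157
Wunga,Rindi,0.02015
Anakalang,Wunga,0.04181
Mamboro,Wunga,0.06872
Mamboro,Anakalang,0.03533
Loli,Mamboro,0.04736
Kodi,Mamboro,0.01528
Kodi,Wunga,0.03312
Kodi,Rindi,0.00891
Lamboya,Rindi,0.00536
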