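pop_a,pop_b,label,theta_printed
Kodi,Loli,1,0.7624459
Kodi,Lamboya,2,1.943735
Lamboya,Loli,3,1.875696
Lamboya,Wanokaka,4,2.187413
Loli,Wanokaka,5,1.400967
Loli,Anakalang,6,1.189525
Wanokaka,Anakalang,7,1.681032
Wanokaka,Rindi,8,1.013773
Anakalang,Rindi,9,0.1476047
Wunga,Rindi,10,2.743607
Anakalang,Wunga,11,1.337191
Mamboro,Wunga,12,2.014021
Mamboro,Anakalang,13,1.927833
Loli,Mamboro,14,1.054552
Kodi,Mamboro,15,1.286779
Kodi,Wunga,16,0.1883666
Kodi,Rindi,17,2.101859
Lamboya,Rindi,18,0.2763413
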