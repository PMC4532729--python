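name,longitude_deg,latitude_deg
Kodi,118.960,-9.583
Lamboya,119.355,-9.722
Loli,119.398,-9.633
Wanokaka,119.449,-9.725
Mamboro,119.545,-9.401
Anakalang,119.575,-9.588
Wunga,119.958,-9.385
Rindi,120.675,-9.931
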