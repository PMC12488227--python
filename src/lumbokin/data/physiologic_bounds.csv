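family,pair_group,quantity,lower,upper
AR,spinal,rom_total,0,150
AR,hip,rom_total,0,80
LB,spinal,rom_total,0,120
LB,hip,rom_total,0,80
FE,spinal,rom_total,0,170
FE,hip,rom_total,0,160
SAG,spinal,rom_mean,0,120
SAG,hip,rom_mean,0,140
AR,spinal,vel_mean,0,500
AR,hip,vel_mean,0,400
LB,spinal,vel_mean,0,500
LB,hip,vel_mean,0,400
FE,spinal,vel_mean,0,500
FE,hip,vel_mean,0,500
SAG,spinal,vel_mean,0,500
SAG,hip,vel_mean,0,500
AR,spinal,acc_mean,0,4000
AR,hip,acc_mean,0,4000
LB,spinal,acc_mean,0,4000
LB,hip,acc_mean,0,4000
FE,spinal,acc_mean,0,4000
FE,hip,acc_mean,0,4000
SAG,spinal,acc_mean,0,4000
SAG,hip,acc_mean,0,4000
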