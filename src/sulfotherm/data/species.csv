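name,formula,z,phase,G_f_J,H_f_J,S_J_K,a1,a2,a3,a4,c1,c2,omega,a_ring,mk_a,mk_b,mk_c,source
H+,H+,1,aqueous,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,9.0,,,,SUPCRT/slop-lineage compilation
OH-,OH-,-1,aqueous,-157297.48,-230023.768,-10.711,0.52413,30.878,7.7082,-116403.1,17.3636,-432876.6,721572.6,3.5,,,,SUPCRT/slop-lineage compilation
H2S,H2S,0,aqueous,-27919.832,-37660.184,125.52,2.723658,2833.572,24.9559,-127988.6,135.1432,197903.2,-41840.0,0.0,,,,SUPCRT/slop-lineage compilation
HS-,HS-,-1,aqueous,11966.24,-16108.4,68.1992,2.096979,2083.59,14.5457,-124888.2,14.3093,-262336.8,602914.4,3.5,,,,SUPCRT/slop-lineage compilation
SO4-2,SO4-2,-2,aqueous,-744459.12,-909601.6,18.828,3.473306,-830.357,-25.9918,-112842.5,6.8618,-753036.3,1316411.9,4.0,,,,SUPCRT/slop-lineage compilation
HSO4-,HSO4-,-1,aqueous,-755755.92,-889100.0,125.52,2.91993,-11.464,29.8487,-116122.7,83.68,-81588.0,491536.3,4.5,,,,SUPCRT/slop-lineage compilation
NH4+,NH4+,1,aqueous,-79454.16,-133260.4,111.1689,0.0,0.0,0.0,0.0,67.6553,-12552.0,66107.2,2.5,,,,SUPCRT/slop-lineage compilation
NH3,NH3,0,aqueous,-26706.472,-81336.96,107.8217,0.0,0.0,0.0,0.0,73.0108,0.0,-20920.0,0.0,,,,SUPCRT/slop-lineage compilation
N2,N2,0,aqueous,18187.848,-10439.08,94.0982,0.0,0.0,0.0,0.0,167.36,251040.0,-70249.4,0.0,,,,SUPCRT/slop-lineage compilation
NO2-,NO2-,-1,aqueous,-32216.8,-104600.0,123.0096,0.0,0.0,0.0,0.0,41.84,-167360.0,495678.5,3.0,,,,SUPCRT/slop-lineage compilation
NO3-,NO3-,-1,aqueous,-110905.288,-206810.936,146.9421,0.0,0.0,0.0,0.0,32.2168,-281374.0,459277.7,3.0,,,,SUPCRT/slop-lineage compilation
Na+,Na+,1,aqueous,-261880.744,-240299.672,58.4086,0.769438,-956.044,13.6231,-114055.8,76.0651,-124725.0,138323.0,4.0,,,,SUPCRT/slop-lineage compilation
K+,K+,1,aqueous,-282461.84,-252169.68,101.0436,1.489086,-616.303,22.74,-113470.1,30.9616,-74935.4,80625.7,3.0,,,,SUPCRT/slop-lineage compilation
Mg+2,Mg+2,2,aqueous,-453984.92,-465959.528,-138.072,-0.343799,-3597.822,35.1038,-99997.6,87.0272,-246521.3,643164.5,8.0,,,,SUPCRT/slop-lineage compilation
Ca+2,Ca+2,2,aqueous,-552790.08,-543083.2,-56.484,-0.081462,-3034.237,22.161,-103729.7,37.656,-105520.5,517393.4,6.0,,,,SUPCRT/slop-lineage compilation
Cl-,Cl-,-1,aqueous,-131289.736,-167079.672,56.735,1.686989,2008.738,23.2756,-119118.5,-18.4096,-239073.8,609190.4,3.0,,,,SUPCRT/slop-lineage compilation
HCO3-,HCO3-,-1,aqueous,-586939.888,-689933.232,98.4495,3.163983,481.369,5.1656,-118264.9,54.141,-199074.7,532748.7,4.5,,,,SUPCRT/slop-lineage compilation
CO2,CO2,0,aqueous,-385974.0,-413797.6,117.5704,2.613577,3125.908,11.7721,-129197.7,167.4855,368192.0,-8368.0,0.0,,,,SUPCRT/slop-lineage compilation
S0,S,0,crystalline,0.0,0.0,31.7984,,,,,,,,,14.9787,0.02610816,0.0,SUPCRT/slop-lineage compilation
H2O,H2O,0,liquid-water,-237182.592,-285838.328,69.923,,,,,,,,,75.3497,0.0,0.0,SUPCRT/slop-lineage compilation
H2S(g),H2S,0,gas,-33438.528,-20631.304,205.811,,,,,,,,,32.677,0.01238464,-192464.0,SUPCRT/slop-lineage compilation
N2(g),N2,0,gas,0.0,0.0,191.5017,,,,,,,,,28.5767,0.0037656,-50208.0,SUPCRT/slop-lineage compilation
CO2(g),CO2,0,gas,-394358.736,-393509.384,213.8024,,,,,,,,,44.2249,0.0087864,-861904.0,SUPCRT/slop-lineage compilation
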