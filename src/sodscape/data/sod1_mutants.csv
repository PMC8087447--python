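mutant,d_zn_A,d_cu_A,dG_kcal_mol
A4V,19.6,19.3,-1.6
C6A,17,15.7,-2.1
G37R,23.7,17.2,-1.0
L38V,22.2,13.6,-1.2
H43R,17.8,9.9,-1.0
H46R,7.8,10.2,-2.3
H80R,4.2,10.3,-2.3
G85R,8.6,8.4,-2.0
G93A,20.5,22.7,-1.8
C111A,11.9,18.3,-3.3
C112S,19.7,17.6,-1.3
I113T,16,18.5,-3.2
D124V,9,13,-2.1
H72F,2.9,8.2,-3.1
H121F,14.4,5.6,-1.9
S134N,9.6,10.9,-1.6
C147S,16.3,10.3,-1.7
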