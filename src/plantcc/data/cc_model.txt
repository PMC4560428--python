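# Logical rules of the A. thaliana cell-cycle Boolean model
targets, factors
CYCD3;1, !SCF
CYCB1;1, (MYB3R1/4 & !E2Fc & !APC/C) | (E2Fb & MYB77 & MYB3R1/4 & !E2Fc) | (E2Fb & MYB77 & MYB3R1/4 & !KRP1) | (E2Fb & MYB77 & !RBR & !APC/C) | (E2Fb & MYB77 & !RBR & !KRP1) | (E2Fb & MYB3R1/4 & !RBR & !APC/C) | (E2Fb & MYB3R1/4 & !RBR & !KRP1) | (MYB77 & MYB3R1/4 & !RBR & !E2Fc) | (MYB77 & MYB3R1/4 & !RBR & !APC/C) | (MYB77 & MYB3R1/4 & !E2Fc & !KRP1) | (MYB77 & MYB3R1/4 & !APC/C & !KRP1) | (MYB77 & !RBR & !E2Fc & !APC/C) | (MYB3R1/4 & !RBR & !E2Fc & !KRP1)
CYCA2;3, (MYB77 & MYB3R1/4) | (MYB77 & !APC/C) | (MYB3R1/4 & !APC/C)
CDKB1;1, (E2Fb & !RBR) | (E2Fb & !E2Fc) | (MYB77 & !RBR) | (MYB77 & !E2Fc) | (E2Fb & MYB77 & MYB3R1/4)
KRP1, (MYB77 & !CYCA2;3) | (MYB77 & MYB3R1/4 & !SCF) | (MYB77 & MYB3R1/4 & !CDKB1;1) | (MYB3R1/4 & !SCF & !CDKB1;1) | (MYB3R1/4 & !CDKB1;1 & !CYCA2;3)
RBR, KRP1 | (E2Fa & MYB3R1/4) | (E2Fa & !CYCD3;1) | (MYB3R1/4 & !CYCD3;1)
E2Fa, (!E2Fc & !CDKB1;1 & !CYCA2;3) | (!E2Fc & !CDKB1;1 & !RBR) | (!E2Fc & !CYCA2;3 & !RBR)
E2Fb, E2Fa & !RBR
E2Fc, (E2Fa & MYB3R1/4 & !CYCD3;1) | (E2Fa & MYB3R1/4 & !SCF) | (MYB3R1/4 & KRP1 & !SCF) | (E2Fa & !RBR & !SCF) | (MYB3R1/4 & !CYCD3;1 & !SCF) | (KRP1 & !RBR & !SCF) | (E2Fa & KRP1 & !CYCD3;1 & !SCF)
E2Fe, (E2Fb & MYB77) | (E2Fb & !RBR) | (MYB77 & !RBR) | (!RBR & !E2Fc)
MYB77, E2Fb & !RBR
MYB3R1/4, MYB77 | (MYB3R1/4 & !KRP1)
SCF, (E2Fb & !RBR) | (MYB3R1/4 & !APC/C)
APC/C, (MYB3R1/4 & !E2Fe) | (E2Fa & MYB77 & !RBR)
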