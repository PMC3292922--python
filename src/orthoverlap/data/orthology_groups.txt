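# Curated orthology groups linking worm (cel), yeast (sce), fly (dme) and human (hsa)
# members for the overlapping regulators. One group per line, OrthoMCL groups dialect.
GRP01: cel|Y53C10A.12 hsa|HSF1
GRP02: cel|F26D10.3 dme|CG4264 hsa|HSPA8
GRP03: cel|F54D5.8 dme|CG8863 hsa|DNAJB5
GRP04: cel|K01C8.10 hsa|CCT4
GRP05: cel|C07G2.3 hsa|CCT5
GRP06: cel|T09B4.10 dme|CG5203 hsa|STUB1
GRP07: cel|Y94H6A.6 dme|CG2257 sce|UBC8 hsa|UBE2H
GRP08: cel|M7.1 dme|CG5788 hsa|UBE2D2
GRP09: cel|C06A1.1 hsa|VCP
GRP10: cel|F52D10.3 cel|M117.2 dme|CG31196 hsa|YWHAE
GRP11: cel|C39F7.4 sce|YPT1 dme|CG3320 hsa|RAB1A
GRP12: cel|B0361.10 sce|YKT6 hsa|YKT6
GRP13: cel|C54H2.5 sce|ERV29 hsa|SURF4
GRP14: cel|Y54E2A.12 sce|GYP8 hsa|TBC1D20
GRP15: cel|R11A8.4 dme|CG5216 hsa|SIRT1
GRP16: cel|C53A5.3 dme|CG7471 hsa|HDAC1
GRP17: cel|F02E9.4 dme|CG8815 hsa|SIN3B
GRP18: cel|C48B4.1 cel|F08A8.1 cel|F08A8.2 cel|F08A8.3 cel|F08A8.4 cel|F25C8.1 cel|F59F4.1 sce|POX1 dme|CG5009 hsa|ACOX1
GRP19: cel|ZK256.1 sce|PMR1 hsa|ATP2C1
GRP20: cel|W08D2.5 sce|YPK9 hsa|ATP13A2
GRP21: cel|Y43F4B.4 dme|CG8722 hsa|SEH1L
GRP22: cel|F49E10.5 dme|CG7583 hsa|CTBP1
GRP23: cel|K08F8.6 dme|CG42614 hsa|MED13
GRP24: cel|T17E9.1 dme|CG14217 hsa|TAOK1
GRP25: cel|H18N23.2 dme|CG9238 hsa|PPP1R3C
GRP26: cel|T14F9.1 hsa|ATP6V1H
GRP27: cel|T21E12.4 dme|CG7507 hsa|DYNC1H1
GRP28: cel|Y113G7B.18 hsa|MED17
GRP29: cel|Y116A8C.35 hsa|U2AF1
GRP30: cel|F56C11.1 hsa|DUOX1
GRP31: cel|C32E8.10 sce|YAP1802 hsa|PICALM
GRP32: cel|JC8.10 sce|INP52 hsa|SYNJ1
GRP33: cel|ZK742.1 dme|CG13387 sce|CRM1 hsa|XPO1
GRP34: cel|C05C8.7 hsa|MPI
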