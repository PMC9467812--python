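descriptor,importance
Smax11,0.00065
MATSp7,0.00065
CIC4,0.000652
MDEC-14,0.000656
S17,0.000659
minHCsats,0.00066
Smin34,0.000661
SHaaCH,0.000664
SIC3,0.000664
SHCsats,0.000681
Smin,0.000681
CrippenLogP,0.000682
maxsOH,0.000684
ATSc1,0.000684
bcutm13,0.000684
phi,0.000686
MATSm3,0.000688
CIC3,0.000688
VSAEstate7,0.000691
SPC-4,0.000695
EstateVSA7,0.000702
Smin8,0.000704
WTPT-5,0.000706
TPSA1,0.000708
naccr,0.00071
MATSm7,0.000712
maxdsN,0.000712
CIC1,0.000713
Smin35,0.000714
ATSe5,0.000716
minHCsatu,0.000725
GATSp3,0.000726
GATSm5,0.000727
ALogp2,0.000729
GATSp7,0.00073
EstateVSA1,0.000737
IDE,0.000741
mindO,0.000744
mChi1,0.000745
SaasC,0.00076
bcute9,0.000761
nAtomLAC,0.000762
maxdssC,0.000771
GATSe7,0.000775
Smax,0.000781
ETA_Epsilon_1,0.000787
MATSv5,0.000789
bcutp5,0.000793
IC1,0.000796
maxHBint7,0.000797
QCss,0.000823
CIC6,0.000823
ALogP,0.000826
bcutm3,0.00083
SsOH,0.000847
BertzCT,0.000851
EstateVSA4,0.000851
SdssC,0.000855
bcutm2,0.000866
MAXDN,0.000868
PC6,0.000872
MATSm6,0.000891
SHBint5,0.000897
SaaCH,0.0009
MATSp5,0.000901
MRVSA6,0.000904
slogPVSA1,0.000904
MATSm5,0.000922
bcute12,0.000926
J,0.000927
GATSm4,0.000927
MRVSA5,0.000933
MATSm1,0.000934
GATSm8,0.000939
Smin12,0.000946
hmin,0.00095
VC-4,0.000962
MATSe5,0.000963
MATSp4,0.000964
PEOEVSA5,0.000967
minHBd,0.000971
GATSv3,0.000974
bcutm9,0.000979
PEOEVSA8,0.00098
ECCEN,0.000987
MATSm8,0.000988
IC2,0.000995
BCUTp-1l,0.001004
minssCH2,0.001017
QHss,0.001019
Smax16,0.00102
bcutm12,0.001026
ETA_EtaP_F,0.001026
ETA_dEpsilon_D,0.001038
bcute4,0.001038
WTPT-3,0.001042
MAXDP2,0.001042
knotpv,0.001043
MDEO-11,0.001043
maxHCsats,0.00105
Chiv5ch,0.001063
GATSe5,0.001072
VPC-5,0.001081
MATSv8,0.00109
maxsF,0.001096
QNmin,0.001109
ETA_BetaP_s,0.001109
Chiv6ch,0.00111
IC3,0.001117
VPC-6,0.001119
VSAEstate2,0.001121
MATSp3,0.001137
slogPVSA2,0.00114
WTPT-4,0.001162
gmin,0.001163
minHBint6,0.001176
minHBint7,0.001195
Smax24,0.001225
MATSp6,0.001229
PEOEVSA1,0.001234
SIC2,0.001237
S34,0.001257
bcute1,0.001278
MATSv3,0.001281
SC-5,0.001283
dchi0,0.00129
SIC1,0.001291
maxHBd,0.001307
PEOEVSA7,0.001342
MDEC-24,0.001345
SCH-7,0.001347
SHBd,0.001349
MATSe8,0.001375
MATSv1,0.001375
SHCsatu,0.001386
Smin15,0.001398
BCUTp-1h,0.00141
GATSm3,0.001461
bcutp12,0.001465
MLFER_BH,0.001485
GATSv1,0.001559
QOmax,0.001589
slogPVSA0,0.001592
bcute10,0.001605
Smin24,0.001609
MATSp1,0.001616
Chiv3,0.001662
QNmax,0.001663
bcutv4,0.00168
VCH-5,0.001717
VSAEstate4,0.001785
ATSc5,0.001813
C3SP2,0.001831
mindssC,0.001846
ATSc2,0.001859
minHBint10,0.001866
ATSc3,0.001892
MDEC-22,0.001909
MAXDP,0.001935
knotp,0.001942
GATSm1,0.002
GATSp4,0.002026
maxsssCH,0.002031
S25,0.002032
bcutp1,0.002049
ETA_Shape_Y,0.002124
bcutp9,0.002186
XLogP,0.002237
ATSc4,0.002298
maxHBint5,0.002321
maxHBint8,0.002379
minsOH,0.002424
GATSm2,0.002443
SPC-6,0.00248
MATSe3,0.002549
MLFER_S,0.002597
SHBint6,0.002733
ndssC,0.002743
bcutv1,0.002787
VCH-7,0.002879
BCUTc-1l,0.002923
QCmax,0.00298
Scar,0.003191
minssO,0.003312
BCUTc-1h,0.003494
MLFER_A,0.003711
TopoPSA,0.003768
MDEO-12,0.003868
minHBa,0.004054
Smin33,0.004253
SHsOH,0.004402
GATSe8,0.004485
PEOEVSA6,0.00461
Mnc,0.004826
MATSe1,0.004978
LDI,0.005205
MDEC-33,0.005471
GATSe1,0.005843
bcute2,0.005866
VC-5,0.006197
nC,0.0064
nHBAcc,0.006408
LogP2,0.006781
SHBint10,0.006873
Hy,0.007517
kappam3,0.007695
VSAEstate1,0.007799
QNss,0.009891
minsssN,0.01014
LogP,0.011371
maxssO,0.011647
ATSp4.1,0.013044
QHmax,0.014923
C1SP2,0.01631
minHBint5,0.017225
ATSv5,0.017404
Smax35,0.018515
minHsOH,0.025883
maxHsOH,0.028849
LipoaffinityIndex,0.031403
QOmin,0.041317
Qmin,0.043254
MDEC-23,0.049635
ATSp5.1,0.143226
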