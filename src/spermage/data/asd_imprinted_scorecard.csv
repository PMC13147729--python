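gene,chr,probe_id,icr,co,multi_cpg,top90,ma,op,is_island,pr,score
MAGEL2,15,cg10073842,1,0,1,1,1,0,0,1,5
DLGAP2,8,cg03439898,1,1,1,0,0,0,1,0,4
GNAS,20,cg21809160,1,0,1,0,1,0,1,0,4
B4GALNT4,11,cg10798664,1,0,1,0,0,0,0,1,3
GRB10,7,cg27006764,1,0,0,0,0,0,1,1,3
KCNQ1,11,cg03371125,1,0,1,0,0,0,0,1,3
KCNQ1OT1,11,cg03654058,1,0,1,0,0,0,0,1,3
OTX1,2,cg10487970,0,0,0,0,0,1,1,1,3
PLAGL1,6,cg21113768,1,0,1,0,0,0,0,1,3
PTPRN2,7,cg04937416,1,0,1,0,0,0,1,0,3
PRDM16,1,cg10588310,0,0,1,0,0,1,1,0,3
CDH24,14,cg03156547,1,0,1,0,0,1,0,0,3
SLC26A10,12,cg08177625,0,0,1,0,0,1,0,1,3
ATP10A,15,cg06066676,0,0,1,0,0,0,0,1,2
FBRSL1,12,cg19100996,1,0,0,0,0,1,0,0,2
HOXB3,17,cg10585948,0,0,1,0,0,0,0,1,2
ANO1,11,cg11058904,0,0,0,0,1,0,0,0,1
C6orf145,6,cg18815879,0,0,0,0,0,0,0,1,1
FOXG1,14,cg18299578,0,0,0,0,0,0,0,1,1
GLIS3,9,cg13804450,0,0,1,0,0,0,0,0,1
LMX1B,9,cg13466694,0,0,1,0,0,0,0,0,1
MAGI2,7,cg00110846,0,0,1,0,0,0,0,0,1
NTM,11,cg12079699,0,0,1,0,0,0,0,0,1
OBSCN,1,cg18477163,0,0,0,0,0,0,1,0,1
UBE3A,15,cg12060334,0,0,1,0,0,0,0,0,1
ADAMTS16,5,cg26892415,0,0,0,0,0,0,0,0,0
DDC,7,cg15001032,0,0,0,0,0,0,0,0,0
RNU5D,5,cg19107296,0,0,0,0,0,0,0,0,0
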