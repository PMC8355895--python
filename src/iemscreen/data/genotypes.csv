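patient_id,cohort,disorder,gene,sex,ethnicity,allele1_c,allele1_p,allele2_c,allele2_p,novel1_abstract,novel1_table,novel2_abstract,novel2_table
NB-PKU-1,newborn,PKU,PAH,M,Zhuang,c.1174T>A,p.F392I,c.1223G>A,p.R408Q,0,0,0,0
NB-PKU-2,newborn,PKU,PAH,M,Han,c.1223G>A,p.R408Q,c.208_210del,p.70del,0,0,0,0
NB-PKU-3,newborn,PKU,PAH,F,Han,c.611A>G,p.Tyr204Cys,c.611A>G,p.Tyr204Cys,0,0,0,0
NB-PKU-4,newborn,PKU,PAH,F,Han,c.331C>T,p.Arg111Ter,c.728G>A,p.Arg243Gln,0,0,0,0
NB-PKU-5,newborn,PKU,PAH,M,Han,c.320A>G,p.His107Arg,c.1223G>A,p.Arg408Gln,0,0,0,0
NB-PKU-6,newborn,PKU,PAH,M,Han,c.721C>T,p.Arg241Cys,c.728G>A,p.Arg243Gln,0,0,0,0
NB-CTLN2-1,newborn,CTLN2,SLC25A13,M,Yao,c.851_854delGTAT,,c.1638_1660dup23,,0,0,0,0
NB-HCY-1,newborn,HCY,CBS,F,Han,c.1465C>T,p.Gln489Ter,c.1465C>T,p.Gln489Ter,1,1,1,1
NB-PCD-1,newborn,PCD,SLC22A5,M,Han,c.51C>G,p.Phe17Leu,c.760C>T,p.Arg254Ter,0,0,0,0
NB-PCD-2,newborn,PCD,SLC22A5,M,Han,c.760C>T,p.Arg254Ter,c.919delG,p.Val307LeufsX14,0,0,0,1
NB-PCD-3,newborn,PCD,SLC22A5,F,Han,c.1400C>G,p.Ser467Cys,c.1400C>G,p.Ser467Cys,0,0,0,0
NB-PCD-4,newborn,PCD,SLC22A5,F,Han,c.1195C>T,p.Arg399Try,c.517delC,p.Leu173CysfsX3,0,0,0,0
NB-PCD-5,newborn,PCD,SLC22A5,F,Zhuang,c.51C>G,p.Phe17Leu,c.51C>G,p.Phe17Leu,0,0,0,0
NB-PCD-6,newborn,PCD,SLC22A5,F,Han,c.51C>G,p.Phe17Leu,c.338G>A,p.Cys113Tyr,0,0,0,0
NB-PCD-7,newborn,PCD,SLC22A5,F,Han,c.1400C>G,p.Ser467Cys,c.839C>T,p.Ser280Phe,0,0,0,0
NB-PCD-8,newborn,PCD,SLC22A5,F,Miao,c.976C>T,p.Gln326X,c.505C>T,p.Arg169Trp,0,1,0,0
NB-PCD-9,newborn,PCD,SLC22A5,M,Han,c.760C>T,p.Arg254Ter,c.760C>T,p.Arg254Ter,0,0,0,0
NB-PCD-10,newborn,PCD,SLC22A5,M,Han,c.51C>G,p.Phe17Leu,c.51C>G,p.Phe17Leu,0,0,0,0
NB-PCD-11,newborn,PCD,SLC22A5,M,Zhuang,c.51C>G,p.Phe17Leu,c.51C>G,p.Phe17Leu,0,0,0,0
NB-PCD-12,newborn,PCD,SLC22A5,M,Han,c.338G>A,p.Cys113Tyr,c.338G>A,p.Cys113Tyr,0,0,0,0
NB-SCADD-1,newborn,SCADD,ACADS,F,Zhuang,c.625G>A,p.Gly209Ser,c.625G>A,p.Gly209Ser,0,0,0,0
NB-SCADD-2,newborn,SCADD,ACADS,F,Han,c.268G>A,p.Gly90Ser,c.337G>A,p.Gly113Arg,0,0,1,1
NB-MCADD-1,newborn,MCADD,ACADM,M,Zhuang,c.580A>,p.Asn194Asp,c.580A>,p.Asn194Asp,0,0,0,0
NB-IVA-1,newborn,IVA,IVD,F,Zhuang,c.214G>A,p.Asp72Asn,c.1208A>G,p.Tyr403Cys,0,0,0,0
NB-IVA-2,newborn,IVA,IVD,M,Han,c.548C>T,p.Ala183Val,c.757A>G,p.Thr253Ala,1,1,1,1
NB-IVA-3,newborn,IVA,IVD,M,Zhuang,c.149G>A,p.Arg50His,c.1199A>G,p.Tyr400Cys,0,0,0,0
NB-GA1-1,newborn,GA-1,GCDH,M,Zhuang,c.532G>A,p.Gly178Arg,c.532G>A,p.Gly178Arg,0,0,0,0
NB-MMA-1,newborn,MMA,MMACHC,F,Han,c.315C>G,p.Tyr105Ter,1076bp del,,0,0,1,1
NB-PA-1,newborn,PA,PCCB,F,Zhuang,c.1559-4_1559-3insAGAAGCA,,c.1594C>T,p.Arg532Cys,0,0,0,0
NB-HMGCLD-1,newborn,HMGCLD,HMGCL,F,Dong,c.252+1G>A,,c.501C>G,p.Tyr167Ter,0,0,1,1
HR-CTLN2-1,high_risk,CTLN2,SLC25A13,F,Han,c.851_854delGTAT,,c.851_854delGTAT,,0,0,0,0
HR-CTLN2-2,high_risk,CTLN2,SLC25A13,M,Han,c.851_854delGTAT,,c.851_854delGTAT,,0,0,0,0
HR-CTLN2-3,high_risk,CTLN2,SLC25A13,F,Zhuang,c.851_854delGTAT,,c.851_854delGTAT,,0,0,0,0
HR-CTLN2-4,high_risk,CTLN2,SLC25A13,M,Zhuang,c.851_854delGTAT,,c.851_854delGTAT,,0,0,0,0
HR-OTC-1,high_risk,OTC,OTC,F,Zhuang,IVS7-1G>A,,,,0,0,0,0
HR-OTC-2,high_risk,OTC,OTC,M,Han,2-7exon del,,,,0,0,0,0
HR-HTYR-1,high_risk,H-TYR,HPD,F,Yao,c.93+1delG,,c.941T>C,p.Ile314Thr,0,1,1,0
HR-CPS1-1,high_risk,CPS1,CPS1,M,Han,c.1649C>T,p.Thr550Met,c.858G>C,p.Lys286Asn,0,0,0,0
HR-PCD-1,high_risk,PCD,SLC22A5,F,Dong,c.976C>T,p.Gln326Ter,c.976C>T,p.Gln326Ter,0,1,0,1
HR-PCD-2,high_risk,PCD,SLC22A5,M,Zhuang,c.1411C>T,p.Arg471Cys,c.1195C>T,p.Arg399Try,0,0,0,0
HR-SCADD-1,high_risk,SCADD,ACADS,M,Han,c.1148G>A,p.Arg383His,c.1031A>G,p.Glu344Gly,0,0,0,0
HR-SCADD-2,high_risk,SCADD,ACADS,F,Zhuang,c.320G>A,p.Arg107His,c.1195C>T,p.Arg399Trp,0,0,1,1
HR-CPT2-1,high_risk,CPT2,CPT2,F,Han,c.886C>T,p.Arg296Ter,c.1148T>A,p.Phe383Tyr,0,0,0,0
HR-MADD-1,high_risk,MADD,ETFA,M,Han,c.494T>C,p.Val165Ala,c.737G>T,p.Gly246Val,0,0,1,1
HR-IVA-1,high_risk,IVA,IVD,M,Han,c.1208A>G,p.Tyr403Cys,c.1208A>G,p.Tyr403Cys,0,0,0,0
HR-GA1-1,high_risk,GA-1,GCDH,M,Han,c.532G>A,p.Gly178Arg,c.655G>A,p.Ala219Thr,0,0,0,0
HR-GA1-2,high_risk,GA-1,GCDH,M,Zhuang,c.532G>A,p.Gly178Arg,c.1060G>T,p.Gly354Cys,0,0,1,1
HR-MMA-1,high_risk,MMA,MMUT,F,Han,c.103C>T,p.Gln35Ter,c.346G>A,p.Val116Met,0,0,0,0
HR-PA-1,high_risk,PA,PCCB,F,Han,c.132-134delGACinsAT,,,,1,1,0,0
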