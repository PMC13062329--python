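synonym,ingredient,is_target_ici,ici_class
PEMBROLIZUMAB,PEMBROLIZUMAB,1,PD1
KEYTRUDA,PEMBROLIZUMAB,1,PD1
MK-3475,PEMBROLIZUMAB,1,PD1
PEMBROLIZMAB,PEMBROLIZUMAB,1,PD1
NIVOLUMAB,NIVOLUMAB,1,PD1
OPDIVO,NIVOLUMAB,1,PD1
BMS-936558,NIVOLUMAB,1,PD1
NIVOLUMAB BMS,NIVOLUMAB,1,PD1
TORIPALIMAB,TORIPALIMAB,1,PD1
LOQTORZI,TORIPALIMAB,1,PD1
JS001,TORIPALIMAB,1,PD1
TISLELIZUMAB,TISLELIZUMAB,1,PD1
TEVIMBRA,TISLELIZUMAB,1,PD1
BGB-A317,TISLELIZUMAB,1,PD1
CEMIPLIMAB,CEMIPLIMAB,1,PD1
CEMIPLIMAB-RWLC,CEMIPLIMAB,1,PD1
LIBTAYO,CEMIPLIMAB,1,PD1
DOSTARLIMAB,DOSTARLIMAB,1,PD1
DOSTARLIMAB-GXLY,DOSTARLIMAB,1,PD1
JEMPERLI,DOSTARLIMAB,1,PD1
ATEZOLIZUMAB,ATEZOLIZUMAB,1,PDL1
TECENTRIQ,ATEZOLIZUMAB,1,PDL1
ATEZOLIZMAB,ATEZOLIZUMAB,1,PDL1
AVELUMAB,AVELUMAB,1,PDL1
BAVENCIO,AVELUMAB,1,PDL1
DURVALUMAB,DURVALUMAB,1,PDL1
IMFINZI,DURVALUMAB,1,PDL1
MEDI4736,DURVALUMAB,1,PDL1
IPILIMUMAB,IPILIMUMAB,1,CTLA4
YERVOY,IPILIMUMAB,1,CTLA4
MDX-010,IPILIMUMAB,1,CTLA4
IPILIMUMAB.,IPILIMUMAB,1,CTLA4
PACLITAXEL,PACLITAXEL,0,
TAXOL,PACLITAXEL,0,
PACLITAXEL (TAXOL),PACLITAXEL,0,
CARBOPLATIN,CARBOPLATIN,0,
PARAPLATIN,CARBOPLATIN,0,
CISPLATIN,CISPLATIN,0,
PLATINOL,CISPLATIN,0,
ETOPOSIDE,ETOPOSIDE,0,
VEPESID,ETOPOSIDE,0,
VP-16,ETOPOSIDE,0,
CABOZANTINIB,CABOZANTINIB,0,
CABOMETYX,CABOZANTINIB,0,
AXITINIB,AXITINIB,0,
INLYTA,AXITINIB,0,
PEMETREXED,PEMETREXED,0,
ALIMTA,PEMETREXED,0,
LEVOTHYROXINE,LEVOTHYROXINE,0,
LEVOTHYROXINE SODIUM,LEVOTHYROXINE,0,
SYNTHROID,LEVOTHYROXINE,0,
OMEPRAZOLE,OMEPRAZOLE,0,
PRILOSEC,OMEPRAZOLE,0,
PANTOPRAZOLE,PANTOPRAZOLE,0,
PROTONIX,PANTOPRAZOLE,0,
METFORMIN,METFORMIN,0,
METFORMIN HYDROCHLORIDE,METFORMIN,0,
GLUCOPHAGE,METFORMIN,0,
ATORVASTATIN,ATORVASTATIN,0,
ATORVASTATIN CALCIUM,ATORVASTATIN,0,
LIPITOR,ATORVASTATIN,0,
LISINOPRIL,LISINOPRIL,0,
ZESTRIL,LISINOPRIL,0,
PRINIVIL,LISINOPRIL,0,
AMLODIPINE,AMLODIPINE,0,
NORVASC,AMLODIPINE,0,
IBUPROFEN,IBUPROFEN,0,
ADVIL,IBUPROFEN,0,
MOTRIN,IBUPROFEN,0,
PREDNISONE,PREDNISONE,0,
DELTASONE,PREDNISONE,0,
GABAPENTIN,GABAPENTIN,0,
NEURONTIN,GABAPENTIN,0,
FUROSEMIDE,FUROSEMIDE,0,
LASIX,FUROSEMIDE,0,
ONDANSETRON,ONDANSETRON,0,
ZOFRAN,ONDANSETRON,0,
DEXAMETHASONE,DEXAMETHASONE,0,
DECADRON,DEXAMETHASONE,0,
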