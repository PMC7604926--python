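name,mw,logp,c_test_mg_ml,loq_ng_ml
Carboplatin,371.25,-0.46,10,0.95
Carmustine,214.06,1.53,3.3,150
Cisplatin,300.5,-2.19,0.5,0.77
Cyclophosphamide,261.1,0.6,20,0.06
Doxorubicin,543.5,1.4,10,30
Etoposide,588.6,0.6,20,12
Fluorouracil,130.8,-1.0,50,0.3
Ifosfamide,261.09,0.86,40,0.03
Oxaliplatin,397.29,-1.6,5,1.02
Paclitaxel,853.9,3.7,6,30
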