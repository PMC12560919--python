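row_type,group,meat,children,youth,adults
basis,isoleucine,5.92,4.6,4.0,3.0
basis,leucine,10.31,9.3,7.0,4.4
basis,lysine,11.47,6.6,5.5,3.1
basis,met_cys,4.58,4.2,3.5,2.7
basis,phe_tyr,9.57,7.2,6.0,3.3
basis,threonine,5.78,4.3,4.0,2.6
basis,tryptophan,13.88,1.7,1.0,0.6
basis,valine,6.06,5.5,5.0,2.3
basis,eaa_total,67.58,43.4,36.0,22.0
chemical_score,isoleucine,,128.71,148.01,197.35
chemical_score,leucine,,110.91,147.35,234.42
chemical_score,lysine,,173.80,208.56,370.03
chemical_score,met_cys,,109.03,130.83,169.60
chemical_score,phe_tyr,,132.98,159.57,290.14
chemical_score,threonine,,134.46,144.54,222.37
chemical_score,tryptophan,,816.24,1387.60,2312.67
chemical_score,valine,,110.17,121.18,263.44
index,eaai,,160.25,197.43,321.49
index,bv,,162.97,203.50,338.73
index,ni,,34.65,42.68,69.51
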