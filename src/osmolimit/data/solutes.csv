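name,mode,m0,m1,constant_d,citation
ammonium,linear_ionic,9.5,0.413,,"Boudreau (1997) Diagenetic Models and Their Implementation, Table 4.8 (NH4+)"
nitrite,linear_ionic,10.3,0.331,,"Boudreau (1997) Table 4.8 (NO2-)"
nitrate,linear_ionic,9.5,0.388,,"Boudreau (1997) Table 4.8 (NO3-)"
phosphate_hpo4,linear_ionic,3.26,0.177,,"Boudreau (1997) Table 4.8 (HPO4 2-)"
phosphate_h2po4,linear_ionic,4.02,0.223,,"Boudreau (1997) Table 4.8 (H2PO4-)"
phosphate_po4,linear_ionic,2.62,0.143,,"Boudreau (1997) Table 4.8 (PO4 3-)"
urea,constant,,,1.36e-5,"constant diffusivity for urea in seawater, 1.36e-5 cm2 s-1"
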