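wavelength_nm,Hb,HbO2,lipid,water
700,1.794,0.290,0.083,0.006
710,1.540,0.314,0.077,0.007
720,1.326,0.342,0.073,0.009
730,1.102,0.390,0.074,0.014
740,1.116,0.446,0.080,0.022
750,1.405,0.562,0.085,0.028
760,1.549,0.586,0.098,0.027
770,1.312,0.650,0.091,0.025
780,1.075,0.710,0.082,0.023
790,0.891,0.756,0.080,0.023
800,0.762,0.816,0.081,0.022
810,0.682,0.864,0.086,0.026
820,0.629,0.916,0.094,0.030
830,0.587,0.974,0.107,0.033
840,0.554,1.022,0.122,0.037
850,0.527,1.058,0.138,0.043
860,0.507,1.104,0.157,0.049
870,0.491,1.136,0.184,0.056
880,0.479,1.170,0.224,0.063
890,0.471,1.204,0.292,0.068
900,0.468,1.198,0.409,0.068
910,0.469,1.214,0.608,0.072
920,0.475,1.222,0.911,0.095
930,0.485,1.220,1.235,0.131
940,0.500,1.214,1.048,0.174
950,0.518,1.196,0.772,0.222
960,0.541,1.176,0.608,0.283
970,0.568,1.154,0.517,0.412
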