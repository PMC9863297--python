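des,polyol,chcl_ratio,polyol_ratio,x_star_des,temperature_K,xE_1e4,cE_mg_per_mL,sd_xE_1e4,sd_cE
GLE,glycerol,1,1,1.0,298.15,786.83,138.18,3.34,1.21
GLE,glycerol,1,1,1.0,303.15,1173.65,202.99,39.25,6.76
GLE,glycerol,1,1,1.0,308.15,1615.31,274.07,40.69,6.88
GLE,glycerol,1,1,1.0,313.15,2429.30,398.02,72.71,10.92
GLE,glycerol,1,2,1.0,298.15,1052.85,191.06,68.85,11.91
GLE,glycerol,1,2,1.0,303.15,1606.43,282.25,50.52,8.03
GLE,glycerol,1,2,1.0,308.15,2151.57,369.09,64.56,11.3
GLE,glycerol,1,2,1.0,313.15,2991.42,492.12,64.1,9.58
GLE,glycerol,1,4,1.0,298.15,926.44,177.17,23.62,4.09
GLE,glycerol,1,4,1.0,303.15,1321.28,246.26,36.17,5.86
GLE,glycerol,1,4,1.0,308.15,1861.97,336.43,40.45,6.12
GLE,glycerol,1,4,1.0,313.15,2739.72,470.20,65.05,9.06
ETA,ethylene glycol,1,1,1.0,298.15,1031.93,189.66,62.91,10.5
ETA,ethylene glycol,1,1,1.0,303.15,1400.98,251.75,40.74,7.12
ETA,ethylene glycol,1,1,1.0,308.15,2089.82,359.76,49.36,7.92
ETA,ethylene glycol,1,1,1.0,313.15,2966.24,484.49,120.59,16.00
ETA,ethylene glycol,1,2,1.0,298.15,1579.47,302.96,70.73,11.01
ETA,ethylene glycol,1,2,1.0,303.15,2135.68,392.28,42.46,6.53
ETA,ethylene glycol,1,2,1.0,308.15,2878.22,499.02,133.85,18.34
ETA,ethylene glycol,1,2,1.0,313.15,3602.21,592.85,117.41,14.78
ETA,ethylene glycol,1,4,1.0,298.15,1306.68,280.14,55.75,10.35
ETA,ethylene glycol,1,4,1.0,303.15,1677.66,346.64,47.52,7.87
ETA,ethylene glycol,1,4,1.0,308.15,2434.99,467.15,114.12,16.58
ETA,ethylene glycol,1,4,1.0,313.15,3428.20,601.77,105.69,12.46
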