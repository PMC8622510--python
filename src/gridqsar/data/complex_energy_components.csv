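complex,vdwaals,e_el,e_pbgb,e_surf
FLT3-M01,-71.17,-51.49,68.69,-8.82
FLT3-M03,-72.23,-275.18,295.32,-8.72
FLT3-M17,-53.77,-21.27,34.20,-6.48
FLT3-M20,-69.48,-222.37,240.20,-9.02
FLT3-M24,-62.38,-28.98,39.64,-7.83
FLT3-M34,-56.90,-248.23,262.59,-6.76
FLT3-D835Y-M01,-70.94,-51.33,67.31,-8.58
FLT3-F691L-M01,-69.99,-53.10,69.92,-8.86
FLT3-D835Y-F691L-M01,-70.43,-50.96,67.16,-8.56
FLT3-D01,-71.01,-45.14,66.81,-8.84
FLT3-D02,-70.82,-32.90,49.71,-9.17
FLT3-D03,-71.38,-55.60,71.34,-9.04
FLT3-D04,-72.37,-54.24,71.68,-9.30
FLT3-D05,-76.94,-63.43,79.81,-9.90
FLT3-D07,-73.59,-48.56,60.95,-9.45
FLT3-D08,-72.79,-33.30,50.01,-8.72
FLT3-D09,-74.03,-54.80,78.07,-9.34
FLT3-D10,-69.67,-49.27,71.01,-9.41
FLT3-D11,-80.40,-37.05,71.92,-10.24
FLT3-D12,-76.69,-27.84,46.29,-9.39
FLT3-D14,-80.42,-28.40,56.25,-10.07
FLT3-D15,-78.07,-57.04,70.96,-9.45
FLT3-D17,-66.50,-64.74,81.42,-8.66
FLT3-D21,-72.32,-17.78,46.93,-9.08
FLT3-D22,-73.23,-25.85,45.39,-9.44
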