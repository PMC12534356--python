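site_id,group,distance_km,pH,Al,As,Cd,Co,Cr,Cu,Fe,Mn,Mo,Ni,Pb,Zn
NY-01,main_stem,0,7.43,33.0,0.25,<0.29,<0.053,<0.05,1.91,130,17.5,0.55,<0.098,0.41,<1.46
NY-04,main_stem,2.66,7.29,27.8,0.26,<0.29,494,<0.05,181,38.2,444,0.41,104,0.15,49.8
NY-05,main_stem,2.82,7.39,39.3,0.23,<0.29,493,<0.05,159,51.8,467,0.46,109,0.19,51.6
NY-07,main_stem,3.56,7.10,37.0,0.28,<0.29,564,<0.05,150,28.1,604,0.56,113,0.11,51.4
NY-08,main_stem,4.25,7.42,40.4,0.15,<0.29,171,<0.05,101,96.7,200,0.41,32.6,0.07,14.2
NY-11,main_stem,6.7,7.27,62.0,0.12,<0.29,193,<0.05,77.7,179,240,0.42,31.4,0.14,17.1
NY-12,main_stem,10.39,7.21,84.8,0.18,<0.29,137,<0.05,78.9,272,205,0.40,22.8,0.13,8.58
NY-14,main_stem,11.64,7.32,84.7,0.21,<0.29,123,<0.05,75.2,275,190,0.41,20.2,0.17,6.86
NY-15,main_stem,16.2,6.85,90.8,0.19,<0.29,84.3,<0.05,66.1,282,165,0.40,14.8,0.17,11.3
NY-02,tributary,,6.52,21.8,0.57,<0.29,1420,<0.05,1170,31.9,1130,0.54,326,0.42,216
NY-03,tributary,,7.60,16.4,0.18,<0.29,3.26,<0.05,1.44,161,148,0.82,0.88,0.22,<1.46
NY-06,mine_drainage,,6.66,25.4,1.17,<0.29,3060,<0.05,223,198,4360,2.56,514,0.08,182
NY-09,tributary,,7.54,72.2,0.22,<0.29,<0.053,<0.05,0.12,197,88.1,0.41,<0.098,0.25,3.03
NY-10,tributary,,7.77,33.6,0.13,<0.29,<0.053,<0.05,0.12,415,7.59,0.36,<0.098,0.17,2.64
NY-13,tributary,,7.34,61.0,0.30,<0.29,<0.053,<0.05,<0.453,267,22.1,0.32,<0.098,0.13,4.18
LG-01,lake,,9.01,15.16,0.17,<0.29,<0.053,<0.05,<0.453,25.56,2.73,<0.238,<0.098,0.16,12.94
LG-02,lake,,9.26,10.19,0.21,<0.29,<0.053,<0.05,<0.453,13.35,1.56,<0.238,<0.098,0.21,1.83
LG-03,lake,,8.92,24.95,0.16,<0.29,<0.053,<0.05,<0.453,35.32,1.91,<0.238,<0.098,0.71,3.49
LG-04,lake,,8.91,9.72,0.24,<0.29,<0.053,<0.05,<0.453,12.81,0.68,<0.238,<0.098,0.20,3.53
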