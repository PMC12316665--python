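genotype,total_cardiac_suv,cov,summed_basal,summed_apical,summed_septal,summed_lateral
wt,24.16,259.40,17.23,6.93,8.64,6.19
v,33.46,157.07,24.65,8.81,9.61,10.47
v,35.99,161.16,25.49,10.50,10.66,10.30
v,37.42,155.92,26.70,10.72,11.71,10.77
v,38.23,221.59,28.08,10.15,12.75,10.34
wt,44.36,285.17,31.73,12.63,14.80,12.04
wt,45.39,211.71,32.96,12.43,16.21,13.01
wt,46.01,153.64,32.91,13.10,14.44,13.01
wt,46.38,166.83,33.05,13.33,15.07,12.04
wt,46.49,159.86,32.86,13.64,14.56,11.45
wt,47.29,157.07,33.67,13.62,15.64,12.64
wt,50.12,314.87,36.47,13.65,15.88,16.11
wt,50.17,186.86,35.19,14.98,16.08,13.69
wt,50.30,239.24,36.32,13.98,15.73,13.71
wt,53.61,165.70,38.66,14.95,16.75,15.55
wt,55.20,204.80,39.04,16.16,17.60,14.40
wt,56.35,148.96,40.66,15.69,17.22,16.26
v,58.37,86.38,41.39,16.99,17.31,17.16
wt,62.72,172.45,45.66,17.06,20.09,17.67
wt,62.77,176.56,44.83,17.94,18.27,18.49
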