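compound_id,ache_ic50_nM,ache_ic50_sd,ache_r2,bche_ic50_nM,bche_ic50_sd,bche_r2,maoa_ic50_nM,maoa_ic50_sd,maoa_r2,maob_ic50_nM,maob_ic50_sd,maob_r2,ache_ki_nM,ache_ki_sd,bche_ki_nM,bche_ki_sd
5a,14.90,1.54,0.913,124.72,9.13,0.982,104.17,4.58,0.960,391.03,9.04,0.989,11.37,3.06,101.32,22.43
5b,33.81,3.41,0.906,202.05,5.66,0.937,132.05,7.01,0.931,409.76,7.47,0.928,26.55,3.34,190.57,15.65
5c,38.42,5.03,0.904,217.78,8.41,0.929,188.54,6.46,0.933,296.47,6.01,0.990,25.43,5.32,182.65,15.04
5d,39.37,2.87,0.968,252.54,10.46,0.923,170.66,10.42,0.935,406.18,8.24,0.942,32.23,5.93,234.84,15.04
5e,31.04,4.16,0.921,208.43,7.53,0.951,117.13,7.33,0.923,>1000,,0.935,25.36,3.32,195.34,11.53
5f,49.53,5.21,0.947,253.53,6.31,0.964,133.50,8.04,0.901,388.10,5.37,0.957,38.82,6.18,239.89,18.65
5g,80.43,7.62,0.978,287.26,8.57,0.970,187.66,5.36,0.964,398.57,7.93,0.902,72.43,10.08,258.50,16.14
5h,16.76,1.35,0.949,145.03,8.96,0.913,100.38,4.57,0.930,249.01,9.10,0.944,14.59,3.36,136.01,9.17
5i,24.81,2.41,0.958,199.54,9.41,0.902,121.24,3.15,0.924,285.25,4.02,0.912,21.02,4.12,190.27,13.60
5j,40.62,2.77,0.979,265.38,7.90,0.970,136.93,6.21,0.981,395.37,8.35,0.966,36.52,5.23,228.42,12.35
5k,116.01,8.42,0.906,252.64,9.15,0.977,144.71,8.03,0.976,>1000,,0.952,95.75,9.54,205.34,10.16
5l,29.54,2.68,0.918,200.34,6.88,0.985,112.33,2.78,0.907,276.97,6.33,0.938,27.41,3.45,182.09,9.05
5m,38.49,3.21,0.909,214.30,7.13,0.963,132.28,4.96,0.954,368.58,11.25,0.926,30.22,5.02,193.05,11.62
5n,47.70,5.67,0.970,308.43,9.98,0.932,137.19,6.55,0.976,395.72,8.09,0.930,42.44,4.10,270.16,13.54
5o,18.93,1.33,0.998,192.09,6.36,0.981,122.65,7.01,0.932,267.07,6.35,0.905,14.25,2.32,160.33,9.01
5p,54.46,4.57,0.915,254.24,8.08,0.965,145.32,3.57,0.985,326.68,9.13,0.955,47.09,6.35,226.45,12.57
5q,19.34,1.28,0.984,202.31,14.86,0.963,119.06,9.24,0.926,308.44,6.07,0.927,17.63,3.34,182.76,11.48
5r,27.39,2.42,0.912,293.55,7.14,0.912,142.55,6.78,0.944,495.13,8.36,0.995,21.17,1.05,249.09,15.30
5s,71.43,8.92,0.954,220.34,8.53,0.954,131.09,5.34,0.976,369.46,12.04,0.975,63.86,7.54,195.21,13.45
5t,56.21,4.58,0.902,271.12,6.90,0.981,138.74,6.02,0.932,289.02,9.11,0.945,48.30,7.32,226.65,16.08
5u,12.89,1.02,0.987,148.18,7.35,0.973,96.25,5.77,0.906,208.95,5.84,0.978,9.82,1.76,112.06,7.61
galantamine,101.24,5.72,0.984,261.62,9.03,0.945,,,,,,,84.05,8.70,242.17,13.88
clorgyline,,,,,,,150.62,4.03,0.979,468.63,16.05,0.987,,,,
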