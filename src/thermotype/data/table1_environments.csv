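trial_code,n_genotypes,sowing,anthesis,grain_filling,harvest,gy,d13c,sdd,tmax,vpdmax,swc
FIsr 2011,384,2011-08-31,2011-11-24,2011-12-22,2012-01-11,8.03,18.0,1.81,23.4,1.76,542.7
FIsr 2012,384,2012-08-07,2012-11-05,2012-11-19,2013-01-28,9.83,18.8,-1.70,21.5,1.52,404.8
FIsr 2014,64,2014-08-27,2014-11-24,2014-12-17,2015-01-22,9.90,,1.60,23.5,1.92,212.3
FIsr 2015,64,2015-07-29,2015-11-20,2015-12-08,2016-01-25,9.38,18.8,1.38,21.5,1.63,198.3
FIc 2015,64,2015-05-18,2015-10-23,2015-11-12,2015-12-23,8.46,16.9,1.12,19.1,1.35,246.2
WSsr 2011,384,2011-08-31,2011-11-24,2011-12-22,2012-01-11,4.81,16.5,6.44,23.4,1.76,418.8
WSc 2011,384,2011-09-07,2011-11-29,2011-12-13,2012-01-05,1.68,14.2,12.29,25.4,2.39,320.9
WSc 2012,384,2012-05-23,2012-09-11,2012-10-25,2012-12-23,3.18,15.0,2.17,20.6,1.51,225.5
WSsr 2015,64,2015-07-29,2015-11-20,2015-12-08,2016-01-25,7.40,18.5,3.31,21.5,1.63,180.4
WSc 2015,64,2015-05-18,2015-10-23,2015-11-12,2015-12-23,8.13,16.9,2.16,19.1,1.35,283.8
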