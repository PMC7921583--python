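cone_year,cone_score,netting_days,siskins_caught,arrival_date,abundance_netting_days,abundance_start,abundance_end,rain_correlation,rain_corr_significant,mean_adults_per_catch
2005,8,35,503,2006-02-06,19,2006-02-17,2006-07-29,0.06,0,11.2
2006,2,31,425,2006-12-28,14,2007-04-06,2007-08-05,0.34,0,19.4
2007,8,28,607,2007-12-05,18,2008-02-13,2008-08-17,0.37,0,21.2
2008,6,32,1128,2008-12-02,18,2009-01-21,2009-07-15,-0.31,0,43.3
2009,1,38,1005,2010-02-25,15,2010-04-03,2010-08-07,0.52,1,51.5
2010,7,42,1634,2010-12-11,29,2011-01-05,2011-07-29,0.22,0,48.0
2011,9,28,1470,2011-11-13,21,2012-01-12,2012-08-19,0.35,0,33.6
2012,4,33,1017,2013-01-14,16,2013-03-13,2013-08-15,0.29,0,51.8
2013,6,33,605,2013-12-11,15,2014-02-26,2014-08-10,0.18,0,25.3
2014,4,28,643,2014-12-17,13,2015-03-22,2015-08-27,0.39,0,33.0
2015,8,33,986,2015-12-26,20,2016-02-06,2016-08-15,0.35,0,13.8
2016,2,44,1481,2017-01-01,22,2017-02-26,2017-07-27,-0.23,0,47.8
2017,3,42,1805,2018-01-04,20,2018-03-06,2018-07-23,0.15,0,76.6
2018,8,43,1158,2018-12-22,21,2019-02-19,2019-07-25,0.57,1,42.2
2019,2,38,1261,2020-02-02,18,2020-03-25,2020-08-08,-0.20,0,48.4
2020,9,40,825,2020-12-13,36,2021-01-04,2021-07-08,0.63,1,24.3
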