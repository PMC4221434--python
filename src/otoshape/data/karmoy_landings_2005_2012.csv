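year,month,tonnes
2005,2,21.2
2005,3,24.5
2005,4,129.2
2005,8,1.0
2005,12,0.2
2006,3,32.6
2006,4,0.7
2006,11,72.8
2007,3,16.5
2007,4,1.0
2007,10,0.1
2008,4,4.8
2009,1,0.1
2009,2,172.0
2009,3,19052.0
2009,4,2301.2
2009,9,0.9
2010,2,3302.9
2010,3,14877.0
2010,4,1000.3
2010,11,0.5
2011,2,609.1
2011,3,6528.4
2011,4,52.0
2012,2,897.3
2012,3,6283.2
2012,4,13.4
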