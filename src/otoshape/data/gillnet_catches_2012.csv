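date,location,catch,nets
2012-02-15,Outer Strandfjorden,28,1
2012-02-15,Bufjorden,11,1
2012-03-06,Landvikvannet,4,3
2012-03-06,Inner Strandfjorden,129,1
2012-03-06,Outer Strandfjorden,119,1
2012-03-20,Landvikvannet,47,3
2012-03-20,Inner Strandfjorden,542,1
2012-03-26,Landvikvannet,115,3
2012-03-26,Inner Strandfjorden,486,1
2012-03-26,Bufjorden,100,1
2012-04-11,Landvikvannet,290,2
2012-04-11,Inner Strandfjorden,663,1
2012-05-14,Landvikvannet,177,1
2012-05-14,Inner Strandfjorden,69,1
2012-06-21,Landvikvannet,82,1
2012-06-21,Inner Strandfjorden,66,1
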