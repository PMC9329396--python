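# Preference ("win") counts from the eight-thickener taste study:
# cell (row i, column j) = number of judgments in which product i was
# preferred over product j, aggregated over presentation order.
,A1,A2,A3,A4,A5,A6,A7,A8
A1,0,7,6,2,2,6,7,6
A2,1,0,3,0,0,3,3,4
A3,3,6,0,1,0,3,5,7
A4,5,9,9,0,4,9,7,6
A5,7,10,9,1,0,7,8,8
A6,0,5,5,0,1,0,4,5
A7,1,5,2,1,0,3,0,7
A8,1,3,2,0,0,3,2,0
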