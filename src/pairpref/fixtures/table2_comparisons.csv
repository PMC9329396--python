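# Ordered-pair comparison counts from the eight-thickener taste study:
# cell (row i, column j) = number of judgments in which product i was
# tasted first and product j second. 224 judgments by 37 subjects in total.
,A1,A2,A3,A4,A5,A6,A7,A8
A1,0,5,5,3,4,3,4,3
A2,3,0,4,4,5,4,4,4
A3,4,5,0,5,4,4,4,5
A4,4,5,5,0,2,5,3,3
A5,5,5,5,3,0,4,4,3
A6,3,4,4,4,4,0,5,4
A7,4,4,3,5,4,2,0,4
A8,4,3,4,3,5,4,5,0
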