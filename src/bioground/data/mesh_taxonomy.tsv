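D006801	9606
D051379	10090
D051381	10116
D004331	7227
D012441	4932
D017173	6239
D015027	7955
D004926	562
D014982	8355
D017360	3702
D002645	9031
D002417	9913
D013552	9823
D008253	9544
D011817	9986
D004285	9615
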