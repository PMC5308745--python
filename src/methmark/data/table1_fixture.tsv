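gene	probe_number	mean_beta_normal	mean_beta_cancer	delta_beta
EYA4	27	0.151	0.469	0.318
GFRA1	20	0.134	0.472	0.338
FOXI2	15	0.291	0.579	0.288
SLITRK1	9	0.336	0.610	0.274
STOX2	9	0.118	0.378	0.260
CNRIP1	8	0.182	0.531	0.349
SFRP1	8	0.292	0.549	0.257
ADHFE1	7	0.133	0.627	0.494
C2orf40	6	0.265	0.528	0.263
KCNC2	6	0.279	0.572	0.293
KCNQ1	6	0.670	0.481	-0.189
LONRF2	6	0.110	0.498	0.388
MEST	6	0.762	0.505	-0.257
RALYL	6	0.287	0.550	0.263
HKDC1	5	0.782	0.533	-0.249
KCNIP4	5	0.190	0.443	0.253
SORCS1	5	0.223	0.524	0.301
CBLN2	4	0.236	0.495	0.259
FRZB	4	0.236	0.487	0.251
GALR1	4	0.255	0.496	0.241
PMEPA1	4	0.754	0.457	-0.297
RARRES2	4	0.396	0.639	0.243
SLC6A5	4	0.376	0.605	0.229
AZGP1	3	0.718	0.453	-0.265
C10orf81	3	0.641	0.417	-0.224
FAM110A	3	0.787	0.542	-0.245
GLRA3	3	0.194	0.445	0.251
GSTM2	3	0.216	0.514	0.298
HSD11B1	3	0.700	0.446	-0.254
MAL	3	0.173	0.471	0.298
PHACTR3	3	0.715	0.454	-0.261
SST	3	0.293	0.533	0.240
TMEFF2	3	0.157	0.475	0.318
TNFRSF8	3	0.815	0.581	-0.234
TUSC3	3	0.244	0.464	0.220
ZNF655	3	0.056	0.279	0.223
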