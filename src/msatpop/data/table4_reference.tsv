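# Transcription of published pairwise Nei unbiased genetic identity (above
# diagonal) and distance (below diagonal) between the seven guinea fowl
# plumage phenotypes.  Transcribed reference numbers, not package output.
population	Albino	Bonaparte	Pearl grey	Lavender	Black pied	Multi-coloured	Royal purple
Albino		0.9659	0.9492	0.8557	0.9244	0.9395	0.9271
Bonaparte	0.0346		0.9932	0.8903	0.9581	0.9805	0.9736
Pearl grey	0.0521	0.0068		0.9109	0.9464	0.9670	0.9718
Lavender	0.1559	0.1162	0.0933		0.8566	0.9125	0.8688
Black pied	0.0786	0.0428	0.0550	0.1548		0.9565	0.9492
Multi-coloured	0.0624	0.0197	0.0335	0.0916	0.0445		0.9492
Royal purple	0.0757	0.0267	0.0286	0.1406	0.0536	0.0522
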