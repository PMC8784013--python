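# Transcription of published per-population average diversity values
# (phenotype and agroecological-zone groupings) for the Togolese indigenous
# guinea fowl survey.  Transcribed reference numbers, not package output.
population	grouping	N	Na	AR	Ae	Ho	He	FIS
Albino	phenotype	5	3.2	3.0	2.6	0.447	0.584	0.257
Bonaparte	phenotype	19	4.3	3.0	2.7	0.496	0.606	0.185
Pearl grey	phenotype	19	4.6	3.2	3.1	0.521	0.633	0.181
Lavender	phenotype	8	3.6	3.1	2.7	0.610	0.638	0.047
Black pied	phenotype	5	2.8	2.7	2.1	0.500	0.537	0.077
Multi-coloured	phenotype	18	4.3	3.0	2.7	0.499	0.616	0.196
Royal purple	phenotype	20	4.7	3.1	2.8	0.514	0.617	0.170
Atakora	zone	35	5.17	4.9	3.24	0.498	0.619	0.199
Dry Savannah	zone	59	5.22	4.7	3.05	0.522	0.614	0.150
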