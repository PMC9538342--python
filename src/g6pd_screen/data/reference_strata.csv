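sex,panel_status,activity_status,sanger_status,count,zygosity,variants,ratios,ages
male,positive,deficient,not_done,413,hemizygous,c.1388G>A,,
male,positive,normal,not_done,1,hemizygous,c.1024C>T,,
male,negative,deficient,positive,7,hemizygous,c.98T>C;c.202G>A;c.305T>C;c.305T>C;c.305T>C;c.739G>A;c.835A>T,0.61;0.34;0.27;0.23;0.20;0.46;0.38,38;34;19;39;29;41;76
male,negative,normal,negative,16,,,,
female,positive,deficient,not_done,58,heterozygous,c.1388G>A,,
female,positive,normal,not_done,36,heterozygous,c.1388G>A,,
female,negative,deficient,positive,2,heterozygous,c.305T>C;c.563C>T,0.84;0.73,30;26
female,negative,normal,negative,22,,,,
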